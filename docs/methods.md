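# Methods

## The model

tau is an intrinsically disordered protein with more than 80
phosphorylable residues; a molecule with *n* sites occupies one of 2^n
phosphoform microstates, which makes explicit kinetic bookkeeping
hopeless at tau scale. `tauphos` instead integrates only per-site
*macrostates* and reconstructs microstates on demand by probability
theory. Three pools are tracked per residue *i* (all concentrations in
μM, time in minutes):

```
R_i_close  <--slow-->  R_i_open  --fast-->  P_i
```

* `R_i_close` — the residue is inaccessible to kinases,
* `R_i_open` — accessible, unphosphorylated,
* `P_i` — phosphorylated.

Phosphorylation is Michaelis–Menten with substrate competition: every
residue a kinase acts on shares one Michaelis constant, so

    V_i = k_i · [kinase] · R_i_eff / (K_M + Σ_j R_j_eff).

For random-mechanism residues `R_i_eff = R_i_open`. S396 is
phosphorylated by GSK3β only after S404 on the same molecule
(self-priming); under the independence assumption the doubly constrained
pool factorises, `R_396_eff = R_396_open · P_404 / tau_total`. CDK5
phosphorylates every residue, including S396/S404, by the random
mechanism. Dephosphorylation by PP2A mirrors the same competitive law
over the phosphorylated pools and returns material to the open pool;
PP2A acts randomly on all residues.

Partial phosphorylation is the central device: only a fraction `alpha_i`
of molecules has residue *i* open at the start of a short-term assay
(`R_i_open(0) = alpha_i · tau`), so each `P_i` plateaus at
`alpha_i · tau` and the total stoichiometry at `N = Σ alpha_i` mol P/mol
tau — far below *n*, as the in vitro data demand. Conformational
opening is far slower than catalysis, so `k_open = k_close = 0` during
short-term simulations (a config switch allows nonzero values); the
long-term regime is represented instead by setting all `alpha_i = 1`,
under which every `P_i → tau`.

Ten residues are modelled explicitly (T181, S199, S202, T205, T212,
T217, T231, S396, S404, S422) plus one *pseudoresidue* per kinase that
lumps all remaining phosphorylable sites so that total stoichiometry can
be matched; the pseudoresidues compete in the shared K_M denominator
like any other substrate. Kinases: GSK3β and CDK5 (fitted), p38γ
(constants are configuration, chosen so that T205 is strongly
p38γ-dependent and S199/S396/S404 only weakly), and PKA, which acts only
through priming: the PKA flag selects the `alpha_i^PKA` / `k_i^PKA`
variants rather than adding reactions. The only phosphatase is PP2A.

### Microstate reconstruction

With independent per-site phosphorylation, the probability of pattern
`(a_1…a_n)` is `Π_i S(a_i)/S_total` where `S(a_i=1) = P_i`. Two variants
are exposed for the sequential pair, where independence is violated by
construction: the naive product, and a conditional law that zeroes the
unreachable cell `(pS396, S404 unphosphorylated)` and assigns
`p(1,1) = P_396/S_total`, `p(0,1) = (P_404 − P_396)/S_total`. The
brute-force oracle (below) quantifies the difference; users querying
joint states of the sequential pair should prefer the conditional
variant.

### Observation model

Measured signals are arbitrary-unit immunodetection values, proportional
to the phosphorylated pool through a single coefficient `f` (a.u./μM)
shared by all datasets. Phosphorylation of S396 masks the pS404
antibody epitope, so the observed pS404 signal under GSK3β follows
`f · (P_404 − P_396)`, floored at zero (immunodetection cannot be
negative; whether masking is total or partial is absorbed into `f`).
Masking applies only to the GSK3β sequential pair — CDK5 phosphorylates
the two sites independently — and is ignored in the dephosphorylation
stage. This difference signal is what makes the observed GSK3β pS404
time course biphasic (transient peak, lower plateau) while the CDK5
curve is monotone.

## Validation oracle

`tauphos.oracle` builds the full combinatorial ODE system for small
models: each molecule is classified per site as closed /
open-unphosphorylated / phosphorylated (3^n extended states), with
single-site flips whose rate laws aggregate the identical substrate
totals as the reduced model. For random mechanisms with a shared K_M
the reduced marginals and the product-form microstate probabilities are
exact (deviation at integrator tolerance, < 1e-6); for the sequential
motif the oracle measures the real independence-approximation error,
which is material mid-course and — for the gated site's plateau —
persistent: the reduced model lets `P_396` reach `alpha_396·tau`
whereas the true gated plateau is `alpha_396·alpha_404·tau`. The
`P_404` marginal is unaffected. The oracle is capped at 6 sites
(729 states) and requires the frozen open/closed partition; it is a test
instrument, never the production simulator.

## Calibration

Stage one fits the phosphorylation parameters jointly over four
datasets (GSK3β/CDK5 × ±PKA prephosphorylation): per-dataset `k_i` and
`alpha_i` for every participating residue plus the shared `f`. The
pseudoresidue is excluded from the CDK5-without-PKA condition, where the
observed sites already carry the full stoichiometry. Homoscedastic
Gaussian errors make maximum likelihood equivalent to least squares;
stoichiometry records are converted to the signal scale with the fixed
weight `f_0 · tau` so both channels share one noise scale (the weight
uses the *initial* `f` estimate, keeping the objective a genuine sum of
squares rather than a parameter-dependent reweighting).

The procedure has three steps:

1. **Starting values.** `f_0` is the plateau-signal ratio
   `Σ E_i / (tau · N)` computed per dataset, keeping the maximum
   candidate (the largest comes from the condition whose observed sites
   cover the most stoichiometry — CDK5 without prephosphorylation in
   the packaged design). `alpha` starts from plateau signal over
   `f_0 · tau`; `k` from the initial slope of each curve.
2. **Preliminary fit** of all parameters with bounded trust-region
   least squares (`scipy.optimize.least_squares`, TRF) exploiting the
   block structure of the Jacobian (each dataset depends only on its own
   parameters plus `f`). Multi-start perturbation is available behind
   `FitConfig.n_starts`; α is bounded to [0, 1], catalytic constants to
   [0, 20]/min — a soft cap from the minutes-scale assays.
3. **Grouping and refit.** Parameters of the same kind (α with α,
   k with k, across datasets) whose preliminary values fall within a
   relative tolerance (default 15%; "similar values" is otherwise
   unquantified) are merged by single-linkage chaining and refitted as
   one coordinate. Grouping trades variance for bias: it is the right
   tool when curves do not saturate and `alpha_i·k_i` products are all
   the data constrain. On densely spread synthetic truth the 15% chain
   can over-merge, so recovery experiments here run with grouping
   disabled; the grouped path is validated against truth generated with
   genuinely shared values (nested-model F-test).

Stage two fixes the stage-one estimates, simulates the pre-incubation
protocol recorded in the dephosphorylation dataset (kinase, PKA flag and
endpoint time are dataset fields, not constants) to obtain the initial
phospho-state, and fits the PP2A catalytic constants of the six residues
with data (S199, S202, T205, T212, S396, S404); the remaining residues
and the pseudoresidue receive the mean of the six. `K_M` values are
never fitted: 1 μM for GSK3β/CDK5 and 11.6 μM for PP2A.

## Uncertainty

At the optimum, `cov = σ̂²(JᵀJ)⁻¹` with `J` the residual Jacobian and
`σ̂²` estimated from the residuals (measurement noise is never known a
priori); 95% intervals use the Student-t quantile at `n − p` degrees of
freedom with `p` the effective (grouped) parameter count. Rank
deficiency of `JᵀJ` (singular values below 1e-10 of the largest) is
reported as a named list of locally non-identifiable parameters; no
pseudo-inverse is taken silently. Trajectory bands are Monte-Carlo:
multivariate-normal draws at the optimum, rejection-sampled into the box
bounds (so α stays a probability), simulated and summarised as pointwise
2.5/97.5 percentiles; deterministic given the seed, and convergent to
the linearization band for linear observables.

## Sensitivity analysis

Pseudoglobal design: i.i.d. uniform draws over (a) 0 to twice the
fitted value for GSK3β/CDK5/PP2A catalytic constants, (b) 0 to 1.0 μM
for enzyme levels, (c) 0 to 100 for Michaelis constants and the p38γ
constants; endpoints are the per-residue phosphorylated levels and total
stoichiometry at the endpoint time (default 240 min, the calibration
assay's final time; configurable, and extra early times can be recorded
to expose the transient S396–S404 coupling). Pearson correlation is
used deliberately, although the responses are monotone-nonlinear, so the
heatmap is comparable with correlation-based sensitivity reports;
rank-based indices would be the conservative alternative. Failed
simulations are excluded and counted; above 1% the run aborts. The
PP2A→GSK3β activation cross-talk is ON by default for sensitivity runs
and OFF elsewhere, implemented as a saturating multiplicative factor
`[GSK3β]·(1 + a_max·[PP2A]/(K_act + [PP2A]))` with `a_max = 1`,
`K_act = 0.25 μM` — a declared model choice, since only the existence of
the activation is established.

## Packaged parameter set

The shipped "calibrated" model is a synthetic stand-in constructed to
satisfy the constraints reported for the fitted model rather than a
copy of it: PKA priming raises plateau stoichiometry by 50% (GSK3β) and
24% (CDK5); `alpha_404 > alpha_396`; CDK5 openness exceeds GSK3β's on
the six proline-directed sites and the reverse holds for
S396/S404/S422; the pseudoresidue is more open for GSK3β; CDK5 priming
is negative on T181/S202/T212/T217/S404; GSK3β catalytic constants
exceed CDK5's by up to three orders of magnitude (S396); PP2A
dephosphorylates S199 and S404 slowly. Assay conventions not stated by
the sources are fixed once: tau 2 μM, enzymes 0.5 μM, signal scale
f = 10 a.u./μM, phosphorylation sampling to 240 min, dephosphorylation
to 300 min after a 240-min pre-incubation. Fitted `k_i` are therefore
defined only up to these time/concentration conventions.

## Synthetic data

The generator emits the full study design (four phosphorylation
conditions with per-site signals and a total-stoichiometry series, one
dephosphorylation condition) from any truth model, with homoscedastic
Gaussian noise of σ = 0.3 a.u. by default (2–5% of typical signals,
ordinary densitometry precision), clipped at zero, plus a noise-free
channel for oracle tests. It reproduces the masking-induced biphasic
GSK3β pS404 curve and the monotone CDK5 curve. It does **not** emulate
blot saturation, inter-batch scale drift, heteroscedastic or correlated
errors, or epitope effects beyond the single pS404 rule — passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated error model, not robustness to real-blot
pathologies.

## Numerical choices and problem sizes

* Integrator: LSODA (via `scipy.integrate.odeint`), rtol 1e-8/atol 1e-12
  for simulation, relaxed to 1e-6/1e-9 inside fitting loops where
  residuals sit on the noise floor; oracle comparisons run at 1e-10.
  Mass conservation per site holds to 1e-8 relative along all
  trajectories and the oracle conserves total concentration likewise.
* Plateaus are read at t = 1e6 min, far beyond the slowest effective
  rate in the packaged set (CDK5 at S396).
* Recovery experiments use a compact three-residue, four-condition
  design (25 free parameters, 9 time points per curve) so that repeated
  refits run in seconds; the full 10-residue + pseudoresidue structure
  is refitted once per acceptance run. Sensitivity checks use 400–800
  draws (the full published-scale design of 1e5 draws is available via
  `--n-samples`); null-correlation thresholds follow the 3/√n standard
  error of Pearson's r.
* Degenerate inputs: zero substrate, zero enzymes, `S_total = 0`,
  unknown sites, negative pools, decreasing time grids and rank-
  deficient information matrices all raise explicit errors; microstate
  enumeration is guarded above 20 sites.

## Known limitations

* The sequential pair violates independence by construction; the
  reduced model overestimates the gated site's plateau (see the oracle
  section). All downstream quantities inherit this approximation, as
  intended by the modelling framework.
* Grouping is decided once after the preliminary fit; no model-selection
  criterion arbitrates the tolerance.
* The SBML layer writes and reads a well-formed SBML L3 core subset
  sufficient for round-tripping this model family; it is not a general
  SBML consumer, and condition switches/prerequisites travel in a
  package annotation block because SBML core has no native notion of
  them.
* GSK3β autophosphorylation, reciprocal GSK3β/CDK5 priming, the
  GSK3β→PP2A inhibitory arm, tau aggregation and microstate-explicit
  production simulation are out of scope.
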
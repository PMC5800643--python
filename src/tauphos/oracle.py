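"""Brute-force microstate ODE oracle.

Integrates the full combinatorial system for small site counts to ground-
truth the reduced macrostate model.  Every molecule is classified by an
extended per-site state: closed (0), open-unphosphorylated (1) or
phosphorylated (2), giving 3^n extended microstates.  Transitions flip one
site at a time; kinase and phosphatase fluxes use the same shared-K_M
competitive rate laws as the reduced model, with the competition
denominator aggregated over the identical substrate totals.

The oracle is a validation instrument only (capped at 6 sites ≈ 729
states); the production simulator never enumerates microstates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import MacroState, PhosphoModel, SimulationError, simulate
from .probability import MacroSummary, MicrostatePattern, microstate_probability

__all__ = ["MicrostateSystem", "build_full_system", "compare_to_reduced"]

MAX_ORACLE_SITES = 6
_ORACLE_RTOL = 1e-10
_ORACLE_ATOL = 1e-14


@dataclass
class MicrostateSystem:
    """The compiled 3^n extended-microstate ODE system."""

    model: PhosphoModel
    states: list[tuple[int, ...]]          # extended per-site states 0/1/2
    index: dict[tuple[int, ...], int]
    y0: np.ndarray                         # initial concentrations, μM
    kinase_transitions: list[tuple[str, float, float, np.ndarray, np.ndarray, np.ndarray]]
    dephos_transitions: tuple[float, float, np.ndarray, np.ndarray, np.ndarray] | None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        for _name, conc, km, fr, to, kvec in self.kinase_transitions:
            denom = km + y[fr].sum()
            flux = kvec * conc * y[fr] / denom
            np.subtract.at(dy, fr, flux)
            np.add.at(dy, to, flux)
        if self.dephos_transitions is not None:
            conc, km, fr, to, kvec = self.dephos_transitions
            denom = km + y[fr].sum()
            flux = kvec * conc * y[fr] / denom
            np.subtract.at(dy, fr, flux)
            np.add.at(dy, to, flux)
        return dy

    def integrate(self, t_grid) -> np.ndarray:
        t = np.asarray(t_grid, dtype=float)
        sol = solve_ivp(self.rhs, (t[0], t[-1]), self.y0, t_eval=t,
                        method="LSODA", rtol=_ORACLE_RTOL, atol=_ORACLE_ATOL)
        if not sol.success:
            raise SimulationError(f"oracle integration failed: {sol.message}")
        return np.clip(sol.y.T, 0.0, None)  # (n_times, n_states)

    # -- marginalisation ---------------------------------------------------

    def phospho_marginals(self, y: np.ndarray) -> np.ndarray:
        """P_i(t): total concentration with site i phosphorylated."""
        n = self.model.n_sites
        out = np.zeros((y.shape[0], n))
        for idx, st in enumerate(self.states):
            for i, v in enumerate(st):
                if v == 2:
                    out[:, i] += y[:, idx]
        return out

    def open_marginals(self, y: np.ndarray) -> np.ndarray:
        n = self.model.n_sites
        out = np.zeros((y.shape[0], n))
        for idx, st in enumerate(self.states):
            for i, v in enumerate(st):
                if v == 1:
                    out[:, i] += y[:, idx]
        return out

    def pattern_concentrations(self, y_row: np.ndarray) -> dict[tuple[int, ...], float]:
        """Collapse open/closed bookkeeping to 2^n phosphoform patterns."""
        out: dict[tuple[int, ...], float] = {}
        for idx, st in enumerate(self.states):
            pat = tuple(1 if v == 2 else 0 for v in st)
            out[pat] = out.get(pat, 0.0) + float(y_row[idx])
        return out


def build_full_system(model: PhosphoModel,
                      active_enzymes=("GSK3B",)) -> MicrostateSystem:
    """Enumerate the extended microstate system for a small model.

    Requires every site's conformational exchange rates to be zero (the
    open/closed split is then a static initial partition) and at most
    ``MAX_ORACLE_SITES`` sites.
    """
    n = model.n_sites
    if n > MAX_ORACLE_SITES:
        raise ValueError(
            f"oracle capped at {MAX_ORACLE_SITES} sites (got {n}); "
            "restrict the model to a small site subset for validation")
    for s in model.sites:
        if s.k_open != 0.0 or s.k_close != 0.0:
            raise ValueError("oracle assumes k_open = k_close = 0 "
                             "(open/closed handled as an initial partition)")

    states = [tuple(st) for st in itertools.product((0, 1, 2), repeat=n)]
    index = {st: i for i, st in enumerate(states)}

    pka = model.pka_flag
    alpha = np.array([s.get_alpha(model.condition_kinase, pka)
                      for s in model.sites])
    y0 = np.zeros(len(states))
    for st in states:
        if any(v == 2 for v in st):
            continue
        w = 1.0
        for i, v in enumerate(st):
            w *= alpha[i] if v == 1 else (1.0 - alpha[i])
        y0[index[st]] = w * model.tau_total

    kinase_transitions = []
    dephos = None
    for name in active_enzymes:
        enz = model.enzymes[name]
        if enz.role == "kinase":
            fr, to, kv = [], [], []
            for i, site in enumerate(model.sites):
                k = site.get_kcat(name, pka)
                if k <= 0:
                    continue
                prereq = site.prerequisite.get(name)
                j = model.site_index(prereq) if prereq is not None else None
                for st in states:
                    if st[i] != 1:
                        continue
                    if j is not None and st[j] != 2:
                        continue  # sequential gate: prerequisite not yet phosphorylated
                    dst = list(st)
                    dst[i] = 2
                    fr.append(index[st])
                    to.append(index[tuple(dst)])
                    kv.append(k)
            kinase_transitions.append(
                (name, model.effective_kinase_concentration(name), enz.km,
                 np.array(fr, dtype=int), np.array(to, dtype=int),
                 np.array(kv)))
        else:
            fr, to, kv = [], [], []
            for i, site in enumerate(model.sites):
                if site.kcat_pp2a <= 0:
                    continue
                for st in states:
                    if st[i] != 2:
                        continue
                    dst = list(st)
                    dst[i] = 1  # dephosphorylation returns the open pool
                    fr.append(index[st])
                    to.append(index[tuple(dst)])
                    kv.append(site.kcat_pp2a)
            dephos = (enz.concentration, enz.km, np.array(fr, dtype=int),
                      np.array(to, dtype=int), np.array(kv))

    return MicrostateSystem(model=model, states=states, index=index, y0=y0,
                            kinase_transitions=kinase_transitions,
                            dephos_transitions=dephos)


def compare_to_reduced(model: PhosphoModel, t_grid,
                       active_enzymes=("GSK3B",)) -> dict:
    """Deviation report: reduced macrostate model vs the full oracle.

    Returns per-time maxima of the relative deviation of phospho marginals
    and of the independence-reconstructed microstate probabilities, plus
    the oracle's conservation defect.
    """
    sys_ = build_full_system(model, active_enzymes)
    y_oracle = sys_.integrate(t_grid)
    traj = simulate(model, t_grid, active_enzymes=active_enzymes,
                    rtol=_ORACLE_RTOL, atol=_ORACLE_ATOL)

    scale = model.tau_total
    p_oracle = sys_.phospho_marginals(y_oracle)
    marg_dev = np.max(np.abs(traj.p - p_oracle), axis=1) / scale

    prob_dev = np.zeros(len(t_grid))
    seq_pairs = {}
    for i, site in enumerate(model.sites):
        for kin, prereq in site.prerequisite.items():
            if kin in active_enzymes:
                seq_pairs[i] = model.site_index(prereq)
    for ti in range(len(t_grid)):
        summary = MacroSummary(p=traj.p[ti], s_total=scale,
                               site_names=model.site_names)
        pats = sys_.pattern_concentrations(y_oracle[ti])
        worst = 0.0
        for pat, conc in pats.items():
            p_reduced = microstate_probability(summary, MicrostatePattern(pat))
            worst = max(worst, abs(p_reduced - conc / scale))
        prob_dev[ti] = worst

    conservation = np.max(np.abs(y_oracle.sum(axis=1) - scale)) / scale
    report = {
        "times": np.asarray(t_grid, dtype=float),
        "marginal_rel_deviation": marg_dev,
        "probability_deviation": prob_dev,
        "max_marginal_rel_deviation": float(marg_dev.max()),
        "max_probability_deviation": float(prob_dev.max()),
        "oracle_conservation_defect": float(conservation),
        "sequential_pairs": seq_pairs,
    }
    return report
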
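"""Two-stage calibration of the tau phosphorylation model.

Stage one fits the phosphorylation parameters — per-condition catalytic
constants ``k_i`` and openness fractions ``alpha_i`` plus a single signal
scale ``f`` shared by all four datasets (GSK3β/CDK5 × ±PKA
prephosphorylation) — by homoscedastic Gaussian maximum likelihood,
i.e. joint least squares over per-site signals and the total-stoichiometry
series.  The procedure follows three steps: heuristic starting values
(``f`` seeded from the plateau-signal ratio, the largest candidate across
datasets), a preliminary fit of all parameters, then grouping of
similar-valued parameters (single-linkage on relative difference) and a
final refit of the reduced set.

Stage two fits the PP2A catalytic constants against a dephosphorylation
time course whose initial state is produced by simulating the
phosphorylation protocol to the experiment's pre-incubation endpoint.
Only six residues carry data; the unobserved residues receive the mean of
the six fitted constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (CDK5, GSK3B, PP2A, PP2A_OBSERVED_SITES, PhosphoModel,
                    SimulationError, initialize, simulate, stoichiometry)
from .observation import ObservationMap, estimate_f_initial, predict_signal_trajectory

__all__ = ["CalibrationDataset", "GroupingMap", "FitResult", "FitConfig",
           "objective", "fit_phosphorylation", "group_parameters",
           "fit_dephosphorylation", "load_datasets_csv", "save_datasets_csv"]

#: Penalty returned when a parameter draw makes the ODE system unintegrable.
_PENALTY = 1e6

_FIT_RTOL = 1e-6   # looser than simulation default: residuals sit on noise
_FIT_ATOL = 1e-9

STOICH_SITE = "total"


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class CalibrationDataset:
    """One experimental condition's time courses in arbitrary units.

    ``records`` columns: site, time (min), value, value_type
    (``signal_au`` for per-site signals with site set to the residue name,
    ``stoichiometry`` for total mol P/mol tau with site = ``"total"``).
    Dephosphorylation datasets carry the pre-incubation protocol
    (``preincubation = {"kinase", "pka", "time"}``) that defines their
    initial phospho-state.
    """

    condition: str
    kinase: str
    pka: int
    records: pd.DataFrame
    preincubation: dict | None = None

    def __post_init__(self):
        req = {"site", "time", "value", "value_type"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        if (self.records["time"] < 0).any():
            raise ValueError("negative time in dataset")
        if self.pka not in (0, 1):
            raise ValueError("pka flag must be 0 or 1")

    @property
    def is_dephosphorylation(self) -> bool:
        return self.kinase == PP2A

    @property
    def observed_sites(self) -> list[str]:
        mask = self.records["value_type"] == "signal_au"
        return sorted(self.records.loc[mask, "site"].unique())

    def times(self) -> np.ndarray:
        t = np.unique(self.records["time"].to_numpy(dtype=float))
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
        return t

    def masking_rules(self) -> dict[str, str]:
        """pS396 masks the pS404 antibody only under sequential GSK3β."""
        if self.kinase == GSK3B and {"S396", "S404"} <= set(self.observed_sites):
            return {"S404": "S396"}
        return {}


def save_datasets_csv(datasets: Sequence[CalibrationDataset], path) -> None:
    frames = []
    for ds in datasets:
        df = ds.records.copy()
        df.insert(0, "condition", ds.condition)
        df.insert(1, "kinase", ds.kinase)
        df.insert(2, "pka", ds.pka)
        if ds.preincubation:
            df["preinc_kinase"] = ds.preincubation["kinase"]
            df["preinc_pka"] = ds.preincubation["pka"]
            df["preinc_time"] = ds.preincubation["time"]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_datasets_csv(path) -> list[CalibrationDataset]:
    df = pd.read_csv(path)
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        preinc = None
        if "preinc_kinase" in grp.columns and grp["preinc_kinase"].notna().any():
            preinc = {"kinase": str(grp["preinc_kinase"].iloc[0]),
                      "pka": int(grp["preinc_pka"].iloc[0]),
                      "time": float(grp["preinc_time"].iloc[0])}
        records = grp[["site", "time", "value", "value_type"]].reset_index(drop=True)
        out.append(CalibrationDataset(condition=str(cond),
                                      kinase=str(grp["kinase"].iloc[0]),
                                      pka=int(grp["pka"].iloc[0]),
                                      records=records, preincubation=preinc))
    return out


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

def param_name(kind: str, site: str | None = None, kinase: str | None = None,
               pka: int | None = None) -> str:
    if kind == "f":
        return "f"
    if kind == "kpp2a":
        return f"kpp2a:{site}"
    return f"{kind}:{site}:{kinase}:{pka}"


@dataclass
class _ParamEntry:
    """One free optimiser coordinate; may stand for a whole group."""

    name: str
    kind: str              # "alpha" | "k" | "f" | "kpp2a"
    lo: float
    hi: float
    x0: float
    members: list[tuple]   # (kinase, pka, site) or (None, None, site) or ()


@dataclass
class GroupingMap:
    """Parameter name → group id; grouped parameters share one value."""

    assignments: dict[str, int]

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, gid in self.assignments.items():
            out.setdefault(gid, []).append(name)
        return out

    @property
    def n_parameters(self) -> int:
        return len(set(self.assignments.values()))

    def validate(self) -> None:
        for gid, members in self.groups().items():
            if not members:
                raise ValueError(f"empty group {gid}")


@dataclass
class FitResult:
    """Estimates plus everything needed for downstream uncertainty work."""

    param_names: list[str]
    x: np.ndarray
    estimates: dict[str, float]
    objective: float
    grouping: GroupingMap | None
    residuals: np.ndarray
    jacobian: np.ndarray
    bounds: tuple[np.ndarray, np.ndarray]
    covariance: np.ndarray | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_residuals(self) -> int:
        return len(self.residuals)

    def to_json(self, path) -> None:
        payload = {
            "estimates": self.estimates,
            "objective": self.objective,
            "grouping": self.grouping.assignments if self.grouping else None,
            "ci95": {k: list(v) for k, v in (self.ci95 or {}).items()},
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


@dataclass
class FitConfig:
    """Optimiser and grouping settings."""

    grouping_tolerance: float = 0.15   # relative difference for "similar"
    k_upper: float = 20.0              # 1/min, soft bound from data timescale
    alpha_lower: float = 0.0
    max_nfev: int = 400
    n_starts: int = 1
    seed: int = 0
    sim_rtol: float = _FIT_RTOL
    stoich_weight: float | None = None  # a.u. per (mol P/mol); default f0·tau


# ---------------------------------------------------------------------------
# Residuals and objective
# ---------------------------------------------------------------------------

class _PhosphoProblem:
    """Joint residuals over the four phosphorylation datasets."""

    def __init__(self, datasets: Sequence[CalibrationDataset],
                 model: PhosphoModel, entries: list[_ParamEntry],
                 stoich_weight: float, sim_rtol: float):
        self.datasets = list(datasets)
        self.base = model
        self.entries = entries
        self.stoich_weight = stoich_weight
        self.sim_rtol = sim_rtol
        self.models = {}
        self.layout = []  # per dataset: (times, rows) where rows reference time idx
        for ds in self.datasets:
            m = model.with_condition(ds.kinase, ds.pka)
            self.models[ds.condition] = m
            t = ds.times()
            tidx = {tt: i for i, tt in enumerate(t)}
            rows = []
            for _, r in ds.records.iterrows():
                rows.append((r["site"], tidx[float(r["time"])],
                             float(r["value"]), r["value_type"]))
            self.layout.append((ds, t, rows))
        self.n_residuals = sum(len(rows) for _, _, rows in self.layout)

    def param_index(self) -> dict[str, int]:
        return {e.name: i for i, e in enumerate(self.entries)}

    def apply(self, x: np.ndarray) -> float:
        """Write parameter vector into the per-dataset models; returns f."""
        f_val = None
        for e, val in zip(self.entries, x):
            if e.kind == "f":
                f_val = float(val)
                continue
            for kinase, pka, site in e.members:
                for ds in self.datasets:
                    if ds.kinase != kinase or ds.pka != pka:
                        continue
                    m = self.models[ds.condition]
                    s = m.site(site)
                    if e.kind == "alpha":
                        s.alpha[(kinase, pka)] = float(val)
                    else:
                        s.kcat[(kinase, pka)] = float(val)
        if f_val is None:
            raise ValueError("parameter space lacks f")
        return f_val

    def residuals(self, x: np.ndarray) -> np.ndarray:
        f_val = self.apply(x)
        out = np.empty(self.n_residuals)
        pos = 0
        for ds, t, rows in self.layout:
            m = self.models[ds.condition]
            try:
                traj = simulate(m, t, active_enzymes=(ds.kinase,),
                                rtol=self.sim_rtol, atol=_FIT_ATOL)
            except SimulationError:
                out[pos:pos + len(rows)] = _PENALTY
                pos += len(rows)
                continue
            obs = ObservationMap(f=f_val, observed_sites=ds.observed_sites,
                                 masking_rules=ds.masking_rules())
            signals = {s: predict_signal_trajectory(traj, obs, s)
                       for s in ds.observed_sites}
            stoich = traj.p.sum(axis=1) / m.tau_total
            for site, ti, value, vtype in rows:
                if vtype == "stoichiometry":
                    out[pos] = (stoich[ti] - value) * self.stoich_weight
                else:
                    out[pos] = signals[site][ti] - value
                pos += 1
        return out

    def sparsity(self) -> np.ndarray:
        """Residual-row → parameter dependence mask (for cheap Jacobians)."""
        mask = np.zeros((self.n_residuals, len(self.entries)), dtype=int)
        pos = 0
        for ds, _t, rows in self.layout:
            n = len(rows)
            for j, e in enumerate(self.entries):
                if e.kind == "f":
                    mask[pos:pos + n, j] = 1
                    continue
                if any(k == ds.kinase and p == ds.pka for k, p, _s in e.members):
                    mask[pos:pos + n, j] = 1
            pos += n
        return mask


def objective(params: Mapping[str, float],
              datasets: Sequence[CalibrationDataset], model: PhosphoModel,
              config: FitConfig | None = None) -> float:
    """Homoscedastic Gaussian MLE objective: the residual sum of squares."""
    config = config or FitConfig()
    entries = _build_entries(datasets, model, config, starts=params)
    f0 = float(params.get("f", 1.0))
    weight = config.stoich_weight or f0 * model.tau_total
    prob = _PhosphoProblem(datasets, model, entries, weight, config.sim_rtol)
    x = np.array([e.x0 for e in entries])
    r = prob.residuals(x)
    return float(r @ r)


# ---------------------------------------------------------------------------
# Starting values and parameter-space construction
# ---------------------------------------------------------------------------

def _plateau_table(ds: CalibrationDataset) -> tuple[dict[str, float], float | None]:
    """Last-time signal per site and final stoichiometry, if present."""
    sig = {}
    for site in ds.observed_sites:
        sub = ds.records[(ds.records["site"] == site)
                         & (ds.records["value_type"] == "signal_au")]
        sig[site] = float(sub.sort_values("time")["value"].iloc[-1])
    st = ds.records[ds.records["value_type"] == "stoichiometry"]
    n = float(st.sort_values("time")["value"].iloc[-1]) if len(st) else None
    return sig, n


def seed_f(datasets: Sequence[CalibrationDataset], model: PhosphoModel) -> float:
    """One f candidate per dataset from plateau signals; keep the maximum."""
    candidates = []
    for ds in datasets:
        sig, n = _plateau_table(ds)
        if n is None or n <= 0 or not sig:
            continue
        candidates.append(estimate_f_initial(sig, model.tau_total, n))
    if not candidates:
        raise ValueError("no dataset provides plateau stoichiometry to seed f")
    return max(candidates)


def _initial_slope(ds: CalibrationDataset, site: str) -> float:
    sub = ds.records[(ds.records["site"] == site)
                     & (ds.records["value_type"] == "signal_au")].sort_values("time")
    t = sub["time"].to_numpy(dtype=float)
    v = sub["value"].to_numpy(dtype=float)
    lead = min(3, len(t))
    if lead < 2 or t[lead - 1] == t[0]:
        return 0.0
    return max((v[lead - 1] - v[0]) / (t[lead - 1] - t[0]), 0.0)


def _build_entries(datasets, model, config: FitConfig,
                   starts: Mapping[str, float] | None = None,
                   f0: float | None = None) -> list[_ParamEntry]:
    """Ungrouped parameter space: f plus per-dataset (alpha_i, k_i)."""
    if f0 is None:
        f0 = (starts or {}).get("f") or seed_f(datasets, model)
    entries = [_ParamEntry("f", "f", 1e-6, np.inf, float(f0), [])]
    for ds in datasets:
        m = model.with_condition(ds.kinase, ds.pka)
        sig, _n = _plateau_table(ds)
        # crude openness guess: plateau signal over f0·tau
        alpha0 = {s: float(np.clip(v / (f0 * model.tau_total), 0.02, 0.95))
                  for s, v in sig.items()}
        sum_r0 = sum(alpha0.values()) * model.tau_total
        km = m.enzymes[ds.kinase].km
        conc = m.enzymes[ds.kinase].concentration
        for site_spec in m.sites:
            site = site_spec.name
            if site_spec.get_kcat(ds.kinase, ds.pka) <= 0 and site not in sig:
                continue  # residue not phosphorylated under this condition
            a_name = param_name("alpha", site, ds.kinase, ds.pka)
            k_name = param_name("k", site, ds.kinase, ds.pka)
            a0 = alpha0.get(site, 0.3)
            slope = _initial_slope(ds, site) if site in sig else 0.0
            denom = f0 * conc * max(a0 * model.tau_total, 1e-6)
            k0 = slope * (km + sum_r0) / denom if denom > 0 else 0.1
            k0 = float(np.clip(k0, 5e-3, config.k_upper / 2))
            if starts:
                a0 = float(starts.get(a_name, a0))
                k0 = float(starts.get(k_name, k0))
            entries.append(_ParamEntry(a_name, "alpha", config.alpha_lower, 1.0,
                                       float(np.clip(a0, 0.01, 0.99)),
                                       [(ds.kinase, ds.pka, site)]))
            entries.append(_ParamEntry(k_name, "k", 0.0, config.k_upper, k0,
                                       [(ds.kinase, ds.pka, site)]))
    return entries


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def _single_linkage_groups(values: dict[str, float], tol: float) -> list[list[str]]:
    """Chain-merge sorted values whose relative gap is within ``tol``."""
    if tol <= 0:
        return [[name] for name in values]
    items = sorted(values.items(), key=lambda kv: kv[1])
    groups: list[list[str]] = []
    for name, val in items:
        if groups:
            prev = values[groups[-1][-1]]
            mean = 0.5 * (abs(prev) + abs(val))
            if mean > 0 and abs(val - prev) / mean <= tol:
                groups[-1].append(name)
                continue
        groups.append([name])
    return groups


def group_parameters(preliminary: FitResult,
                     tolerance: float = 0.15) -> GroupingMap:
    """Group similar-valued alpha and k estimates (kinds never mix)."""
    assignments: dict[str, int] = {}
    gid = 0
    for kind in ("alpha", "k"):
        vals = {n: v for n, v in preliminary.estimates.items()
                if n.startswith(kind + ":")}
        for grp in _single_linkage_groups(vals, tolerance):
            for name in grp:
                assignments[name] = gid
            gid += 1
    for name in preliminary.estimates:
        if name not in assignments:
            assignments[name] = gid
            gid += 1
    gm = GroupingMap(assignments)
    gm.validate()
    return gm


def _grouped_entries(entries: list[_ParamEntry], grouping: GroupingMap,
                     values: Mapping[str, float]) -> list[_ParamEntry]:
    by_gid: dict[int, _ParamEntry] = {}
    order: list[int] = []
    for e in entries:
        gid = grouping.assignments.get(e.name)
        if gid is None or sum(1 for n, g in grouping.assignments.items()
                              if g == gid) == 1:
            gid = -1 - len(order)  # singleton keeps its own coordinate
        if gid in by_gid:
            by_gid[gid].members.extend(e.members)
        else:
            member_vals = [values.get(n, e.x0)
                           for n, g in grouping.assignments.items() if g == gid]
            x0 = float(np.mean(member_vals)) if member_vals else e.x0
            by_gid[gid] = _ParamEntry(
                name=e.name if gid < 0 else f"group{gid}[{e.kind}]",
                kind=e.kind, lo=e.lo, hi=e.hi,
                x0=float(np.clip(x0, e.lo if np.isfinite(e.lo) else x0,
                                 e.hi if np.isfinite(e.hi) else x0)),
                members=list(e.members))
            order.append(gid)
    return [by_gid[g] for g in order]


# ---------------------------------------------------------------------------
# Fitting drivers
# ---------------------------------------------------------------------------

def _run_least_squares(prob: _PhosphoProblem, config: FitConfig):
    x0 = np.array([e.x0 for e in prob.entries])
    lo = np.array([e.lo for e in prob.entries])
    hi = np.array([e.hi for e in prob.entries])
    x0 = np.clip(x0, lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, x0))
    res = least_squares(prob.residuals, x0, bounds=(lo, hi), method="trf",
                        jac_sparsity=prob.sparsity(), x_scale="jac",
                        max_nfev=config.max_nfev, diff_step=1e-5)
    if not res.success and res.status <= 0:
        raise RuntimeError(f"optimizer failed to converge: {res.message}")
    return res


def _result_from(res, prob: _PhosphoProblem, grouping, config,
                 provenance) -> FitResult:
    jac = np.asarray(res.jac.todense() if hasattr(res.jac, "todense") else res.jac)
    estimates = {}
    for e, val in zip(prob.entries, res.x):
        if e.kind == "f":
            estimates["f"] = float(val)
        elif not e.members:
            estimates[e.name] = float(val)
        for kinase, pka, site in e.members:
            estimates[param_name(e.kind, site, kinase, pka)] = float(val)
    fit = FitResult(param_names=[e.name for e in prob.entries],
                    x=np.asarray(res.x, dtype=float), estimates=estimates,
                    objective=float(res.fun @ res.fun), grouping=grouping,
                    residuals=np.asarray(res.fun, dtype=float), jacobian=jac,
                    bounds=(np.array([e.lo for e in prob.entries]),
                            np.array([e.hi for e in prob.entries])),
                    provenance=provenance)
    from .uncertainty import attach_linearized_ci
    try:
        attach_linearized_ci(fit)
    except np.linalg.LinAlgError:
        fit.provenance["ci_note"] = "information matrix singular; CIs omitted"
    return fit


def fit_phosphorylation(datasets: Sequence[CalibrationDataset],
                        model: PhosphoModel,
                        config: FitConfig | None = None) -> FitResult:
    """Three-step joint fit of (k_i, alpha_i, f) across the four datasets."""
    config = config or FitConfig()
    phospho = [ds for ds in datasets if not ds.is_dephosphorylation]
    if not phospho:
        raise ValueError("no phosphorylation datasets supplied")
    f0 = seed_f(phospho, model)
    weight = config.stoich_weight or f0 * model.tau_total

    entries = _build_entries(phospho, model, config, f0=f0)
    prob = _PhosphoProblem(phospho, model, entries, weight, config.sim_rtol)
    rng = np.random.default_rng(config.seed)
    best = None
    for start in range(max(1, config.n_starts)):
        if start > 0:
            for e in prob.entries:
                if e.kind == "alpha":
                    e.x0 = float(np.clip(e.x0 * rng.uniform(0.6, 1.4), 0.01, 0.99))
                elif e.kind == "k":
                    e.x0 = float(np.clip(e.x0 * rng.uniform(0.4, 2.5),
                                         1e-3, config.k_upper))
        res = _run_least_squares(prob, config)
        if best is None or res.cost < best.cost:
            best = res
    prelim = _result_from(best, prob, None, config,
                          {"stage": "preliminary", "f0": f0, "seed": config.seed})
    if config.grouping_tolerance <= 0:
        # grouping disabled: the preliminary solution is already final
        prelim.grouping = group_parameters(prelim, 0.0)
        prelim.provenance.update(
            stage="final", n_free_parameters=len(entries),
            n_parameters_before_grouping=len(entries),
            grouping_tolerance=0.0, sim_rtol=config.sim_rtol,
            stoich_weight=weight)
        return prelim

    grouping = group_parameters(prelim, config.grouping_tolerance)
    gentries = _grouped_entries(entries, grouping, prelim.estimates)
    gprob = _PhosphoProblem(phospho, model, gentries, weight, config.sim_rtol)
    gres = _run_least_squares(gprob, config)
    # Refitting the reduced set must not end above the grouped start point.
    provenance = {"stage": "final", "f0": f0, "seed": config.seed,
                  "n_free_parameters": len(gentries),
                  "n_parameters_before_grouping": len(entries),
                  "grouping_tolerance": config.grouping_tolerance,
                  "sim_rtol": config.sim_rtol, "stoich_weight": weight}
    return _result_from(gres, gprob, grouping, config, provenance)


# ---------------------------------------------------------------------------
# Dephosphorylation stage
# ---------------------------------------------------------------------------

class _DephosProblem:
    def __init__(self, dataset: CalibrationDataset, model: PhosphoModel,
                 f_val: float, y0, fit_sites: list[str], sim_rtol: float):
        self.ds = dataset
        self.model = model
        self.f = f_val
        self.y0 = y0
        self.fit_sites = fit_sites
        self.sim_rtol = sim_rtol
        self.t = dataset.times()
        tidx = {tt: i for i, tt in enumerate(self.t)}
        self.rows = [(r["site"], tidx[float(r["time"])], float(r["value"]))
                     for _, r in dataset.records.iterrows()
                     if r["value_type"] == "signal_au"]

    def residuals(self, x: np.ndarray) -> np.ndarray:
        for site, k in zip(self.fit_sites, x):
            self.model.site(site).kcat_pp2a = float(k)
        try:
            traj = simulate(self.model, self.t, active_enzymes=(PP2A,),
                            y0=self.y0, rtol=self.sim_rtol, atol=_FIT_ATOL)
        except SimulationError:
            return np.full(len(self.rows), _PENALTY)
        out = np.empty(len(self.rows))
        for i, (site, ti, value) in enumerate(self.rows):
            out[i] = self.f * traj.p_site(site)[ti] - value
        return out


def phosphorylation_endpoint(model: PhosphoModel, kinase: str, pka: int,
                             t_end: float, rtol: float = _FIT_RTOL):
    """Simulate the pre-incubation protocol; returns the endpoint state."""
    m = model.with_condition(kinase, pka)
    traj = simulate(m, np.linspace(0.0, t_end, 25), active_enzymes=(kinase,),
                    rtol=rtol)
    return traj.state_at(len(traj.times) - 1)


def fit_dephosphorylation(dataset: CalibrationDataset, model: PhosphoModel,
                          phospho_fit: FitResult,
                          config: FitConfig | None = None) -> FitResult:
    """Fit PP2A catalytic constants for the observed residues.

    Residues without data (and the pseudoresidue) receive the mean of the
    fitted constants afterwards; K_M^PP2A stays fixed.
    """
    config = config or FitConfig()
    if not dataset.is_dephosphorylation:
        raise ValueError("dataset is not a dephosphorylation condition")
    if dataset.preincubation is None:
        raise ValueError("dephosphorylation dataset lacks pre-incubation metadata")

    m = model.copy()
    _apply_estimates(m, phospho_fit.estimates)
    f_val = phospho_fit.estimates["f"]
    pre = dataset.preincubation
    y0 = phosphorylation_endpoint(m, pre["kinase"], pre["pka"], pre["time"],
                                  rtol=config.sim_rtol)
    m = m.with_condition(pre["kinase"], pre["pka"])

    observed = dataset.observed_sites
    fit_sites, skipped = [], []
    for site in observed:
        if site in m.site_names:
            fit_sites.append(site)
        else:
            skipped.append(site)
    if skipped:
        import warnings
        warnings.warn(f"dephosphorylation series for unknown sites skipped: {skipped}")

    prob = _DephosProblem(dataset, m, f_val, y0, fit_sites, config.sim_rtol)
    # start from the initial decay slope of each curve
    x0 = []
    p0 = {s: float(y0.p[m.site_index(s)]) for s in fit_sites}
    sum_p = float(np.sum(y0.p))
    pp2a = m.enzymes[PP2A]
    for site in fit_sites:
        sub = dataset.records[(dataset.records["site"] == site)
                              & (dataset.records["value_type"] == "signal_au")
                              ].sort_values("time")
        v = sub["value"].to_numpy(dtype=float)
        t = sub["time"].to_numpy(dtype=float)
        lead = min(3, len(v))
        slope = max((v[0] - v[lead - 1]) / max(t[lead - 1] - t[0], 1e-9), 0.0)
        denom = f_val * pp2a.concentration * max(p0[site], 1e-9)
        k0 = slope * (pp2a.km + sum_p) / denom if denom > 0 else 0.1
        x0.append(float(np.clip(k0, 1e-4, config.k_upper / 2)))
    res = least_squares(prob.residuals, np.asarray(x0),
                        bounds=(0.0, config.k_upper), method="trf",
                        x_scale="jac", max_nfev=config.max_nfev, diff_step=1e-5)
    if not res.success and res.status <= 0:
        raise RuntimeError(f"dephosphorylation fit failed: {res.message}")

    estimates = {param_name("kpp2a", s): float(k)
                 for s, k in zip(fit_sites, res.x)}
    mean_k = float(np.mean(res.x))
    unobserved = [s for s in m.site_names if s not in fit_sites]
    for s in unobserved:
        estimates[param_name("kpp2a", s)] = mean_k
    fit = FitResult(
        param_names=[param_name("kpp2a", s) for s in fit_sites],
        x=np.asarray(res.x, dtype=float),
        estimates=estimates, objective=float(res.fun @ res.fun), grouping=None,
        residuals=np.asarray(res.fun, dtype=float),
        jacobian=np.asarray(res.jac), bounds=(np.zeros(len(fit_sites)),
                                              np.full(len(fit_sites), config.k_upper)),
        provenance={"stage": "dephosphorylation", "mean_kpp2a": mean_k,
                    "unobserved_sites": unobserved,
                    "preincubation": dict(pre), "seed": config.seed})
    from .uncertainty import attach_linearized_ci
    try:
        attach_linearized_ci(fit)
    except np.linalg.LinAlgError:
        fit.provenance["ci_note"] = "information matrix singular; CIs omitted"
    return fit


def _apply_estimates(model: PhosphoModel, estimates: Mapping[str, float]) -> None:
    """Write named estimates (alpha/k/kpp2a) back into a model in place."""
    for name, val in estimates.items():
        if name == "f" or name.startswith("group"):
            continue
        parts = name.split(":")
        if parts[0] == "kpp2a":
            model.site(parts[1]).kcat_pp2a = float(val)
        elif parts[0] == "alpha":
            model.site(parts[1]).alpha[(parts[2], int(parts[3]))] = float(val)
        elif parts[0] == "k":
            model.site(parts[1]).kcat[(parts[2], int(parts[3]))] = float(val)


apply_estimates = _apply_estimates
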
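"""Parameter uncertainty: linearized confidence intervals and Monte-Carlo bands.

At the least-squares optimum the parameter covariance is approximated by

    cov = sigma^2 * (J^T J)^(-1)

with ``J`` the residual Jacobian and ``sigma^2`` the residual variance
estimated from the fit (measurement noise is never known a priori here).
95% intervals use the Student-t quantile at ``n - p`` degrees of freedom,
``p`` being the effective (grouped) number of free parameters.  A
rank-deficient ``J^T J`` means some parameters are locally
non-identifiable; those are reported by name and no pseudo-inverse is
taken silently.

Trajectory confidence bands come from Monte-Carlo propagation: parameter
vectors drawn from the multivariate normal at the optimum (rejection-
sampled into the bounds so alpha stays a probability), simulated, and
summarised as pointwise 2.5/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = ["ConfidenceReport", "linearized_ci", "attach_linearized_ci",
           "monte_carlo_band"]

#: Singular values below this fraction of the largest are treated as zero.
RANK_RTOL = 1e-10


@dataclass
class ConfidenceReport:
    """Per-parameter intervals and/or a pointwise trajectory band."""

    method: str                       # "linearization" | "monte_carlo"
    estimates: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] | None = None
    non_identifiable: list[str] = field(default_factory=list)
    sigma2: float | None = None
    dof: int | None = None
    band_times: np.ndarray | None = None
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    band_central: np.ndarray | None = None

    @property
    def all_identifiable(self) -> bool:
        return not self.non_identifiable

    def to_json_dict(self) -> dict:
        out = {"method": self.method, "estimates": self.estimates,
               "non_identifiable": self.non_identifiable,
               "sigma2": self.sigma2, "dof": self.dof}
        if self.intervals is not None:
            out["ci95"] = {k: list(v) for k, v in self.intervals.items()}
        return out


def _covariance(jac: np.ndarray, residuals: np.ndarray,
                param_names: Sequence[str]):
    """sigma^2 (J^T J)^(-1) with explicit rank handling."""
    n, p = jac.shape
    if n <= p:
        raise np.linalg.LinAlgError(
            f"{n} residuals cannot constrain {p} parameters")
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    bad = s <= s[0] * RANK_RTOL if s[0] > 0 else np.ones_like(s, dtype=bool)
    flagged: list[str] = []
    if bad.any():
        # parameters loading on near-null directions of J
        null_mass = (vt[bad] ** 2).sum(axis=0)
        flagged = [param_names[j] for j in np.nonzero(null_mass > 1e-6)[0]]
        return None, None, n - p, flagged
    dof = n - p
    sigma2 = float(residuals @ residuals) / dof
    cov = (vt.T / s**2) @ vt * sigma2
    return cov, sigma2, dof, flagged


def linearized_ci(fit, confidence: float = 0.95) -> ConfidenceReport:
    """Linearization-method CIs for a finished fit.

    ``fit`` needs ``jacobian``, ``residuals``, ``x`` and ``param_names``
    (a :class:`~tauphos.calibration.FitResult` qualifies).  Singular
    information matrices yield a report naming the non-identifiable
    parameters, with no intervals.
    """
    jac = np.asarray(fit.jacobian, dtype=float)
    cov, sigma2, dof, flagged = _covariance(jac, fit.residuals, fit.param_names)
    estimates = {n: float(v) for n, v in zip(fit.param_names, fit.x)}
    if flagged:
        return ConfidenceReport(method="linearization", estimates=estimates,
                                intervals=None, non_identifiable=flagged,
                                dof=dof)
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
    half = tq * np.sqrt(np.diag(cov))
    intervals = {n: (float(v - h), float(v + h))
                 for n, v, h in zip(fit.param_names, fit.x, half)}
    return ConfidenceReport(method="linearization", estimates=estimates,
                            intervals=intervals, sigma2=sigma2, dof=dof)


def attach_linearized_ci(fit, confidence: float = 0.95) -> None:
    """Populate ``fit.covariance`` and ``fit.ci95`` in place (or raise)."""
    jac = np.asarray(fit.jacobian, dtype=float)
    cov, sigma2, dof, flagged = _covariance(jac, fit.residuals, fit.param_names)
    if flagged:
        raise np.linalg.LinAlgError(
            f"locally non-identifiable parameters: {flagged}")
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
    half = tq * np.sqrt(np.diag(cov))
    fit.covariance = cov
    fit.ci95 = {}
    for i, name in enumerate(fit.param_names):
        fit.ci95[name] = (float(fit.x[i] - half[i]), float(fit.x[i] + half[i]))
        # grouped members inherit the group interval
        if fit.grouping is not None and name.startswith("group"):
            gid = int(name[5:name.index("[")])
            for member, g in fit.grouping.assignments.items():
                if g == gid:
                    fit.ci95[member] = fit.ci95[name]


def monte_carlo_band(fit, predict: Callable[[np.ndarray], np.ndarray],
                     t_grid, n_draws: int = 1000, seed: int = 0,
                     confidence: float = 0.95) -> ConfidenceReport:
    """Pointwise Monte-Carlo confidence band for a predicted trajectory.

    ``predict`` maps a parameter vector (ordered as ``fit.param_names``)
    to the predicted observable on ``t_grid``.  Draws outside the fit's
    box bounds are rejection-sampled.  Deterministic given ``seed``.
    """
    if fit.covariance is None:
        raise ValueError("fit carries no covariance; run attach_linearized_ci")
    rng = np.random.default_rng(seed)
    lo, hi = fit.bounds
    cov = np.asarray(fit.covariance)
    central = np.asarray(predict(np.asarray(fit.x)), dtype=float)
    if np.allclose(cov, 0.0):
        return ConfidenceReport(method="monte_carlo",
                                band_times=np.asarray(t_grid, dtype=float),
                                band_lower=central.copy(),
                                band_upper=central.copy(),
                                band_central=central)
    draws = np.empty((n_draws, len(fit.x)))
    filled = 0
    attempts = 0
    while filled < n_draws:
        batch = rng.multivariate_normal(fit.x, cov,
                                        size=max(n_draws - filled, 64),
                                        method="svd")
        ok = np.all((batch >= lo) & (batch <= hi), axis=1)
        take = batch[ok][:n_draws - filled]
        draws[filled:filled + len(take)] = take
        filled += len(take)
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("rejection sampling cannot satisfy the bounds")
    sims = np.stack([np.asarray(predict(d), dtype=float) for d in draws])
    alpha = (1.0 - confidence) / 2.0
    lo_band = np.quantile(sims, alpha, axis=0)
    hi_band = np.quantile(sims, 1.0 - alpha, axis=0)
    return ConfidenceReport(method="monte_carlo",
                            band_times=np.asarray(t_grid, dtype=float),
                            band_lower=lo_band, band_upper=hi_band,
                            band_central=central)
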
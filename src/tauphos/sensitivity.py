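"""Pseudoglobal sensitivity analysis.

Uniform random sampling over parameter ranges, endpoint evaluation by
simulation, and endpoint–parameter Pearson correlation coefficients
rendered as a heatmap.  Ranges follow three rules: catalytic constants of
the calibrated kinases and of PP2A run from zero to twice their fitted
values; enzyme levels from zero to 1.0 μM; Michaelis constants and the
(uncalibrated) p38γ catalytic constants from zero to 100.  Endpoints are
the per-residue phosphorylated levels and the total stoichiometry at the
endpoint time; correlations at additional (early) times can be requested
to expose the transient S396–S404 coupling of the sequential mechanism.

Pearson (not rank) correlation is used deliberately even though responses
are monotone-nonlinear; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (CDK5, GSK3B, P38G, PP2A, PhosphoModel, SimulationError,
                    simulate)

__all__ = ["SensitivityDesign", "SensitivityResult", "default_design",
           "sample_parameters", "compute_sensitivity"]

#: Hard error threshold on the fraction of failed simulations.
MAX_FAILURE_FRACTION = 0.01

STOICH_ENDPOINT = "stoichiometry"


@dataclass
class SensitivityDesign:
    """Sampling ranges and endpoint definition.

    ``parameters`` maps a parameter key to its (low, high) uniform range.
    Keys: ``conc:<enzyme>``, ``km:<enzyme>``, ``k:<site>:<kinase>``,
    ``kpp2a:<site>``.  ``endpoint_times`` lists the evaluation times; the
    last one is the endpoint proper.
    """

    parameters: dict[str, tuple[float, float]]
    n_samples: int = 10_000
    seed: int = 0
    endpoint_times: tuple[float, ...] = (240.0,)
    condition_kinase: str = GSK3B
    pka: int = 0
    active_enzymes: tuple[str, ...] = (GSK3B, CDK5, P38G, PP2A)
    coupling: float | None = 1.0   # PP2A→GSK3β activation ON by default here

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name, (lo, hi) in self.parameters.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not self.endpoint_times:
            raise ValueError("at least one endpoint time required")


@dataclass
class SensitivityResult:
    """Pearson correlation matrices (endpoint × parameter) per time."""

    matrices: dict[float, pd.DataFrame]
    n_used: int
    n_failed: int
    design: SensitivityDesign
    samples: np.ndarray | None = None

    @property
    def matrix(self) -> pd.DataFrame:
        """Correlations at the endpoint time (the last requested time)."""
        return self.matrices[self.design.endpoint_times[-1]]

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)

    def heatmap(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        m = self.matrix
        fig, ax = plt.subplots(figsize=(1 + 0.5 * m.shape[1],
                                        1 + 0.45 * m.shape[0]))
        im = ax.imshow(m.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1,
                       aspect="auto")
        ax.set_xticks(range(m.shape[1]), m.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(m.shape[0]), m.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def default_design(model: PhosphoModel, n_samples: int = 10_000,
                   seed: int = 0,
                   endpoint_times: tuple[float, ...] = (240.0,)
                   ) -> SensitivityDesign:
    """Ranges per the three sampling rules, anchored to the fitted model."""
    params: dict[str, tuple[float, float]] = {}
    for enz in (GSK3B, CDK5, P38G, PP2A):
        params[f"conc:{enz}"] = (0.0, 1.0)          # rule (b)
        params[f"km:{enz}"] = (0.0, 100.0)          # rule (c)
    for site in model.sites:
        for kinase in (GSK3B, CDK5):
            k = site.get_kcat(kinase, 0)
            if k > 0:
                params[f"k:{site.name}:{kinase}"] = (0.0, 2.0 * k)  # rule (a)
        p38k = site.get_kcat(P38G, 0)
        if p38k > 0:
            params[f"k:{site.name}:{P38G}"] = (0.0, 100.0)          # rule (c)
        if site.kcat_pp2a > 0:
            params[f"kpp2a:{site.name}"] = (0.0, 2.0 * site.kcat_pp2a)
    return SensitivityDesign(parameters=params, n_samples=n_samples,
                             seed=seed, endpoint_times=endpoint_times)


def sample_parameters(design: SensitivityDesign) -> np.ndarray:
    """(n_samples, n_parameters) i.i.d. uniform draws; seed-reproducible."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    names = list(design.parameters)
    lo = np.array([design.parameters[n][0] for n in names])
    hi = np.array([design.parameters[n][1] for n in names])
    return lo + (hi - lo) * rng.random((design.n_samples, len(names)))


def _apply_draw(model: PhosphoModel, names: Sequence[str],
                values: np.ndarray, pka: int) -> None:
    for name, val in zip(names, values):
        parts = name.split(":")
        if parts[0] == "conc":
            model.enzymes[parts[1]].concentration = float(val)
        elif parts[0] == "km":
            model.enzymes[parts[1]].km = max(float(val), 1e-9)
        elif parts[0] == "k":
            site, kinase = parts[1], parts[2]
            spec = model.site(site)
            spec.kcat[(kinase, 0)] = float(val)
            spec.kcat[(kinase, 1)] = float(val)
        elif parts[0] == "kpp2a":
            model.site(parts[1]).kcat_pp2a = float(val)
        else:
            raise KeyError(f"unknown sensitivity parameter {name!r}")


def compute_sensitivity(design: SensitivityDesign, model: PhosphoModel,
                        keep_samples: bool = False) -> SensitivityResult:
    """Simulate every draw and correlate endpoints with parameters.

    Failed simulations are excluded and counted; more than 1% failures
    aborts the analysis (the ranges are then considered pathological).
    """
    design.validate()
    samples = sample_parameters(design)
    names = list(design.parameters)
    times = sorted(design.endpoint_times)
    t_grid = np.unique(np.concatenate([[0.0], np.asarray(times, dtype=float)]))
    t_index = [int(np.searchsorted(t_grid, t)) for t in times]

    site_names = model.site_names
    endpoints = site_names + [STOICH_ENDPOINT]
    values = {t: np.full((design.n_samples, len(endpoints)), np.nan)
              for t in times}
    failed = 0
    base = model.copy()
    base.pp2a_gsk3b_coupling = design.coupling
    base = base.with_condition(design.condition_kinase, design.pka)
    for i in range(design.n_samples):
        m = base.copy()
        _apply_draw(m, names, samples[i], design.pka)
        try:
            traj = simulate(m, t_grid, active_enzymes=design.active_enzymes,
                            rtol=1e-6, atol=1e-10)
        except (SimulationError, ValueError):
            failed += 1
            continue
        for t, ti in zip(times, t_index):
            p = traj.p[ti]
            values[t][i, :-1] = p
            values[t][i, -1] = p.sum() / m.tau_total
    n_used = design.n_samples - failed
    if failed > MAX_FAILURE_FRACTION * design.n_samples:
        raise RuntimeError(
            f"{failed}/{design.n_samples} simulations failed; "
            "sampled ranges are likely pathological")

    matrices = {}
    for t in times:
        ok = ~np.isnan(values[t][:, 0])
        y = values[t][ok]
        x = samples[ok]
        corr = np.zeros((len(endpoints), len(names)))
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        y_std = y.std(axis=0)
        ys = (y - y.mean(axis=0)) / np.where(y_std > 0, y_std, 1.0)
        corr = ys.T @ xs / len(y)
        corr[y_std == 0, :] = 0.0
        matrices[t] = pd.DataFrame(corr, index=endpoints, columns=names)
    return SensitivityResult(matrices=matrices, n_used=n_used, n_failed=failed,
                             design=design,
                             samples=samples if keep_samples else None)
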
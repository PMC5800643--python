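"""Synthetic calibration datasets.

Generates time-course bundles with the structure the calibration stage
assumes: four phosphorylation conditions (GSK3β/CDK5 × ±PKA
prephosphorylation) with per-site signals in arbitrary units and a
total-stoichiometry series, plus one PP2A dephosphorylation condition
whose initial state comes from simulating a pre-incubation protocol.
Signals are the model's own predictions — antibody masking applied to the
GSK3β pS404 channel — corrupted by homoscedastic Gaussian noise of
standard deviation ``sigma`` (a.u.), clipped at zero as immunodetection
cannot go negative.  A noise-free channel is emitted alongside for oracle
tests.

The generator's defaults are the packaged calibrated model and the study
design of the source assays (four conditions, ten residues plus a
pseudoresidue, arbitrary-unit scaling); it emulates neither blot
saturation nor inter-batch scale drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import STOICH_SITE, CalibrationDataset
from .model import (CDK5, DEFAULT_F, DEFAULT_PREINCUBATION_TIME, GSK3B, PP2A,
                    PP2A_OBSERVED_SITES, TAU_SITES, PhosphoModel, simulate,
                    tau_model)
from .observation import ObservationMap, predict_signal_trajectory

__all__ = ["GeneratorConfig", "generate_bundle", "compact_truth_model"]

#: Sampling grid of the phosphorylation assays, minutes.
DEFAULT_PHOS_TIMES = (5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0)
#: Sampling grid of the dephosphorylation assay, minutes.
DEFAULT_DEPHOS_TIMES = (0.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0)


@dataclass
class GeneratorConfig:
    """True parameters live in ``model``; this fixes design and noise."""

    sigma: float = 0.3                # homoscedastic noise, a.u.
    f: float = DEFAULT_F              # a.u. per μM
    seed: int = 0
    phos_times: tuple[float, ...] = DEFAULT_PHOS_TIMES
    dephos_times: tuple[float, ...] = DEFAULT_DEPHOS_TIMES
    observed_sites: tuple[str, ...] = TAU_SITES
    dephos_observed_sites: tuple[str, ...] = PP2A_OBSERVED_SITES
    conditions: tuple[tuple[str, int], ...] = (
        (GSK3B, 0), (GSK3B, 1), (CDK5, 0), (CDK5, 1))
    include_dephosphorylation: bool = True
    preincubation: dict = field(default_factory=lambda: {
        "kinase": GSK3B, "pka": 0, "time": DEFAULT_PREINCUBATION_TIME})
    include_stoichiometry: bool = True

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.f <= 0:
            raise ValueError("f must be positive")
        if not self.phos_times:
            raise ValueError("phos_times must be nonempty")


def _emit(records: list, site: str, times, clean: np.ndarray,
          noisy: np.ndarray, value_type: str) -> None:
    for t, c, v in zip(times, clean, noisy):
        records.append({"site": site, "time": float(t), "value": float(v),
                        "value_type": value_type, "value_clean": float(c)})


def generate_bundle(config: GeneratorConfig | None = None,
                    model: PhosphoModel | None = None
                    ) -> list[CalibrationDataset]:
    """Simulate the full study design and return noisy datasets.

    Each dataset's ``records`` carries an extra ``value_clean`` column
    with the noise-free signal for oracle tests; the calibration code
    ignores it.  Byte-identical output for identical seeds.
    """
    config = config or GeneratorConfig()
    config.validate()
    model = model if model is not None else tau_model()
    rng = np.random.default_rng(config.seed)
    datasets: list[CalibrationDataset] = []

    for kinase, pka in config.conditions:
        m = model.with_condition(kinase, pka)
        t = np.concatenate([[0.0], np.asarray(config.phos_times, dtype=float)])
        traj = simulate(m, t, active_enzymes=(kinase,))
        sites = [s for s in config.observed_sites if s in m.site_names]
        masking = ({"S404": "S396"}
                   if kinase == GSK3B and {"S404", "S396"} <= set(sites) else {})
        obs = ObservationMap(f=config.f, observed_sites=list(sites),
                             masking_rules=masking)
        records: list[dict] = []
        for site in sites:
            clean = predict_signal_trajectory(traj, obs, site)[1:]
            noisy = np.clip(clean + rng.normal(0.0, config.sigma, len(clean)),
                            0.0, None)
            _emit(records, site, t[1:], clean, noisy, "signal_au")
        if config.include_stoichiometry:
            clean_n = traj.p.sum(axis=1)[1:] / m.tau_total
            noise_n = rng.normal(0.0, config.sigma, len(clean_n)) / (
                config.f * m.tau_total)
            noisy_n = np.clip(clean_n + noise_n, 0.0, None)
            _emit(records, STOICH_SITE, t[1:], clean_n, noisy_n, "stoichiometry")
        datasets.append(CalibrationDataset(
            condition=f"{kinase}_pka{pka}", kinase=kinase, pka=pka,
            records=pd.DataFrame.from_records(records)))

    if config.include_dephosphorylation:
        pre = config.preincubation
        m = model.with_condition(pre["kinase"], pre["pka"])
        t_pre = np.linspace(0.0, pre["time"], 25)
        endpoint = simulate(m, t_pre, active_enzymes=(pre["kinase"],)
                            ).state_at(len(t_pre) - 1)
        t = np.asarray(config.dephos_times, dtype=float)
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
        traj = simulate(m, t, active_enzymes=(PP2A,), y0=endpoint)
        # masking ignored during dephosphorylation (fits use plain f·P_i)
        obs = ObservationMap(f=config.f,
                             observed_sites=list(config.dephos_observed_sites))
        records = []
        for site in config.dephos_observed_sites:
            clean = predict_signal_trajectory(traj, obs, site)
            noisy = np.clip(clean + rng.normal(0.0, config.sigma, len(clean)),
                            0.0, None)
            _emit(records, site, t, clean, noisy, "signal_au")
        datasets.append(CalibrationDataset(
            condition="PP2A_dephos", kinase=PP2A, pka=0,
            records=pd.DataFrame.from_records(records),
            preincubation=dict(pre)))
    return datasets


# ---------------------------------------------------------------------------
# Reduced study design for recovery experiments
# ---------------------------------------------------------------------------

def compact_truth_model() -> PhosphoModel:
    """A three-residue variant of the study design, for recovery studies.

    Same four-condition structure (GSK3β/CDK5 × ±PKA), assay enzyme
    levels and protein total as the full model, but only three random-
    mechanism residues — small enough that repeated noisy refits run in
    seconds while exercising the identical fitting machinery.  Catalytic
    constants are chosen so every curve approaches saturation within the
    sampling window, keeping all parameters locally identifiable.
    """
    from .model import EnzymeSpec, SiteSpec
    truth = {
        "S199": dict(a={(GSK3B, 0): .30, (GSK3B, 1): .45, (CDK5, 0): .40, (CDK5, 1): .50},
                     k={(GSK3B, 0): .60, (GSK3B, 1): .80, (CDK5, 0): .40, (CDK5, 1): .40}),
        "T205": dict(a={(GSK3B, 0): .50, (GSK3B, 1): .70, (CDK5, 0): .60, (CDK5, 1): .55},
                     k={(GSK3B, 0): 1.2, (GSK3B, 1): 1.5, (CDK5, 0): .70, (CDK5, 1): .90}),
        "S404": dict(a={(GSK3B, 0): .70, (GSK3B, 1): .80, (CDK5, 0): .35, (CDK5, 1): .30},
                     k={(GSK3B, 0): .90, (GSK3B, 1): 1.3, (CDK5, 0): .55, (CDK5, 1): .60}),
    }
    sites = [SiteSpec(name=name, alpha=d["a"], kcat=d["k"], kcat_pp2a=0.5)
             for name, d in truth.items()]
    enzymes = {
        GSK3B: EnzymeSpec(GSK3B, 0.5, 1.0, "kinase"),
        CDK5: EnzymeSpec(CDK5, 0.5, 1.0, "kinase"),
        PP2A: EnzymeSpec(PP2A, 0.5, 11.6, "phosphatase"),
    }
    return PhosphoModel(sites=sites, enzymes=enzymes, tau_total=2.0)
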
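"""Observation model: μM pools → arbitrary-unit immunodetection signals.

Signals are proportional to the phosphorylated pool, with a single
proportionality coefficient ``f`` (a.u. per μM) shared by all datasets.
For the sequential GSK3β pair the pS404 antibody is masked once S396 is
also phosphorylated, so the observed pS404 signal follows the difference
P_404 − P_396 (floored at zero: immunodetection cannot go negative).
Masking applies only to GSK3β conditions — CDK5 phosphorylates S396 and
S404 independently — and is ignored during dephosphorylation fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import MacroState, PhosphoModel, Trajectory

__all__ = ["ObservationMap", "predict_signal", "predict_signal_trajectory",
           "estimate_f_initial"]


@dataclass
class ObservationMap:
    """Signal scale and antibody-masking rules.

    ``masking_rules`` maps an observed site to the downstream site whose
    phosphorylation hides it, e.g. ``{"S404": "S396"}``.
    """

    f: float
    observed_sites: list[str]
    masking_rules: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("f must be positive")
        for site, masker in self.masking_rules.items():
            if site == masker:
                raise ValueError("a site cannot mask itself")


def _masked_level(p: Mapping[str, float], site: str,
                  rules: Mapping[str, str]) -> float:
    masker = rules.get(site)
    if masker is None:
        return p[site]
    return max(p[site] - p[masker], 0.0)


def predict_signal(state: MacroState, obs_map: ObservationMap,
                   site: str, model: PhosphoModel) -> float:
    """Predicted arbitrary-unit signal for one residue at one state."""
    if site not in obs_map.observed_sites:
        raise KeyError(f"site {site!r} is not observed")
    p = {name: float(state.p[i]) for i, name in enumerate(model.site_names)}
    return obs_map.f * _masked_level(p, site, obs_map.masking_rules)


def predict_signal_trajectory(traj: Trajectory, obs_map: ObservationMap,
                              site: str) -> np.ndarray:
    """Vectorised signal prediction along a trajectory."""
    if site not in obs_map.observed_sites:
        raise KeyError(f"site {site!r} is not observed")
    level = traj.p_site(site).copy()
    masker = obs_map.masking_rules.get(site)
    if masker is not None:
        level = np.maximum(level - traj.p_site(masker), 0.0)
    return obs_map.f * level


def estimate_f_initial(plateau_signals: Mapping[str, float], tau_total: float,
                       n_stoich: float) -> float:
    """Initial estimate of f: sum of plateau signals over tau·N.

    Assumes the observed sites carry the whole phosphorylation
    stoichiometry (no pseudoresidue).  This value seeds the optimiser
    only; f itself is refit jointly with the kinetic parameters.  When
    several datasets are available, compute one candidate per dataset and
    keep the maximum (the largest candidate comes from the condition
    whose observed sites cover the most stoichiometry).
    """
    if tau_total <= 0 or n_stoich <= 0:
        raise ValueError("tau_total and stoichiometry must be positive")
    return float(sum(plateau_signals.values())) / (tau_total * n_stoich)
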
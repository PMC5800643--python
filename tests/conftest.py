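"""Shared fixtures: small models and pre-computed fits reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import tauphos as tp
from tauphos.calibration import FitConfig, fit_phosphorylation
from tauphos.synthetic import GeneratorConfig, compact_truth_model, generate_bundle

COMPACT_SITES = ("S199", "T205", "S404")
COMPACT_TIMES = (5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0)


@pytest.fixture()
def packaged_model() -> tp.PhosphoModel:
    return tp.tau_model()


@pytest.fixture()
def compact_model() -> tp.PhosphoModel:
    return compact_truth_model()


def make_random_mechanism_model(n_sites: int = 3, seed: int = 0,
                                with_pp2a: bool = True) -> tp.PhosphoModel:
    """Random-mechanism toy model with reproducible random parameters."""
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n_sites):
        sites.append(tp.SiteSpec(
            name=f"S{i}",
            alpha={("GSK3B", 0): float(rng.uniform(0.2, 0.9))},
            kcat={("GSK3B", 0): float(rng.uniform(0.1, 1.5))},
            kcat_pp2a=float(rng.uniform(0.05, 0.8)) if with_pp2a else 0.0))
    enzymes = {
        "GSK3B": tp.EnzymeSpec("GSK3B", 0.5, 1.0, "kinase"),
        "PP2A": tp.EnzymeSpec("PP2A", 0.3, 11.6, "phosphatase"),
    }
    return tp.PhosphoModel(sites=sites, enzymes=enzymes, tau_total=2.0)


def make_sequential_pair_model(k396: float = 2.0) -> tp.PhosphoModel:
    """Minimal S404→S396 sequential motif under GSK3β."""
    sites = [
        tp.SiteSpec(name="S404", alpha={("GSK3B", 0): 0.5},
                    kcat={("GSK3B", 0): 1.0}),
        tp.SiteSpec(name="S396", alpha={("GSK3B", 0): 0.3},
                    kcat={("GSK3B", 0): k396}, prerequisite={"GSK3B": "S404"}),
    ]
    enzymes = {"GSK3B": tp.EnzymeSpec("GSK3B", 0.5, 1.0, "kinase")}
    return tp.PhosphoModel(sites=sites, enzymes=enzymes, tau_total=2.0)


def compact_bundle(model, seed: int, sigma: float = 0.3,
                   include_dephos: bool = False):
    cfg = GeneratorConfig(seed=seed, sigma=sigma,
                          observed_sites=COMPACT_SITES,
                          dephos_observed_sites=COMPACT_SITES,
                          include_dephosphorylation=include_dephos,
                          phos_times=COMPACT_TIMES)
    return generate_bundle(cfg, model)


@pytest.fixture(scope="session")
def compact_fit():
    """One noisy four-condition fit on the compact design (reused widely)."""
    model = compact_truth_model()
    bundle = compact_bundle(model, seed=11)
    fit = fit_phosphorylation(bundle, model,
                              FitConfig(seed=0, grouping_tolerance=0.0))
    return model, bundle, fit
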
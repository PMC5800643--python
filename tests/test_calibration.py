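"""Objective, grouping arithmetic and both fitting stages."""

import numpy as np
import pandas as pd
import pytest

import tauphos as tp
from tauphos.calibration import (CalibrationDataset, FitConfig, FitResult,
                                 fit_dephosphorylation, group_parameters,
                                 load_datasets_csv, objective, param_name,
                                 save_datasets_csv)
from tauphos.synthetic import GeneratorConfig, compact_truth_model, generate_bundle

from conftest import COMPACT_SITES, COMPACT_TIMES, compact_bundle


def truth_params(model):
    out = {"f": 10.0}
    for s in model.sites:
        for (kin, pka), a in s.alpha.items():
            out[param_name("alpha", s.name, kin, pka)] = a
        for (kin, pka), k in s.kcat.items():
            out[param_name("k", s.name, kin, pka)] = k
    return out


class TestObjective:
    def test_zero_at_truth_on_noise_free_data(self, compact_model):
        bundle = compact_bundle(compact_model, seed=0, sigma=0.0)
        val = objective(truth_params(compact_model), bundle, compact_model)
        assert val < 1e-6  # integrator tolerance only

    def test_noise_raises_objective_to_chi_square_scale(self, compact_model):
        sigma = 0.3
        bundle = compact_bundle(compact_model, seed=5, sigma=sigma)
        val = objective(truth_params(compact_model), bundle, compact_model)
        n_points = sum(len(ds.records) for ds in bundle)
        expected = n_points * sigma**2
        # clipping at zero and stoichiometry reweighting distort mildly
        assert 0.4 * expected < val < 2.0 * expected

    def test_perturbing_identifiable_parameter_increases_objective(
            self, compact_model):
        bundle = compact_bundle(compact_model, seed=0, sigma=0.0)
        p = truth_params(compact_model)
        base = objective(p, bundle, compact_model)
        name = param_name("k", "T205", "GSK3B", 0)
        for factor in (0.7, 1.3):
            q = dict(p)
            q[name] = p[name] * factor
            assert objective(q, bundle, compact_model) > base + 1e-2

    def test_invariant_to_record_ordering(self, compact_model):
        bundle = compact_bundle(compact_model, seed=3, sigma=0.2)
        p = truth_params(compact_model)
        v1 = objective(p, bundle, compact_model)
        shuffled = []
        for ds in bundle:
            rec = ds.records.sample(frac=1.0, random_state=7).reset_index(drop=True)
            shuffled.append(CalibrationDataset(ds.condition, ds.kinase, ds.pka,
                                               rec, ds.preincubation))
        assert objective(p, shuffled, compact_model) == pytest.approx(v1, rel=1e-9)


class TestGrouping:
    def _fit_with_estimates(self, estimates):
        names = list(estimates)
        return FitResult(param_names=names,
                         x=np.array([estimates[n] for n in names]),
                         estimates=estimates, objective=0.0, grouping=None,
                         residuals=np.zeros(len(names) + 1),
                         jacobian=np.eye(len(names) + 1, len(names)),
                         bounds=(np.zeros(len(names)), np.ones(len(names))))

    def test_identical_values_form_one_group(self):
        est = {param_name("alpha", s, "GSK3B", 0): 0.4 for s in "ABC"}
        gm = group_parameters(self._fit_with_estimates(est), 0.15)
        gids = {gm.assignments[n] for n in est}
        assert len(gids) == 1

    def test_clustering_arithmetic_on_mixed_values(self):
        est = {param_name("k", "A", "GSK3B", 0): 0.10,
               param_name("k", "B", "GSK3B", 0): 0.11,
               param_name("k", "C", "GSK3B", 0): 0.50}
        gm = group_parameters(self._fit_with_estimates(est), 0.15)
        a, b, c = (gm.assignments[param_name("k", s, "GSK3B", 0)] for s in "ABC")
        assert a == b != c

    def test_zero_tolerance_is_identity_map(self):
        est = {param_name("alpha", s, "GSK3B", 0): v
               for s, v in zip("ABC", (0.4, 0.4, 0.4))}
        gm = group_parameters(self._fit_with_estimates(est), 0.0)
        assert len({gm.assignments[n] for n in est}) == 3

    def test_kinds_never_mix(self):
        est = {param_name("alpha", "A", "GSK3B", 0): 0.30,
               param_name("k", "A", "GSK3B", 0): 0.30}
        gm = group_parameters(self._fit_with_estimates(est), 0.15)
        assert gm.assignments[param_name("alpha", "A", "GSK3B", 0)] != \
            gm.assignments[param_name("k", "A", "GSK3B", 0)]


class TestFitPhosphorylation:
    def test_recovery_on_noisy_compact_design(self, compact_fit):
        model, _bundle, fit = compact_fit
        errs = []
        for s in model.sites:
            for (kin, pka), a in s.alpha.items():
                errs.append(abs(fit.estimates[param_name("alpha", s.name, kin,
                                                         pka)] - a) / a)
            for (kin, pka), k in s.kcat.items():
                errs.append(abs(fit.estimates[param_name("k", s.name, kin,
                                                         pka)] - k) / k)
        assert float(np.median(errs)) < 0.20
        assert abs(fit.estimates["f"] - 10.0) / 10.0 < 0.10

    def test_grouped_refit_matches_ungrouped_under_grouped_truth(self):
        # truth built with shared values: grouping must not cost fit quality
        model = compact_truth_model()
        shared_alpha, shared_k = 0.5, 0.8
        for s in model.sites:
            for key in s.alpha:
                s.alpha[key] = shared_alpha
            for key in s.kcat:
                s.kcat[key] = shared_k
        bundle = compact_bundle(model, seed=21, sigma=0.2)
        from tauphos.calibration import fit_phosphorylation
        free = fit_phosphorylation(bundle, model,
                                   FitConfig(seed=0, grouping_tolerance=0.0))
        grouped = fit_phosphorylation(bundle, model,
                                      FitConfig(seed=0, grouping_tolerance=0.15))
        assert grouped.provenance["n_free_parameters"] < \
            grouped.provenance["n_parameters_before_grouping"]
        # nested-model F-test: the grouped restriction must not be rejected
        from scipy import stats as sps
        n = free.n_residuals
        p_free = len(free.param_names)
        p_grp = len(grouped.param_names)
        f_stat = ((grouped.objective - free.objective) / (p_free - p_grp)) \
            / (free.objective / (n - p_free))
        assert f_stat < sps.f.ppf(0.99, p_free - p_grp, n - p_free)

    def test_provenance_records_settings(self, compact_fit):
        _model, _bundle, fit = compact_fit
        assert fit.provenance["stage"] == "final"
        assert "f0" in fit.provenance and "seed" in fit.provenance


class TestFitDephosphorylation:
    @pytest.fixture()
    def dephos_setup(self):
        model = tp.tau_model()
        bundle = generate_bundle(GeneratorConfig(seed=9, sigma=0.2), model)
        dephos = next(d for d in bundle if d.is_dephosphorylation)
        truth_fit = FitResult(param_names=["f"], x=np.array([10.0]),
                              estimates={"f": 10.0}, objective=0.0,
                              grouping=None, residuals=np.zeros(2),
                              jacobian=np.ones((2, 1)),
                              bounds=(np.zeros(1), np.full(1, 20.0)))
        return model, dephos, truth_fit

    def test_recovers_pp2a_constants_within_ci(self, dephos_setup):
        model, dephos, truth_fit = dephos_setup
        fit = fit_dephosphorylation(dephos, model, truth_fit, FitConfig(seed=0))
        inside = 0
        for s in tp.model.PP2A_OBSERVED_SITES:
            lo, hi = fit.ci95[param_name("kpp2a", s)]
            inside += lo <= model.site(s).kcat_pp2a <= hi
        assert inside >= 5  # of 6

    def test_unobserved_sites_get_mean_of_fitted(self, dephos_setup):
        model, dephos, truth_fit = dephos_setup
        fit = fit_dephosphorylation(dephos, model, truth_fit, FitConfig(seed=0))
        fitted = [fit.estimates[param_name("kpp2a", s)]
                  for s in tp.model.PP2A_OBSERVED_SITES]
        mean = float(np.mean(fitted))
        for s in ("T181", "T217", "T231", "S422", "pseudo_GSK3B"):
            assert fit.estimates[param_name("kpp2a", s)] == pytest.approx(mean)

    def test_half_time_ranking_matches_input_data(self, dephos_setup):
        # fast sites (T205, S202) must rank ahead of slow ones (S404, S199)
        model, dephos, truth_fit = dephos_setup
        fit = fit_dephosphorylation(dephos, model, truth_fit, FitConfig(seed=0))
        k = {s: fit.estimates[param_name("kpp2a", s)]
             for s in tp.model.PP2A_OBSERVED_SITES}
        assert k["T205"] > k["S404"] and k["S202"] > k["S199"]
        true_order = sorted(tp.model.PP2A_OBSERVED_SITES,
                            key=lambda s: model.site(s).kcat_pp2a)
        est_order = sorted(k, key=k.get)
        assert true_order == est_order


class TestDatasetIO:
    def test_csv_roundtrip_preserves_bundle(self, tmp_path, compact_model):
        bundle = compact_bundle(compact_model, seed=2, include_dephos=True)
        path = tmp_path / "bundle.csv"
        save_datasets_csv(bundle, path)
        back = load_datasets_csv(path)
        assert [d.condition for d in back] == [d.condition for d in bundle]
        for a, b in zip(bundle, back):
            assert a.kinase == b.kinase and a.pka == b.pka
            pd.testing.assert_frame_equal(
                a.records[["site", "time", "value", "value_type"]],
                b.records[["site", "time", "value", "value_type"]],
                check_dtype=False)
        dep = next(d for d in back if d.is_dephosphorylation)
        assert dep.preincubation == {"kinase": "GSK3B", "pka": 0, "time": 240.0}
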
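"""Settler projection, extra-baseline probability, mixed-stock EM."""

import numpy as np
import pandas as pd
import pytest

import shellfingerprint as sf
from shellfingerprint.assignment import (extra_baseline_probability, fit_baseline,
                                         mle_mixture_proportions, project_settlers)
from shellfingerprint.io_preprocess import SignatureSet, log_transform
from shellfingerprint.synthetic import paper_like_region_specs
from conftest import two_region_specs


def _settler_sig(table):
    return sf.average_replicate_ablations(table)


@pytest.fixture(scope="module")
def brood_setup():
    specs = paper_like_region_specs(n_broods=(30, 30, 30))
    table = sf.generate_brood_dataset(specs, seed=42)
    sig = sf.average_replicate_ablations(table)
    sig_log = log_transform(sig)
    sig_z, params = sf.log_standardize(sig_log)
    model = sf.fit_lda(sig_z, "region", transform_params=params)
    return specs, sig_log, model


class TestProjection:
    def test_training_sample_lands_inside_its_region_ellipse(self, brood_setup):
        specs, sig_log, model = brood_setup
        # feed a brood back through the settler path
        raw = SignatureSet(np.exp(sig_log.values.iloc[[0]]),
                           sig_log.meta.iloc[[0]].copy(), "raw")
        rep = project_settlers(model, raw)
        region = sig_log.meta.iloc[0]["region"]
        assert bool(rep.inside_ellipse.iloc[0][region])

    def test_uses_frozen_brood_transform_only(self, brood_setup):
        specs, sig_log, model = brood_setup
        center_before = model.transform_params.center.copy()
        scen = sf.SettlerScenario({"CS": 1.0}, n_settlers=20, seed=8)
        settlers = _settler_sig(sf.generate_settler_dataset(specs, scen))
        rep = project_settlers(model, settlers)
        # projecting settlers must not refit the transform
        pd.testing.assert_series_equal(model.transform_params.center, center_before)
        assert set(rep.scores.to_frame().index) == set(settlers.values.index)
        assert not set(model.transform_params.fit_ids) & set(settlers.values.index)

    def test_outside_fraction_matches_heldout_brood_simulations(self, brood_setup):
        # settlers drawn from the brood generating model should be excluded
        # from all ellipses about as often as held-out broods are
        specs, _, model = brood_setup
        scen = sf.SettlerScenario({"CS": 1 / 3, "NS": 1 / 3, "Seq": 1 / 3},
                                  n_settlers=600, seed=3)
        settlers = _settler_sig(sf.generate_settler_dataset(specs, scen))
        rep = project_settlers(model, settlers)
        held = sf.generate_brood_dataset(
            [sf.RegionSpec(s.name, s.mean_log, s.cov_log, 200,
                           ablations_per_brood=1, ablation_noise_sd=0.0,
                           elements=s.elements) for s in specs], seed=99)
        held_sig = sf.average_replicate_ablations(held)
        rep_held = project_settlers(model, held_sig)
        se = np.sqrt(0.25 / 600 + 0.25 / 600)
        assert abs(rep.outside_all_fraction - rep_held.outside_all_fraction) < 4 * se + 0.02

    def test_posterior_rows_sum_to_one(self, brood_setup):
        specs, _, model = brood_setup
        scen = sf.SettlerScenario({"NS": 1.0}, n_settlers=15, seed=4)
        rep = project_settlers(model, _settler_sig(sf.generate_settler_dataset(specs, scen)))
        np.testing.assert_allclose(rep.lda_posteriors.sum(axis=1), 1.0, atol=1e-12)


class TestExtraBaseline:
    def test_settler_at_region_centroid_not_flagged(self, brood_setup):
        specs, sig_log, _ = brood_setup
        baseline = fit_baseline(sig_log, ["Mn", "Sr"])
        centroid = baseline.means[baseline.regions[0]]
        vals = pd.DataFrame([np.exp(centroid)], columns=["Mn", "Sr"],
                            index=["settler0"])
        meta = pd.DataFrame({"region": ["?"]}, index=vals.index)
        prob, flagged = extra_baseline_probability(
            baseline, SignatureSet(vals, meta, "raw"))
        assert prob.iloc[0] < 1e-6
        assert flagged == 0.0

    def test_calibration_on_baseline_draws(self, brood_setup):
        # settlers truly from the baseline regions should rarely be flagged:
        # flagged fraction <= (1 - level) + Monte-Carlo tolerance
        specs, sig_log, _ = brood_setup
        baseline = fit_baseline(sig_log, ["Mn", "Sr"])
        scen = sf.SettlerScenario({"CS": 1 / 3, "NS": 1 / 3, "Seq": 1 / 3},
                                  n_settlers=900, seed=12)
        settlers = _settler_sig(sf.generate_settler_dataset(specs, scen))
        _, flagged = extra_baseline_probability(baseline, log_transform(settlers))
        assert flagged <= 0.05 + 0.03

    def test_invariant_to_region_order(self, brood_setup):
        specs, sig_log, _ = brood_setup
        baseline = fit_baseline(sig_log, ["Mn", "Sr"])
        rev = type(baseline)(list(reversed(baseline.regions)), baseline.elements,
                             baseline.means, baseline.covs, baseline.n_per_region)
        scen = sf.SettlerScenario({"CS": 1.0}, n_settlers=25, seed=6)
        settlers = log_transform(_settler_sig(sf.generate_settler_dataset(specs, scen)))
        p1, f1 = extra_baseline_probability(baseline, settlers)
        p2, f2 = extra_baseline_probability(rev, settlers)
        np.testing.assert_allclose(p1, p2)
        assert f1 == f2

    def test_small_region_rejected(self, brood_setup):
        specs, sig_log, _ = brood_setup
        by_region = sig_log.meta.groupby("region").head(3).index
        tiny = sig_log.select_samples(list(by_region))
        with pytest.raises(ValueError, match="need >= 5|only"):
            fit_baseline(tiny, ["Mn", "Sr"])


class TestMixedStockEM:
    def test_proportions_sum_to_one(self, brood_setup):
        specs, sig_log, _ = brood_setup
        baseline = fit_baseline(sig_log, ["Mn", "Fe", "Sr"])
        scen = sf.SettlerScenario({"CS": 0.5, "NS": 0.5}, n_settlers=60, seed=2)
        settlers = log_transform(_settler_sig(sf.generate_settler_dataset(specs, scen)))
        mix = mle_mixture_proportions(baseline, settlers, n_boot=50, seed=1)
        assert mix.proportions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_source_recovered(self):
        specs = two_region_specs(p=2, delta=5.0, n=(40, 40))
        table = sf.generate_brood_dataset(specs, seed=11)
        sig_log = log_transform(sf.average_replicate_ablations(table))
        baseline = fit_baseline(sig_log, ["E0", "E1"])
        scen = sf.SettlerScenario({"A": 1.0}, n_settlers=100, seed=3)
        settlers = log_transform(_settler_sig(sf.generate_settler_dataset(specs, scen)))
        mix = mle_mixture_proportions(baseline, settlers, n_boot=50, seed=1)
        assert mix.proportions["A"] >= 0.95

    def test_loglik_monotone_nondecreasing(self, brood_setup):
        specs, sig_log, _ = brood_setup
        baseline = fit_baseline(sig_log, ["Mn", "Sr"])
        scen = sf.SettlerScenario({"CS": 0.4, "NS": 0.6}, n_settlers=80, seed=5)
        settlers = log_transform(_settler_sig(sf.generate_settler_dataset(specs, scen)))
        mix = mle_mixture_proportions(baseline, settlers, n_boot=10, seed=0)
        assert (np.diff(mix.loglik_trace) >= -1e-9).all()
        assert mix.converged

    def test_too_few_settlers_rejected(self, brood_setup):
        specs, sig_log, _ = brood_setup
        baseline = fit_baseline(sig_log, ["Mn", "Sr"])
        scen = sf.SettlerScenario({"CS": 1.0}, n_settlers=5, seed=5)
        settlers = log_transform(_settler_sig(sf.generate_settler_dataset(specs, scen)))
        with pytest.raises(ValueError, match="at least 10"):
            mle_mixture_proportions(baseline, settlers)
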
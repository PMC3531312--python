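"""4PL neutralization curves: formula, fitting, titers, caching, virtual sera."""

import dataclasses
import math

import numpy as np
import pytest

from vaxdss.bcell import (
    WIDE_BOUNDS,
    FitCache,
    SigmoidParams,
    VirtualSerumMap,
    align_virtual_sera,
    eval_4pl,
    fit_4pl,
    fit_group,
    series_points,
    titer_from_fit,
)
from vaxdss.core import Particle, TitrationPoint, VaxError, ValidationError
from vaxdss.synthgen import SynthConfig, synth_experiment

DILUTIONS = [20.0 * 3.0 ** k for k in range(8)]


def formula_oracle(top, bottom, slope, ec50, d):
    """Independently coded 4PL, written from the parameter definitions."""
    return bottom + (top - bottom) / (1.0 + (ec50 / d) ** slope)
    # note (ec50/d)**slope == 10**(slope*log10(ec50/d))


def make_points(top, bottom, slope, ec50, dilutions=DILUTIONS, noise=None, rng=None,
                serum="S1", day=14, particle=Particle.AG_PP):
    pts = []
    for d in dilutions:
        y = formula_oracle(top, bottom, slope, ec50, d)
        if noise:
            y += rng.normal(0.0, noise)
        pts.append(TitrationPoint(serum, day, d, particle, y))
    return pts


class TestEval4PL:
    def test_midpoint_at_ec50(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=250.0)
        assert eval_4pl(p, 250.0) == pytest.approx(50.0, abs=1e-12)

    def test_direct_substitution(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=100.0)
        assert eval_4pl(p, 10.0) == pytest.approx(100.0 / 11.0, abs=1e-12)

    def test_logistic_symmetry(self):
        p = SigmoidParams(top=80.0, bottom=5.0, hill_slope=1.7, ec50=300.0)
        for x in (0.3, 1.0, 2.4):
            left = eval_4pl(p, p.ec50 * 10 ** x)
            right = eval_4pl(p, p.ec50 / 10 ** x)
            assert left + right == pytest.approx(p.top + p.bottom, abs=1e-9)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(2000):
            top = rng.uniform(50, 110)
            bottom = rng.uniform(-10, 49)
            slope = rng.uniform(-5, 5)
            ec50 = 10 ** rng.uniform(0, 5)
            d = 10 ** rng.uniform(0, 5)
            p = SigmoidParams(top=top, bottom=bottom, hill_slope=slope, ec50=ec50)
            worst = max(worst, abs(eval_4pl(p, d) - formula_oracle(top, bottom, slope, ec50, d)))
        assert worst < 1e-12

    def test_nonpositive_dilution_rejected(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=100.0)
        with pytest.raises(VaxError):
            eval_4pl(p, 0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            SigmoidParams(top=10.0, bottom=20.0, hill_slope=1.0, ec50=100.0)
        with pytest.raises(ValidationError):
            SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=-5.0)


class TestFit4PL:
    def test_noiseless_recovery(self):
        truth = (100.0, 0.0, 1.2, 300.0)
        fit = fit_4pl(make_points(*truth))
        assert fit.converged
        for got, want in zip((fit.top, fit.hill_slope, fit.ec50), (100.0, 1.2, 300.0)):
            assert abs(got - want) <= 1e-6 * abs(want)
        assert abs(fit.bottom) <= 1e-4  # absolute scale: truth is 0

    def test_underdetermined_rejected(self):
        pts = make_points(100, 0, 1.2, 300, dilutions=[20.0, 60.0, 180.0])
        with pytest.raises(VaxError):
            fit_4pl(pts)
        # 4 points but only 3 distinct dilutions is still underdetermined
        pts = make_points(100, 0, 1.2, 300, dilutions=[20.0, 60.0, 180.0, 180.0])
        with pytest.raises(VaxError):
            fit_4pl(pts)

    def test_noisy_ec50_recovery(self):
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_4pl(make_points(100, 0, 1.2, 300, noise=2.0, rng=rng))
            errors.append(abs(fit.ec50 - 300.0) / 300.0)
        assert np.median(errors) < 0.15

    def test_negative_slope_recovered(self):
        fit = fit_4pl(make_points(100, 0, -1.2, 300))
        assert fit.hill_slope == pytest.approx(-1.2, rel=1e-5)
        assert fit.ec50 == pytest.approx(300.0, rel=1e-5)

    def test_flat_control_series_stays_flat(self, light_config):
        """Antigen-irrelevant control pseudoparticles are generated as flat
        noise; the fitted group curve's asymptote span stays small."""
        flat = 0
        for seed in range(40):
            b = synth_experiment(dataclasses.replace(light_config, seed=seed))
            pts = series_points(b.experiment.get_group("G-VAC1"), "S1", Particle.CTR_PP)
            fit = fit_4pl(pts, bounds=WIDE_BOUNDS)
            flat += (fit.top - fit.bottom) < 10.0
        assert flat >= 0.95 * 40


class TestTiter:
    def test_default_threshold_is_ec50(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.2, ec50=250.0)
        assert titer_from_fit(p) == 250.0

    def test_closed_form_inversion(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=100.0)
        threshold = 100.0 * 10.0 / 11.0  # value the curve takes at d = 1000
        assert titer_from_fit(p, threshold) == pytest.approx(1000.0, rel=1e-9)

    def test_threshold_at_asymptote_rejected(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=100.0)
        for bad in (100.0, 0.0, 120.0, -5.0):
            with pytest.raises(VaxError):
                titer_from_fit(p, bad)

    def test_unconverged_fit_rejected(self):
        p = SigmoidParams(top=100.0, bottom=0.0, hill_slope=1.0, ec50=100.0,
                          converged=False)
        with pytest.raises(VaxError):
            titer_from_fit(p)

    def test_roundtrip_through_eval(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            p = SigmoidParams(
                top=rng.uniform(60, 110), bottom=rng.uniform(-10, 40),
                hill_slope=rng.choice([-1, 1]) * rng.uniform(0.3, 4.0),
                ec50=10 ** rng.uniform(1, 4))
            t = rng.uniform(0.05, 0.95)
            threshold = p.bottom + t * (p.top - p.bottom)
            d = titer_from_fit(p, threshold)
            assert eval_4pl(p, d) == pytest.approx(threshold, abs=1e-9)


class TestGroupFits:
    def test_duplicated_individuals_same_optimum(self):
        pts = make_points(100, 0, 1.2, 300)
        single = fit_4pl(pts)
        doubled = fit_4pl(pts + pts)
        assert doubled.ec50 == pytest.approx(single.ec50, rel=1e-6)
        assert doubled.hill_slope == pytest.approx(single.hill_slope, rel=1e-6)

    def test_pooled_fit_beats_median_individual(self):
        """Pooling all individuals' points gives a lower median EC50 error
        than the median individual fit, over repeated noisy cohorts."""
        pooled_err, median_ind_err = [], []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            cohort = [make_points(100, 0, 1.2, 300, noise=4.0, rng=rng) for _ in range(5)]
            pooled = fit_4pl([p for pts in cohort for p in pts])
            pooled_err.append(abs(pooled.ec50 - 300) / 300)
            ind_errs = [abs(fit_4pl(pts).ec50 - 300) / 300 for pts in cohort]
            median_ind_err.append(float(np.median(ind_errs)))
        assert np.median(pooled_err) < np.median(median_ind_err)

    def test_experiment_scope_pools_across_groups(self, noiseless_bundle):
        exp = noiseless_bundle.experiment
        all_points = series_points(exp, "S1", Particle.AG_PP)
        per_group = [series_points(g, "S1", Particle.AG_PP) for g in exp.groups]
        assert len(all_points) == sum(len(p) for p in per_group)

    def test_cache_hit_on_unchanged_experiment(self, fresh_bundle):
        exp = fresh_bundle.experiment
        cache = FitCache()
        first = fit_group(exp, "S1", Particle.AG_PP, "G-VAC1", cache=cache)
        second = fit_group(exp, "S1", Particle.AG_PP, "G-VAC1", cache=cache)
        assert (cache.misses, cache.hits) == (1, 1)
        assert first is second  # no refit

    def test_cache_invalidated_by_revision(self, fresh_bundle):
        exp = fresh_bundle.experiment
        cache = FitCache()
        fit_group(exp, "S1", Particle.AG_PP, "G-VAC1", cache=cache)
        fresh_bundle.store.revise(exp, lambda e: None)
        fit_group(exp, "S1", Particle.AG_PP, "G-VAC1", cache=cache)
        assert cache.misses == 2


class TestVirtualSera:
    def _experiments(self):
        b1 = synth_experiment(SynthConfig(seed=31, experiment_id="E1",
                                          sera={"S2": 14}))
        b2 = synth_experiment(SynthConfig(seed=32, experiment_id="E2",
                                          sera={"S2": 15}))
        return b1.experiment, b2.experiment

    def test_alignment_across_days(self):
        e1, e2 = self._experiments()
        vs = VirtualSerumMap("VS1", [("E1", "G-VAC1", "S2", 14), ("E2", "G-VAC1", "S2", 15)])
        aligned = align_virtual_sera([vs], [e1, e2])
        assert set(aligned["VS1"]) == {("E1", "G-VAC1"), ("E2", "G-VAC1")}
        assert all(pts for pts in aligned["VS1"].values())

    def test_single_entry_warns_and_passes_through(self):
        e1, _ = self._experiments()
        vs = VirtualSerumMap("VS1", [("E1", "G-VAC1", "S2", 14)])
        with pytest.warns(UserWarning):
            aligned = align_virtual_sera([vs], [e1])
        assert len(aligned["VS1"]) == 1

    def test_duplicate_entry_rejected(self):
        with pytest.raises(ValidationError):
            VirtualSerumMap("VS1", [("E1", "G1", "S2", 14), ("E1", "G1", "S3", 21)])

    def test_absent_serum_rejected(self):
        e1, _ = self._experiments()
        vs = VirtualSerumMap("VS1", [("E1", "G-VAC1", "S9", 99), ("E1", "G-IS", "S2", 14)])
        with pytest.raises(VaxError):
            align_virtual_sera([vs], [e1])
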
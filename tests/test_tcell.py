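"""T-cell analysis: group summaries, naive normalization, IS ratios, radar area."""

import dataclasses
import math

import numpy as np
import pytest

from vaxdss.core import (
    Experiment,
    ExperimentalGroup,
    GroupType,
    Individual,
    TCellMeasurement,
    VaxError,
)
from vaxdss.synthgen import SynthConfig, synth_experiment
from vaxdss.tcell import (
    normalize_vs_naive,
    radar_area_score,
    ratio_vs_internal_standard,
    summarize_group,
)


def make_group(gid, gtype, values_by_individual, parameter="expansion_pct", day=7):
    """values_by_individual: list of lists (one per individual, None = missing day)."""
    individuals = []
    for k, vals in enumerate(values_by_individual):
        ind = Individual(id=f"{gid}-I{k}")
        for d, v in vals:
            if v is not None:
                ind.tcell.append(TCellMeasurement(day=d, **{parameter: v}))
        individuals.append(ind)
    return ExperimentalGroup(gid, gtype, "P1", individuals)


def make_experiment(groups):
    return Experiment("E1", "L1", "a", "2011-01-01", groups=groups)


class TestSummarizeGroup:
    def test_arithmetic_mean_and_count(self):
        g = make_group("G", GroupType.EXPERIMENTAL_VACCINE,
                       [[(7, 10.0)], [(7, 20.0)], [(7, 30.0)]])
        course = summarize_group(g, "expansion_pct")
        assert course.at_day(7) == (20.0, 10.0, 3)

    def test_missing_individual_excluded_from_count(self):
        g = make_group("G", GroupType.EXPERIMENTAL_VACCINE,
                       [[(7, 10.0)], [(7, 20.0)], [(7, None)]])
        mean, _sd, n = summarize_group(g, "expansion_pct").at_day(7)
        assert (mean, n) == (15.0, 2)

    def test_single_reporter_sd_zero(self):
        g = make_group("G", GroupType.EXPERIMENTAL_VACCINE, [[(7, 42.0)]])
        mean, sd, n = summarize_group(g, "expansion_pct").at_day(7)
        assert (mean, sd, n) == (42.0, 0.0, 1)

    def test_days_sorted(self):
        g = make_group("G", GroupType.EXPERIMENTAL_VACCINE,
                       [[(14, 5.0), (0, 1.0), (7, 3.0)]])
        assert summarize_group(g, "expansion_pct").days == [0, 7, 14]

    def test_no_data_raises(self):
        g = make_group("G", GroupType.EXPERIMENTAL_VACCINE, [[(7, 1.0)]])
        with pytest.raises(VaxError):
            summarize_group(g, "memory_pct")

    def test_mean_recovers_planted_effects(self, light_config):
        """Group-mean estimates land within 2*sd/sqrt(n) of the configured
        truth for roughly 95% of simulated groups."""
        hits = total = 0
        for seed in range(125):
            b = synth_experiment(dataclasses.replace(light_config, seed=seed))
            sd, n = b.truth.config.tcell_noise_sd, 5
            half_width = 2.0 * sd / math.sqrt(n)
            for spec in b.truth.config.groups:
                group = b.experiment.get_group(spec.group_id)
                for p in ("expansion_pct", "memory_pct"):
                    est = summarize_group(group, p).at_day(14)[0]
                    truth = b.truth.tcell_expected[spec.group_id][p][14]
                    # truncation to [0,100] can only help near the boundary
                    hits += abs(est - truth) <= half_width
                    total += 1
        assert 0.90 <= hits / total <= 0.995


class TestNormalizeVsNaive:
    def _experiment(self, group_mean, naive_mean):
        naive = make_group("GN", GroupType.NAIVE_CONTROL, [[(7, naive_mean)]])
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [[(7, group_mean)]])
        return make_experiment([naive, vac])

    def test_subtraction(self):
        out = {r.group_id: r for r in normalize_vs_naive(self._experiment(30.0, 10.0), 7)}
        assert out["GV"].values["expansion_pct"] == 20.0

    def test_naive_normalizes_to_zero(self):
        out = {r.group_id: r for r in normalize_vs_naive(self._experiment(30.0, 10.0), 7)}
        assert out["GN"].values["expansion_pct"] == 0.0

    def test_floored_at_zero(self):
        out = {r.group_id: r for r in normalize_vs_naive(self._experiment(5.0, 10.0), 7)}
        assert out["GV"].values["expansion_pct"] == 0.0

    def test_ratio_mode(self):
        out = {r.group_id: r
               for r in normalize_vs_naive(self._experiment(30.0, 10.0), 7, mode="ratio")}
        assert out["GV"].values["expansion_pct"] == pytest.approx(3.0)
        assert out["GN"].values["expansion_pct"] == pytest.approx(1.0)

    def test_translation_consistency(self):
        """Adding a constant to every individual leaves normalized values unchanged."""
        base = normalize_vs_naive(self._experiment(30.0, 10.0), 7)
        shifted = normalize_vs_naive(self._experiment(35.0, 15.0), 7)
        for a, b in zip(base, shifted):
            assert a.values == b.values

    def test_nearest_earlier_day_fallback(self):
        naive = make_group("GN", GroupType.NAIVE_CONTROL, [[(7, 10.0)]])
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [[(5, 25.0)]])
        out = {r.group_id: r for r in normalize_vs_naive(make_experiment([naive, vac]), 7)}
        assert out["GV"].values["expansion_pct"] == 15.0

    def test_missing_naive_group_raises(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [[(7, 25.0)]])
        with pytest.raises(VaxError):
            normalize_vs_naive(make_experiment([vac]), 7)

    def test_other_groups_excluded(self):
        naive = make_group("GN", GroupType.NAIVE_CONTROL, [[(7, 10.0)]])
        other = make_group("GO", GroupType.OTHER, [[(7, 50.0)]])
        out = normalize_vs_naive(make_experiment([naive, other]), 7)
        assert {r.group_id for r in out} == {"GN"}


class TestISRatio:
    def _experiment(self, vac_mean, is_mean, naive_mean=0.0):
        naive = make_group("GN", GroupType.NAIVE_CONTROL, [[(7, naive_mean)]])
        isg = make_group("GI", GroupType.INTERNAL_STANDARD, [[(7, is_mean)]])
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [[(7, vac_mean)]])
        return make_experiment([naive, isg, vac])

    def test_simple_ratio(self):
        exp = self._experiment(40.0, 20.0)
        out = ratio_vs_internal_standard([(exp, exp.get_group("GV"))],
                                         (exp, exp.get_group("GI")), 7)
        assert out[0].ratios["expansion_pct"] == pytest.approx(2.0)

    def test_is_self_ratio_is_one(self):
        exp = self._experiment(40.0, 20.0)
        out = ratio_vs_internal_standard([(exp, exp.get_group("GI"))],
                                         (exp, exp.get_group("GI")), 7)
        assert out[0].ratios["expansion_pct"] == pytest.approx(1.0)

    def test_zero_is_value_reported_missing(self):
        exp = self._experiment(40.0, 0.0)  # IS equals naive -> normalized 0
        out = ratio_vs_internal_standard([(exp, exp.get_group("GV"))],
                                         (exp, exp.get_group("GI")), 7)
        assert out[0].ratios["expansion_pct"] is None

    def test_non_standard_reference_rejected(self):
        exp = self._experiment(40.0, 20.0)
        with pytest.raises(VaxError):
            ratio_vs_internal_standard([(exp, exp.get_group("GV"))],
                                       (exp, exp.get_group("GN")), 7)

    def test_cross_experiment_requires_matching_protocol(self):
        exp1 = self._experiment(40.0, 20.0)
        naive = make_group("GN", GroupType.NAIVE_CONTROL, [[(7, 0.0)]])
        other_is = make_group("GI", GroupType.INTERNAL_STANDARD, [[(7, 10.0)]])
        other_is.immunization_protocol_id = "P-OTHER"
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [[(7, 30.0)]])
        exp2 = Experiment("E2", "L2", "b", "2011-02-01", groups=[naive, other_is, vac])
        with pytest.raises(VaxError):
            ratio_vs_internal_standard([(exp2, vac)], (exp1, exp1.get_group("GI")), 7)

    def test_scale_invariance(self):
        """Scaling every group's response offset by c > 0 leaves ratios unchanged."""
        base = self._experiment(40.0, 20.0)
        scaled = self._experiment(80.0, 40.0)
        r1 = ratio_vs_internal_standard([(base, base.get_group("GV"))],
                                        (base, base.get_group("GI")), 7)
        r2 = ratio_vs_internal_standard([(scaled, scaled.get_group("GV"))],
                                        (scaled, scaled.get_group("GI")), 7)
        assert r1[0].ratios == pytest.approx(r2[0].ratios)


class TestRadarArea:
    def test_square_closed_form(self):
        # K=4 equal radii r: area = 2 r^2
        for r in (1.0, 2.5):
            assert radar_area_score([r] * 4) == pytest.approx(2.0 * r * r)

    def test_zero_vector(self):
        assert radar_area_score([0.0, 0.0, 0.0, 0.0]) == 0.0

    def test_monotone_in_each_coordinate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.uniform(0, 5, size=4)
            base = radar_area_score(v)
            i = rng.integers(0, 4)
            v2 = v.copy()
            v2[i] += rng.uniform(0, 2)
            assert radar_area_score(v2) >= base - 1e-12

    def test_cyclic_rotation_invariance(self):
        rng = np.random.default_rng(1)
        v = list(rng.uniform(0, 5, size=5))
        base = radar_area_score(v)
        for shift in range(1, 5):
            assert radar_area_score(v[shift:] + v[:shift]) == pytest.approx(base)

    def test_matches_triangle_sum_oracle(self):
        """Independent oracle: sum of triangle areas (1/2)ab sin(angle)."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = int(rng.integers(3, 9))
            v = rng.uniform(0, 10, size=k)
            oracle = sum(
                0.5 * v[i] * v[(i + 1) % k] * math.sin(2 * math.pi / k) for i in range(k)
            )
            assert radar_area_score(v) == pytest.approx(oracle, rel=1e-12)

    def test_too_few_axes(self):
        with pytest.raises(VaxError):
            radar_area_score([1.0, 2.0])

    def test_missing_axis_dropped(self):
        # None drops the axis: remaining 3 axes scored as a triangle
        expected = radar_area_score([1.0, 2.0, 3.0])
        assert radar_area_score([1.0, None, 2.0, 3.0]) == pytest.approx(expected)
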
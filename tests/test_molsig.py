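"""Molecular signatures: ratio filtering, extraction, cross-experiment matrices."""

import dataclasses

import numpy as np
import pytest

from vaxdss.core import ExperimentalGroup, ExpressionProfile, GroupType, Individual, VaxError
from vaxdss.molsig import (
    GeneList,
    compare_expression,
    compare_experiment,
    cross_experiment_matrix,
    extract_signature,
)
from vaxdss.synthgen import SynthConfig, synth_experiment


def make_group(gid, gtype, profiles, organ="spleen", cell_type="dendritic", platform="Illumina"):
    """profiles: list of dicts gene -> value, one per individual."""
    individuals = []
    for k, values in enumerate(profiles):
        ind = Individual(id=f"{gid}-I{k}")
        ind.expression.append(ExpressionProfile(organ, cell_type, platform, dict(values)))
        individuals.append(ind)
    return ExperimentalGroup(gid, gtype, "P1", individuals)


class TestCompareExpression:
    def test_identical_groups_all_excluded(self):
        values = {"g1": 10.0, "g2": 20.0}
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [values])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [values])
        comp = compare_expression(vac, ctl, "spleen", "dendritic", 1.5)
        assert all(r == pytest.approx(1.0) for _, _, r in comp.genes.values())
        assert comp.excluded == {"g1", "g2"}

    def test_fold_change_retained(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"g1": 40.0}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [{"g1": 10.0}])
        comp = compare_expression(vac, ctl, "spleen", "dendritic", 2.0)
        assert comp.genes["g1"][2] == pytest.approx(4.0)
        assert "g1" not in comp.excluded

    def test_zero_control_mean_reported_separately(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"g1": 40.0, "g2": 5.0}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [{"g1": 0.0, "g2": 5.0}])
        comp = compare_expression(vac, ctl, "spleen", "dendritic", 2.0)
        assert comp.undefined_ratio == {"g1": (40.0, 0.0)}
        assert "g1" not in comp.genes and "g2" in comp.genes

    def test_swap_inverts_ratios_and_keeps_exclusions(self):
        rng = np.random.default_rng(5)
        values_v = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 100, 40))}
        values_c = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 100, 40))}
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [values_v])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [values_c])
        fwd = compare_expression(vac, ctl, "spleen", "dendritic", 2.0)
        rev = compare_expression(ctl, vac, "spleen", "dendritic", 2.0)
        for g in fwd.genes:
            assert rev.genes[g][2] == pytest.approx(1.0 / fwd.genes[g][2])
        assert fwd.excluded == rev.excluded

    def test_one_sided_mode(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"up": 40.0, "down": 2.5}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [{"up": 10.0, "down": 10.0}])
        comp = compare_expression(vac, ctl, "spleen", "dendritic", 2.0, two_sided=False)
        assert "down" in comp.excluded and "up" not in comp.excluded

    def test_mixed_platforms_rejected(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"g1": 1.0}], platform="Illumina")
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [{"g1": 1.0}], platform="Affymetrix")
        with pytest.raises(VaxError):
            compare_expression(vac, ctl, "spleen", "dendritic", 2.0)

    def test_threshold_below_one_rejected(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"g1": 1.0}])
        with pytest.raises(VaxError):
            compare_expression(vac, vac, "spleen", "dendritic", 0.5)

    def test_missing_profiles_rejected(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"g1": 1.0}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [{"g1": 1.0}], organ="liver")
        with pytest.raises(VaxError):
            compare_expression(vac, ctl, "spleen", "dendritic", 2.0)


class TestExtractSignature:
    def test_noiseless_planted_recovery(self):
        cfg = dataclasses.replace(SynthConfig(seed=40), ).noiseless()
        b = synth_experiment(cfg)
        comp = compare_experiment(b.experiment, "spleen", "dendritic", 2.0,
                                  vaccinated_group_id="G-VAC1")
        signature = {g for g, _ in extract_signature(comp)}
        assert signature == b.truth.planted_genes

    def test_noisy_recall(self):
        recalls = []
        for seed in range(30):
            b = synth_experiment(SynthConfig(seed=100 + seed))
            comp = compare_experiment(b.experiment, "spleen", "dendritic", 2.0,
                                      vaccinated_group_id="G-VAC1")
            found = {g for g, _ in extract_signature(comp)}
            recalls.append(len(found & b.truth.planted_genes) / len(b.truth.planted_genes))
        assert float(np.mean(recalls)) >= 0.9

    def test_ordering_and_tie_break(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE,
                         [{"a": 40.0, "b": 2.5, "c": 80.0}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL,
                         [{"a": 10.0, "b": 10.0, "c": 20.0}])
        comp = compare_expression(vac, ctl, "spleen", "dendritic", 2.0)
        sig = extract_signature(comp)
        # |log2| : a=2, b=2, c=2 -> all tied, ordered by gene id
        assert [g for g, _ in sig] == ["a", "b", "c"]
        assert sig[1][1] == pytest.approx(-2.0)

    def test_empty_retained_set(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [{"g1": 10.0}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [{"g1": 10.0}])
        comp = compare_expression(vac, ctl, "spleen", "dendritic", 2.0)
        assert extract_signature(comp) == []

    def test_superset_gene_list_never_drops_retained(self):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE,
                         [{"a": 40.0, "b": 30.0, "c": 5.0}])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL,
                         [{"a": 10.0, "b": 10.0, "c": 5.0}])
        small = GeneList("small", {"a"})
        big = GeneList("big", {"a", "b", "c", "d"})
        sig_small = {g for g, _ in extract_signature(
            compare_expression(vac, ctl, "spleen", "dendritic", 2.0, gene_list=small))}
        sig_big = {g for g, _ in extract_signature(
            compare_expression(vac, ctl, "spleen", "dendritic", 2.0, gene_list=big))}
        assert sig_small <= sig_big


class TestCrossExperimentMatrix:
    def _comp(self, genes_v, genes_c, threshold=2.0):
        vac = make_group("GV", GroupType.EXPERIMENTAL_VACCINE, [genes_v])
        ctl = make_group("GN", GroupType.NAIVE_CONTROL, [genes_c])
        return compare_expression(vac, ctl, "spleen", "dendritic", threshold)

    def test_single_experiment_equals_signature(self):
        comp = self._comp({"a": 40.0, "b": 10.0}, {"a": 10.0, "b": 10.0})
        matrix = cross_experiment_matrix({"E1": comp})
        assert list(matrix.columns) == ["E1"]
        assert dict(matrix["E1"].dropna()) == dict(extract_signature(comp))

    def test_disjoint_genes_leave_absent_cells(self):
        c1 = self._comp({"a": 40.0, "b": 10.0}, {"a": 10.0, "b": 10.0})
        c2 = self._comp({"a": 10.0, "b": 40.0}, {"a": 10.0, "b": 10.0})
        matrix = cross_experiment_matrix({"E1": c1, "E2": c2})
        assert np.isnan(matrix.loc["a", "E2"]) and np.isnan(matrix.loc["b", "E1"])
        assert matrix.loc["a", "E1"] == pytest.approx(2.0)

    def test_gene_list_restricts_rows(self):
        comp = self._comp({"a": 40.0, "b": 80.0}, {"a": 10.0, "b": 10.0})
        matrix = cross_experiment_matrix({"E1": comp}, gene_list=GeneList("gl", {"a", "z"}))
        assert set(matrix.index) <= {"a", "z"}

    def test_no_comparisons_rejected(self):
        with pytest.raises(VaxError):
            cross_experiment_matrix({})
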
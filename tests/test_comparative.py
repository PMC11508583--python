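import itertools

import numpy as np
import pandas as pd
import pytest

from mitocub import (
    GeneBiasMetrics,
    SpeciesRscuMatrix,
    SyntheticSpec,
    build_rscu_matrix,
    cluster_species,
    count_codons,
    gene_metrics,
    generate,
    paired_rscu_test,
    partition_codons,
    rscu,
    selection_summary,
)


def _matrix_from_rows(rows: dict[str, list[float]], codons: list[str]):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=codons)
    return SpeciesRscuMatrix(
        values=df, codon_amino_acids={c: "X" for c in codons}, mode="concatenated"
    )


@pytest.fixture(scope="module")
def small_panel(code5):
    spec = SyntheticSpec(seed=21, n_genes=3, codons_per_gene=400)
    return {
        label: generate(spec, species_label=label)[0]
        for label in ("sp_a", "sp_b")
    }


class TestBuildRscuMatrix:
    def test_single_species_single_gene_equals_gene_rscu(self, code5):
        recs, _ = generate(SyntheticSpec(seed=1, n_genes=1, codons_per_gene=200))
        mat = build_rscu_matrix({"sp": recs}, code5)
        vec = rscu(count_codons(recs[0], code5), code5)
        for c in mat.codons:
            expected = vec[c]
            got = mat.values.loc["sp", c]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_identical_species_identical_rows(self, code5):
        recs, _ = generate(SyntheticSpec(seed=2, n_genes=3, codons_per_gene=200))
        mat = build_rscu_matrix({"a": recs, "b": recs}, code5)
        pd.testing.assert_series_equal(
            mat.values.loc["a"], mat.values.loc["b"], check_names=False
        )

    def test_family_sum_invariant_concatenated(self, code5, small_panel):
        mat = build_rscu_matrix(small_panel, code5)
        for sp in mat.species:
            for fam in code5.families:
                vals = mat.values.loc[sp, list(fam.codons)]
                if vals.isna().all():
                    continue
                assert vals.sum() == pytest.approx(fam.degeneracy)

    def test_gene_averaged_mode(self, code5, small_panel):
        mat = build_rscu_matrix(small_panel, code5, mode="gene-averaged")
        assert mat.mode == "gene-averaged"
        assert set(mat.species) == set(small_panel)


class TestPartitionCodons:
    def test_uniform_matrix_has_empty_frequent_set(self):
        codons = ["AAA", "AAG", "CCC", "CCT"]
        mat = _matrix_from_rows(
            {"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0, 1.0]}, codons
        )
        part = partition_codons(mat)
        assert part.frequent == ()  # mean exactly 1 is not > 1
        assert set(part.infrequent) == set(codons)

    def test_partition_covers_all_codons_disjointly(self, code5, small_panel):
        mat = build_rscu_matrix(small_panel, code5)
        part = partition_codons(mat)
        assert len(part.frequent) + len(part.infrequent) == 62
        assert not set(part.frequent) & set(part.infrequent)

    def test_single_species_partitions_by_own_rscu(self):
        mat = _matrix_from_rows({"a": [1.5, 0.5, 1.2, 0.8]},
                                ["AAA", "AAG", "CCC", "CCT"])
        part = partition_codons(mat)
        assert set(part.frequent) == {"AAA", "CCC"}


class TestClusterSpecies:
    def test_two_species_single_merge(self, code5, small_panel):
        mat = build_rscu_matrix(small_panel, code5)
        tree = cluster_species(mat)
        assert tree.linkage_matrix.shape == (1, 4)
        assert set(tree.leaf_order) == set(mat.species)

    def test_identical_pair_merges_first(self):
        codons = [f"C{i}" for i in range(6)]
        rows = {
            "x": [1.0, 0.5, 1.5, 0.2, 1.8, 1.0],
            "y": [1.0, 0.5, 1.5, 0.2, 1.8, 1.0],
            "z": [0.1, 1.9, 0.4, 1.6, 0.3, 1.7],
        }
        tree = cluster_species(_matrix_from_rows(rows, codons))
        first = tree.linkage_matrix[0]
        assert first[2] == 0.0  # zero distance merge
        assert {int(first[0]), int(first[1])} == {0, 1}  # x and y

    def test_order_invariance_up_to_isomorphism(self, code5):
        spec = SyntheticSpec(seed=33, n_genes=2, codons_per_gene=300)
        panel = {
            f"s{i}": generate(
                SyntheticSpec(seed=33 + i, n_genes=2, codons_per_gene=300),
                species_label=f"s{i}",
            )[0]
            for i in range(4)
        }
        mat1 = build_rscu_matrix(panel, code5)
        mat2 = build_rscu_matrix(dict(reversed(list(panel.items()))), code5)
        t1 = cluster_species(mat1)
        t2 = cluster_species(mat2)
        assert np.allclose(
            sorted(t1.linkage_matrix[:, 2]), sorted(t2.linkage_matrix[:, 2])
        )

    def test_matches_brute_force_complete_linkage(self):
        # naive agglomerative complete linkage on 5 points
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 2, size=(5, 8))
        codons = [f"C{i}" for i in range(8)]
        rows = {f"s{i}": list(values[i]) for i in range(5)}
        tree = cluster_species(_matrix_from_rows(rows, codons))

        clusters = [{i} for i in range(5)]
        heights = []
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(range(len(clusters)), 2):
                d = max(
                    np.linalg.norm(values[i] - values[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            heights.append(d)
            merged = clusters[a] | clusters[b]
            clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
            clusters.append(merged)
        assert np.allclose(sorted(tree.linkage_matrix[:, 2]), sorted(heights))

    def test_duplicate_species_leaves_heights_unchanged(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 2, size=(4, 6))
        codons = [f"C{i}" for i in range(6)]
        rows = {f"s{i}": list(values[i]) for i in range(4)}
        base = cluster_species(_matrix_from_rows(rows, codons))
        rows_dup = dict(rows)
        rows_dup["s0_dup"] = list(values[0])
        dup = cluster_species(_matrix_from_rows(rows_dup, codons))
        base_heights = sorted(base.linkage_matrix[:, 2])
        dup_heights = sorted(dup.linkage_matrix[:, 2])
        assert dup_heights[0] == 0.0
        assert np.allclose(dup_heights[1:], base_heights)

    def test_single_species_rejected(self):
        mat = _matrix_from_rows({"only": [1.0, 1.0]}, ["AAA", "AAG"])
        with pytest.raises(ValueError):
            cluster_species(mat)


class TestPairedRscuTest:
    def test_species_against_itself(self, code5, small_panel):
        mat = build_rscu_matrix(small_panel, code5)
        r = paired_rscu_test(mat, "sp_a", "sp_a")
        assert r.t_statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_t_on_six_codon_fixture(self):
        codons = [f"C{i}" for i in range(6)]
        a = [1.2, 1.1, 1.3, 0.9, 1.2, 1.15]
        d = [0.2, 0.1, 0.3, -0.1, 0.2, 0.15]
        b = [ai - di for ai, di in zip(a, d)]
        mat = _matrix_from_rows({"a": a, "b": b}, codons)
        r = paired_rscu_test(mat, "a", "b")
        # textbook paired t: mean(d)/(sd(d)/sqrt(6)) with mean 0.85/6
        assert r.t_statistic == pytest.approx(2.557042, abs=1e-5)
        assert r.p_value == pytest.approx(0.050829, abs=1e-5)
        assert r.n_pairs == 6

    def test_antisymmetric_in_t(self, code5, small_panel):
        mat = build_rscu_matrix(small_panel, code5)
        fwd = paired_rscu_test(mat, "sp_a", "sp_b")
        rev = paired_rscu_test(mat, "sp_b", "sp_a")
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_constant_nonzero_differences_degenerate(self):
        codons = [f"C{i}" for i in range(4)]
        mat = _matrix_from_rows(
            {"a": [1.2, 0.9, 1.4, 0.6], "b": [1.0, 0.7, 1.2, 0.4]}, codons
        )
        r = paired_rscu_test(mat, "a", "b")
        assert r.t_statistic is None
        assert "zero-variance" in r.reason

    def test_missing_codons_dropped_pairwise(self):
        codons = [f"C{i}" for i in range(5)]
        mat = _matrix_from_rows(
            {"a": [1.0, np.nan, 1.5, 0.4, 1.2],
             "b": [0.9, 1.1, np.nan, 0.6, 1.0]},
            codons,
        )
        r = paired_rscu_test(mat, "a", "b")
        assert r.n_pairs == 3

    def test_too_few_pairs_reported_with_reason(self):
        mat = _matrix_from_rows(
            {"a": [1.0, np.nan], "b": [0.9, 1.1]}, ["C0", "C1"]
        )
        r = paired_rscu_test(mat, "a", "b")
        assert r.p_value is None
        assert "shared" in r.reason


class TestSelectionSummary:
    @staticmethod
    def _metric(species, gene, enc, selected):
        return GeneBiasMetrics(
            species_label=species, gene_name=gene, total_codons=300,
            rscu={}, gc3s=0.3, enc_obs=enc, enc_exp=40.0,
            enc_ratio=(40.0 - enc) / 40.0 if enc is not None else None,
            selected=selected,
        )

    def test_tallies_by_gene_and_species(self):
        metrics = [
            self._metric("s1", "ND1", 30.0, True),
            self._metric("s1", "ND2", 38.0, False),
            self._metric("s2", "ND1", 28.0, True),
            self._metric("s2", "ND2", 26.0, True),
        ]
        s = selection_summary(metrics)
        assert s.per_gene_selected == {"ND1": 2, "ND2": 1}
        assert s.per_species_selected == {"s1": 1, "s2": 2}
        assert s.per_gene_mean_enc["ND1"] == pytest.approx(29.0)
        assert s.per_species_mean_enc["s2"] == pytest.approx(27.0)

    def test_missing_enc_excluded(self):
        metrics = [
            self._metric("s1", "ATP8", None, None),
            self._metric("s1", "ND1", 30.0, True),
        ]
        s = selection_summary(metrics)
        assert "ATP8" not in s.per_gene_selected
        assert s.per_species_mean_enc["s1"] == pytest.approx(30.0)

    def test_no_selection_all_zero(self):
        metrics = [self._metric("s1", "ND1", 39.0, False)]
        s = selection_summary(metrics)
        assert s.per_gene_selected == {"ND1": 0}
        assert s.per_species_selected == {"s1": 0}
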
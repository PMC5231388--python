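"""LD neighborhoods and LD-weighted annotation scores against brute force."""

import numpy as np
import pandas as pd
import pytest

import evoenrich as ev
from evoenrich.ld import (DEFAULT_CATEGORIES, LDNeighborhood, compute_ld,
                          intergenic_flag, ld_weighted_score, raw_indicator,
                          total_ld)
from evoenrich.simulate import generate_panel, generate_tracks
import scipy.sparse as sp

from conftest import tiny_generator
from oracles import brute_force_intergenic, brute_force_ld_table


def _panel_from_dosages(dosages, positions, chroms=None):
    dosages = np.asarray(dosages, dtype=np.int16)
    m = dosages.shape[1]
    chroms = ["1"] * m if chroms is None else chroms
    variants = pd.DataFrame(
        {
            "snp_id": [f"v{i}" for i in range(m)],
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    return ev.ReferencePanel(variants=variants, dosages=dosages)


class TestComputeLD:
    def test_identical_columns_give_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        panel = _panel_from_dosages(np.column_stack([col, col]), [1000, 1500])
        nb = compute_ld(panel)
        assert nb.matrix[0, 1] == pytest.approx(1.0)
        assert nb.matrix[1, 0] == pytest.approx(1.0)

    def test_different_chromosomes_never_pair(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        panel = _panel_from_dosages(
            np.column_stack([col, col]), [1000, 1000], chroms=["1", "2"]
        )
        nb = compute_ld(panel)
        assert nb.matrix[0, 1] == 0.0
        assert nb.matrix[0, 0] == 1.0

    def test_window_excludes_distant_pairs(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        panel = _panel_from_dosages(np.column_stack([col, col]), [1, 2_000_002])
        nb = compute_ld(panel, window_bp=1_000_000)
        assert nb.matrix[0, 1] == 0.0

    def test_self_pair_exact_even_with_disabling_floor(self):
        rng = np.random.default_rng(0)
        panel = _panel_from_dosages(
            rng.integers(0, 3, size=(20, 5)), [100, 200, 300, 400, 500]
        )
        nb = compute_ld(panel, r2_floor=1.5)
        assert nb.matrix.nnz == 5
        np.testing.assert_array_equal(nb.matrix.diagonal(), np.ones(5))

    def test_neighborhood_matches_brute_force(self):
        panel = generate_panel(
            tiny_generator(seed=21, n_snps=50,
                           chrom_lengths={"1": 200_000})
        )
        nb = compute_ld(panel)
        _, _, neighbors = brute_force_ld_table(panel, {})
        got = nb.matrix.toarray()
        want = np.zeros_like(got)
        for i, d in enumerate(neighbors):
            for j, r2 in d.items():
                want[i, j] = r2
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_symmetry_of_tag_submatrix(self, small_scores):
        _, _, nbhd = small_scores
        S = nbhd.tag_submatrix()
        assert abs(S - S.T).max() < 1e-10


class TestScores:
    def test_isolated_in_region_snp_scores_one(self):
        """An isolated SNP inside a salient region scores exactly 1."""
        rng = np.random.default_rng(1)
        panel = _panel_from_dosages(
            rng.integers(0, 3, size=(40, 3)), [100, 5_000_000, 9_999_000]
        )
        nb = compute_ld(panel, window_bp=1_000_000)
        delta = np.array([1.0, 1.0, 0.0])
        scores = ld_weighted_score(nb, delta)
        assert scores[0] == 1.0 and scores[1] == 1.0 and scores[2] == 0.0
        np.testing.assert_array_equal(total_ld(nb), [1.0, 1.0, 1.0])

    def test_direct_summation_example(self):
        """Out-of-region SNP with in-region partners at r2 {0.5, 0.3, 0.19}
        scores 0.8 (the 0.19 partner falls below the floor)."""
        matrix = sp.csr_matrix(
            np.array([[1.0, 0.5, 0.3, 0.0]])  # 0.19 already floored away
        )
        nb = LDNeighborhood(matrix=matrix, tag_idx=np.array([0]),
                            window_bp=1_000_000, r2_floor=0.2)
        delta = np.array([0.0, 1.0, 1.0, 1.0])
        assert ld_weighted_score(nb, delta)[0] == pytest.approx(0.8)
        assert total_ld(nb)[0] == pytest.approx(1.8)

    def test_totld_partner_sum(self):
        matrix = sp.csr_matrix(np.array([[1.0, 0.5, 0.25]]))
        nb = LDNeighborhood(matrix=matrix, tag_idx=np.array([0]),
                            window_bp=1_000_000, r2_floor=0.2)
        assert total_ld(nb)[0] == pytest.approx(1.75)

    def test_raw_indicator_boundaries_and_union(self):
        rng = np.random.default_rng(2)
        panel = _panel_from_dosages(
            rng.integers(0, 3, size=(20, 3)), [100, 150, 250]
        )
        track = ev.AnnotationTrack("t", [("1", 100, 200), ("1", 120, 200)])
        # pos 100 is outside [100,200) under 1-based convention; overlap
        # does not double-count
        np.testing.assert_array_equal(raw_indicator(panel, track), [0, 1, 0])

    def test_score_columns_match_brute_force_with_tracks(self):
        cfg = tiny_generator(seed=33, n_snps=250,
                             chrom_lengths={"1": 1_200_000, "6": 1_200_000})
        panel = generate_panel(cfg)
        tracks = generate_tracks(cfg)
        idx_df = panel.variants.assign(panel_idx=np.arange(panel.n_variants),
                                       z=0.0, p=1.0, n=1, maf=panel.maf())
        index = ev.AlignedIndex(df=idx_df)
        table, nbhd = ev.build_score_table(panel, index, tracks)
        cats = [c for c in DEFAULT_CATEGORIES if c in tracks]
        deltas = {c: raw_indicator(panel, tracks[c]) for c in cats}
        scores, tot, neighbors = brute_force_ld_table(panel, deltas)
        for c in cats:
            np.testing.assert_allclose(
                table[f"ld_{c}"], scores[c], rtol=1e-10, atol=1e-12,
                err_msg=f"category {c}",
            )
        np.testing.assert_allclose(table["tot_ld"], tot, rtol=1e-10)
        want_flag = brute_force_intergenic(panel, neighbors, table, tracks)
        np.testing.assert_array_equal(table["intergenic"], want_flag)

    def test_tot_ld_dominates_every_category(self, small_scores):
        _, table, _ = small_scores
        for col in [c for c in table.columns if c.startswith("ld_")]:
            assert (table["tot_ld"] - table[col] >= -1e-10).all()
        assert (table["tot_ld"] >= 1.0).all()
        for c in [c[4:] for c in table.columns if c.startswith("raw_")]:
            assert (table[f"ld_{c}"] >= table[f"raw_{c}"] - 1e-12).all()

    def test_floor_above_one_reduces_scores_to_raw(self):
        cfg = tiny_generator(seed=5, n_snps=120, chrom_lengths={"1": 600_000})
        panel = generate_panel(cfg)
        tracks = generate_tracks(cfg)
        idx = ev.AlignedIndex(df=panel.variants.assign(
            panel_idx=np.arange(panel.n_variants), z=0.0, p=1.0, n=1,
            maf=panel.maf()))
        table, _ = ev.build_score_table(panel, idx, tracks, r2_floor=1.0 + 1e-9)
        np.testing.assert_array_equal(table["tot_ld"], np.ones(len(table)))
        for c in [c[4:] for c in table.columns if c.startswith("raw_")]:
            np.testing.assert_array_equal(table[f"ld_{c}"], table[f"raw_{c}"])

    def test_track_enlargement_is_monotone(self):
        cfg = tiny_generator(seed=6, n_snps=150, chrom_lengths={"1": 800_000})
        panel = generate_panel(cfg)
        nb = compute_ld(panel)
        track = ev.AnnotationTrack("t", [("1", 100_000, 150_000)])
        bigger = ev.AnnotationTrack("t", [("1", 80_000, 200_000)])
        s1 = ld_weighted_score(nb, raw_indicator(panel, track))
        s2 = ld_weighted_score(nb, raw_indicator(panel, bigger))
        assert (s2 - s1 >= -1e-12).all()

    def test_sample_permutation_invariance(self):
        cfg = tiny_generator(seed=7, n_snps=100, chrom_lengths={"1": 500_000})
        panel = generate_panel(cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_samples)
        shuffled = ev.ReferencePanel(variants=panel.variants,
                                     dosages=panel.dosages[perm])
        a = compute_ld(panel).matrix.toarray()
        b = compute_ld(shuffled).matrix.toarray()
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-12)


class TestIntergenic:
    def _simple_setup(self):
        """3 SNPs: gene-proximal, far-isolated, gene-adjacent-by-LD only."""
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0, 2, 1])
        rng = np.random.default_rng(3)
        other = rng.integers(0, 3, size=(10, 1)).ravel()
        dosages = np.column_stack([col, other, col])
        panel = _panel_from_dosages(dosages, [50_000, 600_000, 190_000])
        tracks = {
            "protein_coding_gene": ev.AnnotationTrack("g", [("1", 1_000, 10_000)]),
            "exon": ev.AnnotationTrack("exon", [("1", 2_000, 2_200)]),
            "intron": ev.AnnotationTrack("intron", [("1", 2_200, 9_000)]),
            "utr5": ev.AnnotationTrack("utr5", [("1", 1_000, 2_000)]),
            "utr3": ev.AnnotationTrack("utr3", [("1", 9_000, 10_000)]),
        }
        return panel, tracks

    def test_rule_cases(self):
        panel, tracks = self._simple_setup()
        idx = ev.AlignedIndex(df=panel.variants.assign(
            panel_idx=np.arange(3), z=0.0, p=1.0, n=1, maf=panel.maf()))
        table, _ = ev.build_score_table(
            panel, idx, tracks, categories=("exon", "intron", "utr5", "utr3")
        )
        ld_cols = [c for c in table.columns if c.startswith("ld_")]
        # SNP0: genic scores all 0 but it sits 40 kb from the gene itself
        assert table[ld_cols].iloc[0].sum() == 0
        assert table["intergenic"][0] == np.False_
        # SNP1 is isolated and far beyond the 100 kb flank: intergenic
        assert table["intergenic"][1] == np.True_
        # SNP2: genic scores 0 and 180 kb from the gene, but its r2=1
        # partner SNP0 lies within the 100 kb flank: not intergenic
        assert table[ld_cols].iloc[2].sum() == 0
        assert table["intergenic"][2] == np.False_

    def test_missing_gene_track_raises(self, small_scores):
        idx, table, nbhd = small_scores
        with pytest.raises(KeyError):
            intergenic_flag(nbhd, None, table, {})
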
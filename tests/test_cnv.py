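"""ΔCNV, locus counting, shared-loss Fisher tests, Mann-Whitney engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphodyn import simulate
from phosphodyn.cnv import (
    CNVProfile,
    compare_group_counts,
    count_cnv_loci,
    delta_cnv,
    gene_cn_vs_auc,
    loss_matrix,
    shared_loss_test,
)

from _oracles import fisher_enum_p, mwu_perm_p


def profile(cell_line, segs):
    return CNVProfile(
        cell_line=cell_line,
        segments=pd.DataFrame(segs, columns=["chrom", "start", "end", "copy_number"]),
    )


class TestDeltaCNV:
    def test_identical_profiles_all_zero(self):
        p = profile("a", [("chr1", 1, 100, 2), ("chr1", 101, 200, 3)])
        d = delta_cnv(p, profile("b", [("chr1", 1, 100, 2), ("chr1", 101, 200, 3)]))
        assert (d.segments["delta"] == 0).all()

    def test_single_loss_segment(self):
        parental = profile("p", [("chr1", 1, 300, 2)])
        resistant = profile("r", [("chr1", 1, 99, 2), ("chr1", 100, 200, 1), ("chr1", 201, 300, 2)])
        d = delta_cnv(resistant, parental)
        in_region = d.segments[(d.segments["start"] >= 100) & (d.segments["end"] <= 200)]
        out_region = d.segments.drop(in_region.index)
        assert (in_region["delta"] == -1).all()
        assert (out_region["delta"] == 0).all()
        assert d.min_segment["start"] == 100 and d.min_segment["end"] == 200

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)

        def random_profile(name):
            cuts = np.sort(rng.choice(np.arange(2, 500), size=4, replace=False))
            bounds = [1, *cuts, 500]
            segs = [
                ("chr1", lo, hi - 1, int(rng.integers(0, 5)))
                for lo, hi in zip(bounds[:-1], bounds[1:])
            ]
            return profile(name, segs)

        a, b = random_profile("a"), random_profile("b")
        d_ab = delta_cnv(a, b).segments
        d_ba = delta_cnv(b, a).segments
        pd.testing.assert_frame_equal(
            d_ab.assign(delta=-d_ab["delta"]), d_ba
        )

    def test_missing_chromosome_imputed_diploid_with_warning(self):
        a = profile("a", [("chr1", 1, 100, 2), ("chr2", 1, 100, 4)])
        b = profile("b", [("chr1", 1, 100, 2)])
        with pytest.warns(UserWarning, match="chr2"):
            d = delta_cnv(a, b)
        chr2 = d.segments[d.segments["chrom"] == "chr2"]
        assert (chr2["delta"] == 2).all()

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            profile("a", [("chr1", 1, 100, 2), ("chr1", 50, 150, 1)])


class TestCountLoci:
    def test_all_diploid_counts_zero(self):
        p = profile("a", [("chr1", 1, 1000, 2)])
        assert count_cnv_loci(p) == (0, 0)

    def test_adjacent_losses_merge(self):
        # copies {2, 1, 1(adjacent), 3, 0}: the two adjacent 1s merge -> (2, 1)
        p = profile(
            "a",
            [
                ("chr1", 1, 100, 2),
                ("chr1", 101, 200, 1),
                ("chr1", 201, 300, 1),
                ("chr1", 301, 400, 3),
                ("chr1", 401, 500, 0),
            ],
        )
        assert count_cnv_loci(p) == (2, 1)

    def test_invariant_under_equal_copy_split(self):
        whole = profile("a", [("chr1", 1, 200, 1), ("chr1", 201, 300, 3)])
        split = profile(
            "a",
            [
                ("chr1", 1, 120, 1),
                ("chr1", 121, 200, 1),
                ("chr1", 201, 250, 3),
                ("chr1", 251, 300, 3),
            ],
        )
        assert count_cnv_loci(whole) == count_cnv_loci(split)

    def test_non_adjacent_same_kind_counted_separately(self):
        p = profile(
            "a",
            [("chr1", 1, 100, 1), ("chr1", 101, 200, 2), ("chr1", 201, 300, 0)],
        )
        assert count_cnv_loci(p) == (2, 0)

    def test_planted_counts_recovered_from_generator(self):
        profiles, gt = simulate.gen_cnv_profiles(
            4, 200, (50, 70, "A"), ["A", "A", "B", "B"], seed=3, background_rate=0.0
        )
        for prof, label in zip(profiles, ["A", "A", "B", "B"]):
            assert count_cnv_loci(prof) == ((1, 0) if label == "A" else (0, 0))


class TestSharedLoss:
    def test_perfect_split_fisher_p(self):
        # loss in all 5 of group A, none of 3 in group B: p = 1/C(8,5)
        loss = pd.DataFrame(
            {f"L{i}": [1 if i < 5 else 0] for i in range(8)}, index=["g1"]
        )
        groups = {f"L{i}": ("A" if i < 5 else "B") for i in range(8)}
        p = shared_loss_test(loss, groups)["g1"]
        assert p == pytest.approx(1 / 56, rel=1e-9)
        assert p == pytest.approx(0.0179, abs=2e-4)

    def test_proportional_loss_gives_p_one(self):
        loss = pd.DataFrame(
            {"L1": [1], "L2": [0], "L3": [1], "L4": [0]}, index=["g1"]
        )
        groups = {"L1": "A", "L2": "A", "L3": "B", "L4": "B"}
        assert shared_loss_test(loss, groups)["g1"] == 1.0

    def test_only_planted_genes_reach_minimum_p(self):
        labels = ["A"] * 5 + ["B"] * 3
        profiles, gt = simulate.gen_cnv_profiles(
            8, 100, (40, 49, "A"), labels, seed=1, background_rate=0.0, bin_size=1000
        )
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "chrom": "chr4",
                "start": np.arange(10) * 10000 + 1,
                "end": (np.arange(10) + 1) * 10000,
            }
        )
        loss = loss_matrix(profiles, genes)
        groups = dict(zip([p.cell_line for p in profiles], labels))
        ps = shared_loss_test(loss, groups)
        planted = {"g4"}  # bins 40-49 = positions 40001-50000
        assert set(ps[ps == ps.min()].index) == planted
        assert (ps.drop("g4") == 1.0).all()


class TestMannWhitney:
    def test_complete_separation_example(self):
        # U = 0; two-sided exact p = 2/20
        assert compare_group_counts([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        assert compare_group_counts([3, 1, 4], [3, 1, 4]) == 1.0

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=4),
        st.lists(st.integers(0, 5), min_size=2, max_size=4),
    )
    @settings(max_examples=120, deadline=None)
    def test_exact_path_matches_permutation_oracle(self, a, b):
        assert compare_group_counts(a, b) == pytest.approx(
            mwu_perm_p(a, b), abs=1e-9
        )

    def test_large_sample_path_is_reasonable(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(5, size=40)
        b = rng.poisson(9, size=40)
        assert compare_group_counts(a, b) < 1e-4
        null = compare_group_counts(a, rng.permutation(a))
        assert null > 0.05

    def test_threefold_loss_burden_recovered(self):
        """Planted 3x loss-rate contrast survives locus counting."""
        labels = ["S"] * 5 + ["R"] * 5
        rng_rates = {"S": 0.012, "R": 0.004}
        profiles = []
        for i, lab in enumerate(labels):
            prof, _ = simulate.gen_cnv_profiles(
                1, 20000, (0, 0, "nobody"), ["x"], seed=50 + i,
                background_rate=rng_rates[lab],
            )
            profiles.append(prof[0])
        counts = np.array([count_cnv_loci(p)[0] for p in profiles], dtype=float)
        ratio = counts[:5].mean() / counts[5:].mean()
        assert ratio == pytest.approx(3.0, rel=0.2)


class TestGeneCnVsAuc:
    def test_linear_relation_r_one(self):
        cn = np.array([1.0, 2.0, 3.0, 4.0])
        assert gene_cn_vs_auc(cn, 0.1 * cn + 0.2)[0] == pytest.approx(1.0)

    def test_constant_copy_number_rejected(self):
        with pytest.raises(ValueError):
            gene_cn_vs_auc([2, 2, 2], [0.1, 0.5, 0.9])

    def test_planted_negative_relation_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            cn = rng.uniform(0, 4, size=20)
            auc = 2.0 - 0.5 * cn + rng.normal(0, 0.1, size=20)
            r, _ = gene_cn_vs_auc(cn, auc)
            hits += r < -0.8
        assert hits >= 18
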
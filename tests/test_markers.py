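"""Variant filtering, densities/gaps, map anchoring, diversity, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbs3d.markers import (
    DiversityStats,
    FilterConfig,
    VariantRecord,
    assign_genetic_positions,
    count_polymorphic_pair,
    density_and_gaps,
    diversity_stats,
    filter_variants,
    genetic_density_and_gaps,
    ibs_distance_matrix,
)

from _oracles import brute_force_gaps, brute_force_nearest


def rec(chrom="chr1", pos=100, ref="A", alts=("T",), qual=50.0, mq=40.0, gts=None):
    if gts is None:
        gts = [(0, 0), (0, 1), (1, 1), (0, 0), (0, 0)]
    return VariantRecord(chrom, pos, ref, tuple(alts), qual, mq,
                         np.array(gts, dtype=np.int16))


class TestFilterVariants:
    def test_clean_snp_retained(self):
        # biallelic SNP, QUAL 50 / MQ 40, 20% missing, 5% het among called
        gts = [(-1, -1)] * 5 + [(0, 1)] + [(0, 0)] * 19
        retained, reasons = filter_variants([rec(gts=gts)])
        assert reasons == ["pass"] and len(retained) == 1

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(qual=5.0), "low_qual"),
            (dict(mq=20.0), "low_mq"),
            (dict(qual=None), "low_qual"),
            (dict(mq=None), "low_mq"),
            (dict(chrom="scaffold_12"), "scaffold"),
            (dict(ref="AT"), "indel"),
            (dict(alts=("T", "G")), "multiallelic"),
        ],
    )
    def test_single_rule_failures(self, kwargs, reason):
        r = rec(gts=[(0, 0)] * 20, **kwargs)
        retained, reasons = filter_variants([r])
        assert retained == [] and reasons == [reason]

    def test_missing_and_het_thresholds_are_strict(self):
        # missing rate exactly 0.8 fails (retention needs < 0.8)
        gts = [(-1, -1)] * 8 + [(0, 0)] * 2
        _, reasons = filter_variants([rec(gts=gts)])
        assert reasons == ["missing"]
        gts = [(-1, -1)] * 7 + [(0, 0)] * 3
        _, reasons = filter_variants([rec(gts=gts)])
        assert reasons == ["pass"]
        # het rate exactly 0.1 fails
        gts = [(0, 1)] + [(0, 0)] * 9
        _, reasons = filter_variants([rec(gts=gts)])
        assert reasons == ["het"]

    def test_first_failing_rule_reported(self):
        r = rec(qual=1.0, mq=1.0, chrom="scaffold_1", ref="AT")
        _, reasons = filter_variants([r])
        assert reasons == ["low_qual"]

    def test_conjunctive_qual_mq_mode(self):
        cfg = FilterConfig(qual_mq_mode="both")
        ok_one_bad = rec(qual=5.0, mq=40.0, gts=[(0, 0)] * 20)
        both_bad = rec(qual=5.0, mq=5.0, gts=[(0, 0)] * 20)
        _, reasons = filter_variants([ok_one_bad, both_bad], cfg)
        assert reasons == ["pass", "low_qual_mq"]

    def test_allowed_chromosomes_whitelist(self):
        cfg = FilterConfig(allowed_chromosomes=frozenset({"chr1"}))
        _, reasons = filter_variants(
            [rec(chrom="chr1", gts=[(0, 0)] * 20), rec(chrom="chr2", gts=[(0, 0)] * 20)],
            cfg,
        )
        assert reasons == ["pass", "scaffold"]

    @given(st.floats(0.05, 0.95), st.floats(0.01, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_tightening_thresholds_gives_subset(self, max_missing, max_het):
        rng = np.random.default_rng(0)
        records = []
        for i in range(60):
            gts = []
            for _ in range(10):
                x = rng.random()
                if x < 0.3:
                    gts.append((-1, -1))
                elif x < 0.5:
                    gts.append((0, 1))
                else:
                    gts.append((0, 0))
            records.append(rec(pos=i + 1, gts=gts))
        loose = FilterConfig(max_missing_rate=max_missing, max_het_rate=max_het)
        tight = FilterConfig(max_missing_rate=max_missing / 2, max_het_rate=max_het / 2)
        keep_loose = {r.pos for r in filter_variants(records, loose)[0]}
        keep_tight = {r.pos for r in filter_variants(records, tight)[0]}
        assert keep_tight <= keep_loose


class TestDensityAndGaps:
    def test_two_marker_gap_example(self):
        rep = density_and_gaps({"chr1": [100, 11_000_100]}, {"chr1": 12_000_000})
        assert rep.gap_count(5e6) == 1
        assert rep.gap_count(10e6) == 1
        assert rep.gap_reports[10e6].gaps[0][3] == pytest.approx(11.0e6)

    def test_single_marker_no_gaps(self):
        rep = density_and_gaps({"chr1": [500]}, {"chr1": 1_000_000})
        assert rep.gap_count(5e6) == 0 and rep.gap_count(10e6) == 0

    def test_density_definition(self):
        rep = density_and_gaps(
            {"chr1": [1, 2, 3], "chr2": [10]}, {"chr1": 1_000_000, "chr2": 1_000_000}
        )
        assert rep.density == pytest.approx(4 / 2.0)  # markers per Mb

    def test_include_ends_counts_terminal_gaps(self):
        rep = density_and_gaps(
            {"chr1": [6_000_000]}, {"chr1": 12_000_000},
            thresholds=(5e6,), include_ends=True,
        )
        assert rep.gap_count(5e6) == 2

    def test_random_markers_match_brute_force(self):
        rng = np.random.default_rng(77)
        pos = np.sort(rng.choice(50_000_000, size=200, replace=False))
        rep = density_and_gaps({"chr1": pos.tolist()}, {"chr1": 50_000_000},
                               thresholds=(100_000, 250_000, 500_000))
        for thr in (100_000, 250_000, 500_000):
            assert rep.gap_count(thr) == brute_force_gaps(pos, thr)

    def test_marker_beyond_length_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            density_and_gaps({"chr1": [2_000_001]}, {"chr1": 2_000_000})

    def test_genetic_gaps(self):
        rep = genetic_density_and_gaps({"chr1": [0.0, 25.0]}, {"chr1": 100.0})
        assert rep.gap_count(10.0) == 1 and rep.gap_count(20.0) == 1
        even = genetic_density_and_gaps(
            {"chr1": list(np.arange(0, 101, 5.0))}, {"chr1": 100.0}
        )
        assert even.gap_count(10.0) == 0 and even.gap_count(20.0) == 0
        assert even.density == pytest.approx(21 / 100.0)


class TestAssignGeneticPositions:
    CMAP = pd.DataFrame(
        {
            "marker_id": ["m1", "m2"],
            "chrom": ["chr1", "chr1"],
            "pos_bp": [1000, 2000],
            "pos_cM": [0.0, 5.0],
        }
    )

    @pytest.mark.parametrize(
        "query,expected", [(1400, 0.0), (1600, 5.0), (1500, 0.0), (10, 0.0), (9000, 5.0)]
    )
    def test_nearest_anchor_with_tie_rule(self, query, expected):
        out = assign_genetic_positions({"chr1": [query]}, self.CMAP)
        assert out["pos_cM"].iloc[0] == expected
        assert out["placed"].iloc[0]

    def test_unmapped_chromosome_flagged(self):
        out = assign_genetic_positions({"chrX": [5]}, self.CMAP)
        assert not out["placed"].iloc[0]
        assert np.isnan(out["pos_cM"].iloc[0])

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(5)
        bp = np.sort(rng.choice(1_000_000, size=40, replace=False))
        cm = np.sort(rng.random(40) * 120)
        cmap = pd.DataFrame(
            {"marker_id": [f"m{i}" for i in range(40)], "chrom": "chr1",
             "pos_bp": bp, "pos_cM": cm}
        )
        queries = rng.choice(1_000_000, size=300).tolist()
        out = assign_genetic_positions({"chr1": queries}, cmap)
        for q, got in zip(queries, out["pos_cM"]):
            assert got == brute_force_nearest(bp, cm, q)


class TestDiversityStats:
    def test_all_homozygous_reference(self):
        records = [rec(pos=p, gts=[(0, 0)] * 4) for p in (1, 2, 3)]
        d = diversity_stats(records)
        assert d.het_rate == 0.0 and d.mean_maf == 0.0 and d.mean_pi == 0.0
        assert d.missing_rate == 0.0

    def test_two_sample_closed_form(self):
        d = diversity_stats([rec(gts=[(0, 0), (1, 1)])])
        # p = 0.5, n = 4 alleles: pi = 2 * 0.25 * 4/3 = 2/3
        assert d.mean_maf == pytest.approx(0.5)
        assert d.mean_pi == pytest.approx(2 / 3)
        assert d.het_rate == 0.0

    def test_missing_counted_but_skipped_for_maf(self):
        records = [
            rec(pos=1, gts=[(-1, -1), (-1, -1)]),
            rec(pos=2, gts=[(0, 0), (1, 1)]),
        ]
        d = diversity_stats(records)
        assert d.missing_rate == pytest.approx(0.5)
        assert d.n_sites_skipped == 1
        assert d.mean_maf == pytest.approx(0.5)

    def test_generator_maf_recovered(self):
        rng = np.random.default_rng(8)
        true_maf = 0.3
        records = []
        for p in range(1, 400):
            gts = [
                tuple(rng.choice(2, size=2, p=[1 - true_maf, true_maf]))
                for _ in range(30)
            ]
            records.append(rec(pos=p, gts=gts))
        d = diversity_stats(records)
        assert d.mean_maf == pytest.approx(true_maf, abs=0.02)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            diversity_stats([rec(gts=[(0, 0)])])


class TestIbsDistance:
    SAMPLES = ["a", "b", "c"]

    def test_identical_zero_distance(self):
        records = [rec(pos=p, gts=[(0, 1), (0, 1), (0, 0)]) for p in (1, 2)]
        mat = ibs_distance_matrix(records, self.SAMPLES)
        assert mat.loc["a", "b"] == 0.0
        assert np.allclose(np.diag(mat), 0.0)

    def test_shared_allele_arithmetic(self):
        # a=AA, b=TT -> 0 shared; a=AA, c=AT -> 1 shared of 2
        records = [rec(gts=[(0, 0), (1, 1), (0, 1)])]
        mat = ibs_distance_matrix(records, self.SAMPLES)
        assert mat.loc["a", "b"] == 1.0
        assert mat.loc["a", "c"] == 0.5
        assert mat.loc["b", "c"] == 0.5

    def test_undefined_pair_is_nan(self):
        records = [rec(gts=[(0, 0), (-1, -1), (0, 0)])]
        mat = ibs_distance_matrix(records, self.SAMPLES)
        assert np.isnan(mat.loc["a", "b"])
        assert mat.loc["a", "c"] == 0.0

    def test_pseudometric_on_random_genotypes(self):
        rng = np.random.default_rng(13)
        samples = [f"s{i}" for i in range(6)]
        records = [
            rec(pos=p, gts=[tuple(rng.integers(0, 2, 2)) for _ in samples])
            for p in range(1, 120)
        ]
        mat = ibs_distance_matrix(records, samples).to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-12


class TestPolymorphicPairs:
    def test_identical_samples_zero(self):
        records = [rec(pos=p, gts=[(0, 1), (0, 1)]) for p in (1, 2, 3)]
        out = count_polymorphic_pair(records, ["a", "b"], "a", "b")
        assert out["polymorphic_count"] == 0

    def test_constructed_counts(self):
        gts_discordant = [(0, 0), (1, 1)]
        gts_concordant = [(0, 0), (0, 0)]
        gts_half_missing = [(0, 0), (-1, -1)]
        records = (
            [rec(pos=p, gts=gts_discordant) for p in range(1, 8)]
            + [rec(pos=p, gts=gts_concordant) for p in range(8, 11)]
            + [rec(pos=p, gts=gts_half_missing) for p in range(11, 13)]
        )
        out = count_polymorphic_pair(
            records, ["a", "b"], "a", "b", genome_length=7_000_000, map_length_cm=70.0
        )
        assert out["polymorphic_count"] == 7
        assert out["per_mb"] == pytest.approx(1.0)
        assert out["per_cm"] == pytest.approx(0.1)

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            count_polymorphic_pair([rec()], ["a", "b"], "a", "zz")

    def test_extreme_pair_matches_max_distance_without_hets(self):
        """On purely homozygous genotypes the most distant pair by IBS is
        also the pair with the most polymorphic sites."""
        rng = np.random.default_rng(21)
        samples = [f"s{i}" for i in range(5)]
        records = []
        for p in range(1, 200):
            gts = [(int(x), int(x)) for x in rng.integers(0, 2, size=5)]
            records.append(rec(pos=p, gts=gts))
        mat = ibs_distance_matrix(records, samples)
        counts = {
            (a, b): count_polymorphic_pair(records, samples, a, b)["polymorphic_count"]
            for i, a in enumerate(samples)
            for b in samples[i + 1:]
        }
        far_ibs = max(counts, key=lambda ab: mat.loc[ab[0], ab[1]])
        far_cnt = max(counts, key=counts.get)
        assert far_ibs == far_cnt
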
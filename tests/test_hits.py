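"""Fisher enrichment, BH correction, hit thresholds, reversed-integration flag."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from orftag.hits import (
    REVERSED_COMMENT,
    HitCallingConfig,
    bh_fdr,
    call_hits,
    fisher_one_tailed,
    flag_reversed,
)


def hypergeom_upper_tail_exact(a, row1, c, row2):
    """Independent oracle: exact upper-tail by binomial-coefficient enumeration."""
    n = a + c  # column-1 margin
    total = Fraction(math.comb(row1 + row2, n))
    tail = Fraction(0)
    for k in range(a, min(row1, n) + 1):
        if n - k > row2:
            continue
        tail += Fraction(math.comb(row1, k) * math.comb(row2, n - k))
    return tail / total


def bh_stepup_oracle(p):
    """Hand-written BH step-up with monotonicity enforcement."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        value = min(1.0, p[i] * n / rank)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


class TestFisher:
    def test_worked_table_exact(self):
        """[[3,7],[0,10]]: p = C(10,3)C(10,0)/C(20,3) = 120/1140."""
        p, log2_or = fisher_one_tailed(3, 10, 0, 10)
        assert p == pytest.approx(120 / 1140, rel=1e-12)
        assert log2_or == pytest.approx(math.log2((3.5 * 10.5) / (7.5 * 0.5)), rel=1e-12)

    def test_symmetric_table(self):
        p, log2_or = fisher_one_tailed(5, 10, 5, 10)
        assert log2_or == 0.0
        assert p > 0.5

    def test_zero_sorted_gives_p_one(self):
        p, _ = fisher_one_tailed(0, 10, 4, 10)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_sample(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            row1 = int(rng.integers(1, 40))
            row2 = int(rng.integers(1, 40))
            a = int(rng.integers(0, row1 + 1))
            c = int(rng.integers(0, row2 + 1))
            p, _ = fisher_one_tailed(a, row1, c, row2)
            expected = float(hypergeom_upper_tail_exact(a, row1, c, row2))
            assert p == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_monotone_in_n_sorted(self):
        previous = 1.1
        for a in range(0, 21):
            p, _ = fisher_one_tailed(a, 20, 5, 30)
            assert p <= previous + 1e-12
            previous = p

    def test_pseudo_count_only_on_zero_cells(self):
        _, with_zero = fisher_one_tailed(3, 10, 0, 10)
        _, no_zero = fisher_one_tailed(3, 10, 1, 10)
        assert no_zero == pytest.approx(math.log2((3 * 9) / (7 * 1)))
        assert with_zero == pytest.approx(math.log2((3.5 * 10.5) / (7.5 * 0.5)))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_tailed(11, 10, 0, 10)
        with pytest.raises(ValueError):
            fisher_one_tailed(-1, 10, 0, 10)
        with pytest.raises(ValueError):
            fisher_one_tailed(1, 0, 0, 10)


class TestBH:
    def test_hand_computed_example(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.3] * 5) == pytest.approx([0.3] * 5)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_matches_stepup_oracle_random(self):
        rng = np.random.default_rng(23)
        for n in (1, 2, 10, 500):
            p = rng.random(n)
            assert bh_fdr(p) == pytest.approx(bh_stepup_oracle(p))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(29)
        p = rng.random(200)
        perm = rng.permutation(200)
        direct = bh_fdr(p)
        permuted = bh_fdr(p[perm])
        assert permuted == pytest.approx(direct[perm])

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(31)
        p = rng.random(300)
        assert np.all(bh_fdr(p) >= p - 1e-15)


def _counts(rows):
    return pd.DataFrame(rows, columns=["gene_id", "n_sorted", "n_background"])


class TestCallHits:
    def test_min_insertion_prefilter(self):
        # extreme enrichment but only 2 sorted insertions -> never tested
        counts = _counts([("G1", 2, 0)] + [(f"N{i}", 5, 5) for i in range(20)])
        hits = call_hits(counts)
        assert "G1" not in set(hits["gene_id"])

    def test_prefilter_shrinks_bh_family(self):
        base = [(f"N{i}", 3, 30) for i in range(10)] + [("G1", 12, 2)]
        with_sub = base + [("S1", 1, 0)]  # below the filter
        a = call_hits(_counts(base)).set_index("gene_id")
        b = call_hits(_counts(with_sub)).set_index("gene_id")
        # the sub-threshold gene changes totals only marginally but must not
        # enter the BH family
        assert len(b) == len(a)

    def test_planted_enriched_gene_is_hit(self):
        rows = [("HIT", 30, 10)]
        rows += [(f"N{i}", 10, 27) for i in range(997)]
        counts = _counts(rows)
        hits = call_hits(counts, total_sorted=10_000, total_background=30_000)
        row = hits.set_index("gene_id").loc["HIT"]
        assert bool(row.is_hit)
        assert row.log2_odds_ratio >= 1
        assert row.fdr < 0.001

    def test_hit_invariants(self, small_screen):
        from orftag.annotation import build_acceptor_index
        from orftag.assignment import assign_all, build_counts
        from orftag.insertions import merge_background

        genome = small_screen["annotation"]
        index = build_acceptor_index(genome.annotation)
        bg = merge_background(small_screen["background"])
        counts = build_counts(
            assign_all(small_screen["sorted"].sites, index),
            assign_all(bg.sites, index),
        )
        hits = call_hits(counts)
        config = HitCallingConfig()
        for _, row in hits.iterrows():
            assert row.fdr >= row.p_value - 1e-15
            assert row.n_sorted >= config.min_sorted_insertions
            if row.is_hit:
                assert row.fdr < config.fdr_threshold
                assert row.log2_odds_ratio >= config.log2_or_threshold
        # output ordering: FDR ascending, then log2 OR descending
        assert list(hits.fdr) == sorted(hits.fdr)

    def test_null_produces_no_hits(self):
        """Sorted = random subsample of background -> ~0 hits at FDR < 0.001."""
        rng = np.random.default_rng(37)
        false_hits = 0
        for _ in range(20):
            lam = rng.uniform(5, 25, size=300)
            n_bg = rng.poisson(lam * 2)
            n_sorted = rng.binomial(n_bg, 1 / 3)  # subsample, no enrichment
            counts = _counts(
                [(f"G{i}", int(s), int(b)) for i, (s, b) in enumerate(zip(n_sorted, n_bg))]
            )
            hits = call_hits(counts)
            false_hits += int(hits["is_hit"].sum())
        assert false_hits <= 1

    def test_zero_totals_error(self):
        with pytest.raises(ValueError, match="zero assigned"):
            call_hits(_counts([("G", 0, 0)]))


class TestFlagReversed:
    def _forward(self):
        rows = [("SYM", 40, 5), ("SENSE", 40, 5)] + [(f"N{i}", 8, 24) for i in range(200)]
        return call_hits(_counts(rows), total_sorted=5_000, total_background=15_000)

    def test_symmetric_locus_flagged_sense_only_not(self):
        hits = self._forward()
        assert set(hits.loc[hits.is_hit, "gene_id"]) >= {"SYM", "SENSE"}
        # reversed counts: SYM is enriched after flipping, SENSE is not
        reversed_counts = _counts(
            [("SYM", 35, 4), ("SENSE", 3, 9)] + [(f"N{i}", 8, 24) for i in range(200)]
        )
        flagged = flag_reversed(hits, reversed_counts).set_index("gene_id")
        assert flagged.loc["SYM", "comment"] == REVERSED_COMMENT
        assert flagged.loc["SENSE", "comment"] == ""

    def test_non_hits_never_flagged(self):
        hits = self._forward()
        reversed_counts = _counts([("N0", 50, 1)] + [(f"N{i}", 8, 24) for i in range(1, 200)])
        flagged = flag_reversed(hits, reversed_counts).set_index("gene_id")
        assert (flagged.loc[~flagged.is_hit, "comment"] == "").all()

    def test_end_to_end_reversed_flag_on_synthetic_locus(self, toy_index):
        """A strand-symmetric pileup at GA is flagged; a sense-only one is not."""
        from orftag.assignment import assign_all, assign_reversed, build_counts
        from orftag.insertions import InsertionSite

        def sites(positions, strand, sample):
            return [InsertionSite("chr1", p, strand, sample) for p in positions]

        # sense insertions upstream of GA's exon-2 acceptor (300, '+') and an
        # equally strong antisense pileup at the same spot
        sense = sites(range(200, 240), "+", "s")
        antisense = sites(range(200, 240), "-", "s")  # flip -> assign to GA
        # ballast at the other genes so library totals are not GA-dominated:
        # background-heavy everywhere, GA-enriched only in sorted
        ballast_sorted = (
            sites(range(5500, 5510), "+", "s")
            + sites(range(7600, 7610), "+", "s")
            + sites(range(2310, 2320), "-", "s")
        )
        ballast_background = (
            sites(range(5400, 5580), "+", "b")
            + sites(range(7500, 7680), "+", "b")
            + sites(range(2310, 2490), "-", "b")
        )
        sense = sense + ballast_sorted
        background = (
            sites(range(250, 255), "+", "b")
            + sites(range(250, 255), "-", "b")
            + ballast_background
        )
        config = HitCallingConfig(min_sorted_insertions=3)

        fwd = build_counts(
            assign_all(sense + antisense, toy_index), assign_all(background, toy_index)
        )
        rev = build_counts(
            assign_reversed(sense + antisense, toy_index),
            assign_reversed(background, toy_index),
        )
        hits = flag_reversed(call_hits(fwd, config=config), rev, config=config)
        row = hits.set_index("gene_id").loc["GA"]
        assert bool(row.is_hit)
        assert row.comment == REVERSED_COMMENT

        # sense-only: same forward pileup, no antisense partner
        fwd2 = build_counts(assign_all(sense, toy_index), assign_all(background, toy_index))
        rev2 = build_counts(
            assign_reversed(sense, toy_index), assign_reversed(background, toy_index)
        )
        hits2 = flag_reversed(call_hits(fwd2, config=config), rev2, config=config)
        row2 = hits2.set_index("gene_id").loc["GA"]
        assert bool(row2.is_hit)
        assert row2.comment == ""
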
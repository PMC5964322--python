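"""Seed sites, k-mer statistics, Welch test, overlap and proximity tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from iclipkit import (
    MiRNA, seed_site_7merA1, load_mirna_panel, count_kmer, profile_utrs,
    welch_t_test, compare_bound_unbound, overlap_enrichment,
    positional_profile, seed_proximity_bias, POLY_U_7MER,
)
from conftest import make_transcript, make_ce, brute_force_kmer_count


class TestSeedSite:
    def test_canonical_definition(self):
        assert seed_site_7merA1(MiRNA("let7-like", "UAGGUAGUUU")) == "CUACCUA"
        assert seed_site_7merA1(MiRNA("polyA", "AAAAAAAA")) == "UUUUUUA"

    def test_mir128(self):
        assert seed_site_7merA1(MiRNA("miR-128-3p", "UCACAGUGAACCGGUCUCUUU")) \
            == "ACUGUGA"

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="8"):
            MiRNA("short", "UAGGUAG")

    def test_packaged_panel(self):
        panel = load_mirna_panel()
        names = {m.name for m in panel}
        assert len(panel) == 10
        assert "miR-128-3p" in names and "let-7a-5p" in names
        for m in panel:
            assert len(seed_site_7merA1(m)) == 7


class TestCountKmer:
    def test_overlapping_homopolymer(self):
        assert count_kmer("U" * 9, POLY_U_7MER) == 3

    def test_absent(self):
        assert count_kmer("ACGUACGU", POLY_U_7MER) == 0

    def test_kmer_longer_than_seq(self):
        assert count_kmer("ACG", "ACGUACG") == 0

    def test_u_t_equivalence(self):
        assert count_kmer("TTTTTTTT", POLY_U_7MER) == 2

    def test_non_overlapping_mode(self):
        assert count_kmer("U" * 14, POLY_U_7MER, overlapping=False) == 2

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=0, max_size=120),
           st.text(alphabet="ACGU", min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, seq, kmer):
        assert count_kmer(seq, kmer) == brute_force_kmer_count(seq, kmer)


class TestProfileUtrs:
    def test_density_arithmetic(self):
        ann = {"T1": make_transcript("T1", utr5=0, cds=100, utr3=2000)}
        utr = ("GACU" * 500)
        seq = "C" * 100 + utr
        prof = profile_utrs(ann, {"T1": seq}, {"gacu": "GACU"})
        row = prof.iloc[0]
        assert row["utr3_length"] == 2000
        assert row["count"] == 500
        assert row["density"] == pytest.approx(250.0)
        # scale consistency: density * length / 1000 = count
        assert row["density"] * row["utr3_length"] / 1000 == pytest.approx(row["count"])

    def test_zero_length_utr(self):
        ann = {"T1": make_transcript("T1", utr5=10, cds=100, utr3=0)}
        prof = profile_utrs(ann, {"T1": "A" * 110}, {"polyU": POLY_U_7MER})
        row = prof.iloc[0]
        assert (row["count"], row["density"]) == (0, 0.0)

    def test_missing_sequence_raises(self):
        ann = {"T1": make_transcript("T1")}
        with pytest.raises(KeyError, match="T1"):
            profile_utrs(ann, {}, {"polyU": POLY_U_7MER})

    def test_duplicated_utr_bounds(self):
        rng = np.random.default_rng(8)
        kmer = "GACUG"
        for _ in range(20):
            utr = "".join(rng.choice(list("ACGU"), 400))
            c1 = count_kmer(utr, kmer)
            c2 = count_kmer(utr + utr, kmer)
            assert 2 * c1 <= c2 <= 2 * c1 + len(kmer) - 1


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_example(self):
        res = welch_t_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.t == pytest.approx(-1.732, abs=1e-3)
        assert res.df == pytest.approx(4.41, abs=0.01)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 5.0], [0.5, 3.0, 9.0, 2.0]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_both_raises(self):
        with pytest.raises(ValueError, match="variance"):
            welch_t_test([1, 1, 1], [2, 2, 2])

    def test_small_groups_raise(self):
        with pytest.raises(ValueError):
            welch_t_test([1], [2, 3])

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x = rng.normal(0, 1 + rng.random(), size=rng.integers(2, 40))
            y = rng.normal(rng.normal(), 1, size=rng.integers(2, 40))
            ours = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestCompareBoundUnbound:
    @staticmethod
    def _setup(rng, n=100, plant=True):
        ann, seqs, rows = {}, {}, []
        for i in range(2 * n):
            tid = f"T{i:03d}"
            bound = i < n
            utr_len = 1500
            ann[tid] = make_transcript(tid, utr5=0, cds=100, utr3=utr_len)
            utr = "".join(rng.choice(list("ACGU"), utr_len))
            if bound and plant:
                utr = utr[:500] + "U" * 20 + utr[520:]
            seqs[tid] = "C" * 100 + utr
            rows.append((tid, bound, int(bound), 0, utr_len))
        targets = pd.DataFrame(rows, columns=[
            "transcript_id", "bound", "n_peaks", "total_unique_CEs", "utr3_length"])
        return ann, seqs, targets

    def test_planted_polyu_enriched(self):
        rng = np.random.default_rng(23)
        ann, seqs, targets = self._setup(rng, plant=True)
        prof = profile_utrs(ann, seqs, {"polyU": POLY_U_7MER})
        res = compare_bound_unbound(prof, targets, "polyU")
        assert res.mean_density_bound > res.mean_density_unbound
        assert res.density_test.p_value < 0.01
        assert res.count_test.p_value < 0.01

    def test_identical_profiles_t_zero(self):
        ann = {f"T{i}": make_transcript(f"T{i}", utr5=0, cds=10, utr3=100)
               for i in range(6)}
        # same count multiset {0, 1, 2} in the bound and the unbound group
        per_group = ["C" * 100, "GAU" + "C" * 97, "GAUGAU" + "C" * 94]
        seqs = {t: "C" * 10 + per_group[i % 3] for i, t in enumerate(sorted(ann))}
        targets = pd.DataFrame(
            [(t, i < 3, 0, 0, 100) for i, t in enumerate(sorted(ann))],
            columns=["transcript_id", "bound", "n_peaks", "total_unique_CEs",
                     "utr3_length"])
        prof = profile_utrs(ann, seqs, {"gau": "GAU"})
        res = compare_bound_unbound(prof, targets, "gau")
        assert res.count_test.t == pytest.approx(0.0)
        assert res.count_test.p_value == pytest.approx(1.0)

    def test_small_group_raises(self):
        rng = np.random.default_rng(1)
        ann, seqs, targets = self._setup(rng, n=1)
        prof = profile_utrs(ann, seqs, {"polyU": POLY_U_7MER})
        with pytest.raises(ValueError):
            compare_bound_unbound(prof, targets, "polyU")


class TestOverlapEnrichment:
    def test_exhaustive_enumeration_small_case(self):
        """p for N=10, |A|=5, |B|=4, k=4 equals literal enumeration of all
        C(10,4) draws of B."""
        universe = list(range(10))
        A = set(universe[:5])
        B = set(universe[:4])
        res = overlap_enrichment(A, B, 10)
        hits = sum(1 for draw in itertools.combinations(universe, 4)
                   if len(set(draw) & A) >= 4)
        total = sum(1 for _ in itertools.combinations(universe, 4))
        assert total == 210 and hits == 5
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)
        assert res.overlap == 4
        assert res.expected == pytest.approx(2.0)
        assert res.fold == pytest.approx(2.0)

    def test_certain_event(self):
        A = set(range(10))
        B = set(range(4))
        res = overlap_enrichment(A, B, 10)  # B subset of A, |A| = N
        assert res.p_value == pytest.approx(1.0)

    def test_zero_overlap(self):
        res = overlap_enrichment({1, 2}, {3, 4}, 10)
        assert res.overlap == 0 and res.fold == 0.0
        assert res.p_value <= 1.0

    def test_universe_too_small_raises(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment({1, 2, 3}, {4, 5}, 4)


class TestPositionalProfile:
    def test_single_event_one_hot(self):
        seqs = {"T1": "ACGUACGUACGUACGUACGU"}
        prof = positional_profile(make_ce([("T1", 10, 1)]), seqs, flank=3)
        assert prof.matrix.shape == (4, 7)
        for col in range(7):
            assert prof.matrix[:, col].sum() == pytest.approx(1.0)
            assert prof.matrix[:, col].max() == pytest.approx(1.0)

    def test_planted_u_runs_dominate_center(self):
        rng = np.random.default_rng(31)
        seqs, rows = {}, []
        for i in range(50):
            tid = f"T{i}"
            seq = "".join(rng.choice(list("ACG"), 200))
            seq = seq[:95] + "U" * 10 + seq[105:]
            seqs[tid] = seq
            rows.append((tid, 100, int(rng.integers(1, 5))))  # center of the run
        prof = positional_profile(make_ce(rows), seqs, flank=10)
        assert prof.central_u_frequency(width=2) >= 0.8

    def test_uniform_background_flat(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGU"), 50_000))
        rows = [("T1", int(p), 1)
                for p in rng.integers(100, 49_900, size=10_000)]
        prof = positional_profile(make_ce(rows), {"T1": seq}, flank=5)
        assert np.all(np.abs(prof.matrix - 0.25) < 0.02)

    def test_out_of_range_windows_skipped(self):
        seqs = {"T1": "ACGUACGU"}
        prof = positional_profile(make_ce([("T1", 1, 1), ("T1", 4, 1)]),
                                  seqs, flank=3)
        assert prof.n_events == 1 and prof.n_skipped == 1

    def test_no_usable_events_raises(self):
        with pytest.raises(ValueError):
            positional_profile(make_ce([("T1", 0, 1)]), {"T1": "ACGUA"}, flank=3)


class TestSeedProximity:
    @staticmethod
    def _ann(utr3=1000):
        # 3'UTR-first layout keeps positions small and inside the UTR
        from iclipkit import Region, TranscriptModel
        return {"T1": TranscriptModel("T1", "G1", "protein_coding", utr3 + 100, [
            Region(0, utr3, "three_prime_utr"), Region(utr3, utr3 + 100, "cds")])}

    def test_observed_distance(self):
        ann = self._ann()
        res = seed_proximity_bias(make_ce([("T1", 0, 1)]), {"T1": [(10, 17)]},
                                  ann, n_perm=100, seed=1)
        assert res.median_abs_distance == pytest.approx(10.0)

    def test_extreme_case_floor_attained(self):
        ann = self._ann()
        rows = [("T1", 10, 1)] * 1  # exactly at the seed start
        ce = make_ce([("T1", 10, 1)])
        res = seed_proximity_bias(ce, {"T1": [(10, 17)]}, ann, n_perm=200, seed=2)
        assert res.median_abs_distance == 0.0
        assert res.p_value <= 3 / 201

    def test_no_cooccurrence_raises(self):
        ann = self._ann()
        with pytest.raises(ValueError):
            seed_proximity_bias(make_ce([("T1", 5, 1)]), {}, ann, n_perm=10, seed=0)

    def test_uniform_null_p_not_extreme(self):
        rng = np.random.default_rng(11)
        ann = self._ann(2000)
        sites = {"T1": [(int(s), int(s) + 7) for s in rng.integers(0, 1990, 5)]}
        rows = [("T1", int(p), 1) for p in rng.integers(0, 2000, 40)]
        res = seed_proximity_bias(make_ce(rows), sites, ann, n_perm=500, seed=3)
        assert 0.001 < res.p_value <= 1.0
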
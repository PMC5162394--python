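"""BM/BCM/ASB identification: stated rules, limits, brute-force equivalence."""

import math

import numpy as np
import pytest

from barcodegap.distance import DistanceMatrix
from barcodegap.gap import DistancePartition, IntraPair, partition
from barcodegap.identify import (
    all_species_barcodes,
    bcm_threshold,
    best_close_match,
    best_match,
    evaluate,
)

from conftest import oracle_asb, oracle_bcm, oracle_bm


def dm_from(values, species):
    ids = [f"r{i}" for i in range(len(species))]
    return DistanceMatrix(ids=ids, species=species, values=np.array(values, dtype=float))


def intra_partition(distances):
    return DistancePartition(
        intra=[IntraPair("s", ("a", "b"), d) for d in distances],
        inter=[],
        species_counts={"s": 2},
    )


def random_instance(rng, n=8, n_species=3):
    """Random symmetric distance matrix with random species labels."""
    species = [f"sp{rng.integers(0, n_species)}" for _ in range(n)]
    # ensure at least two species present
    species[0], species[1] = "sp0", "sp1"
    a = rng.uniform(0.001, 0.5, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    # occasional exact ties to exercise tie handling
    if rng.random() < 0.5 and n >= 4:
        d[0, 2] = d[2, 0] = d[0, 3] = d[3, 0]
    return dm_from(d, species)


class TestBCMThreshold:
    def test_single_value(self):
        assert bcm_threshold(intra_partition([0.01])) == 0.01

    def test_nearest_rank_95th_of_20(self):
        values = [round(0.001 * k, 6) for k in range(1, 21)]
        # rank ceil(0.95 * 20) = 19 -> 19th smallest = 0.019
        assert bcm_threshold(intra_partition(values)) == pytest.approx(0.019)

    def test_percentile_one_gives_maximum(self):
        assert bcm_threshold(intra_partition([0.03, 0.01, 0.02]), 1.0) == 0.03

    def test_empty_intra_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            bcm_threshold(intra_partition([]))


class TestBestMatch:
    def test_nearest_conspecific_correct(self):
        d = [[0, 0.01, 0.2], [0.01, 0, 0.2], [0.2, 0.2, 0]]
        r = best_match(0, dm_from(d, ["s1", "s1", "s2"]))
        assert r.verdict == "correct"
        assert r.best_distance == pytest.approx(0.01)

    def test_equidistant_mixed_species_ambiguous(self):
        d = [[0, 0.05, 0.05], [0.05, 0, 0.1], [0.05, 0.1, 0]]
        r = best_match(0, dm_from(d, ["s1", "s1", "s2"]))
        assert r.verdict == "ambiguous"
        assert r.matched_species == {"s1", "s2"}

    def test_singleton_necessarily_incorrect(self):
        d = [[0, 0.01, 0.2], [0.01, 0, 0.2], [0.2, 0.2, 0]]
        r = best_match(2, dm_from(d, ["s1", "s1", "s2"]))
        assert r.verdict == "incorrect"
        assert r.is_singleton


class TestBestCloseMatch:
    def test_distant_neighbour_is_no_match(self):
        d = [[0, 0.3, 0.35], [0.3, 0, 0.1], [0.35, 0.1, 0]]
        r = best_close_match(0, dm_from(d, ["s1", "s1", "s2"]), threshold=0.05)
        assert r.verdict == "no_match"

    def test_close_conspecific_correct(self):
        d = [[0, 0.01, 0.2], [0.01, 0, 0.2], [0.2, 0.2, 0]]
        r = best_close_match(0, dm_from(d, ["s1", "s1", "s2"]), threshold=0.05)
        assert r.verdict == "correct"

    def test_infinite_threshold_equals_best_match(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            dm = random_instance(rng)
            for qi in range(dm.n):
                bm = best_match(qi, dm)
                bcm = best_close_match(qi, dm, threshold=math.inf)
                assert bcm.verdict == bm.verdict

    def test_lowering_threshold_monotone_to_no_match(self):
        """Once no_match at threshold t, still no_match at any t' < t."""
        rng = np.random.default_rng(23)
        dm = random_instance(rng)
        for qi in range(dm.n):
            thresholds = sorted(rng.uniform(0, 0.6, size=8), reverse=True)
            seen_no_match = False
            for t in thresholds:
                v = best_close_match(qi, dm, threshold=t).verdict
                if seen_no_match:
                    assert v == "no_match"
                seen_no_match = v == "no_match"


class TestAllSpeciesBarcodes:
    def test_separated_correct(self):
        d = [[0, 0.01, 0.2], [0.01, 0, 0.2], [0.2, 0.2, 0]]
        assert all_species_barcodes(0, dm_from(d, ["s1", "s1", "s2"])).verdict == "correct"

    def test_overlapping_incorrect(self):
        d = [[0, 0.05, 0.03], [0.05, 0, 0.2], [0.03, 0.2, 0]]
        assert all_species_barcodes(0, dm_from(d, ["s1", "s1", "s2"])).verdict == "incorrect"

    def test_asb_correct_implies_bm_correct(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            dm = random_instance(rng)
            for qi in range(dm.n):
                if all_species_barcodes(qi, dm).verdict == "correct":
                    assert best_match(qi, dm).verdict == "correct"


class TestOracleEquivalence:
    def test_all_rules_match_exhaustive_enumeration(self):
        """100 random 8-sequence instances agree with the restated rules."""
        rng = np.random.default_rng(101)
        for _ in range(100):
            dm = random_instance(rng)
            d = dm.values
            thr = float(rng.uniform(0.01, 0.4))
            for qi in range(dm.n):
                assert best_match(qi, dm).verdict == oracle_bm(qi, d, dm.species)
                assert (
                    best_close_match(qi, dm, threshold=thr).verdict
                    == oracle_bcm(qi, d, dm.species, thr)
                )
                assert (
                    all_species_barcodes(qi, dm).verdict
                    == oracle_asb(qi, d, dm.species)
                )


class TestEvaluate:
    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(31)
        dm = random_instance(rng)
        for method, thr in (("BM", None), ("BCM", 0.1), ("ASB", None)):
            s, results = evaluate(dm, method, threshold=thr)
            total = s.pct_correct + s.pct_ambiguous + s.pct_incorrect + s.pct_no_match
            assert total == pytest.approx(100.0, abs=0.02)
            assert s.n_queries == len(results)
            # exactly one verdict per query
            assert all(
                r.verdict in ("correct", "ambiguous", "incorrect", "no_match")
                for r in results
            )

    def test_no_match_only_under_bcm(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            dm = random_instance(rng)
            for method in ("BM", "ASB"):
                _, results = evaluate(dm, method)
                assert all(r.verdict != "no_match" for r in results)

    def test_bcm_requires_threshold(self):
        rng = np.random.default_rng(41)
        with pytest.raises(ValueError):
            evaluate(random_instance(rng), "BCM")

    def test_excluded_queries_counted(self):
        d = [[0, np.nan, np.nan], [np.nan, 0, 0.1], [np.nan, 0.1, 0]]
        s, results = evaluate(dm_from(d, ["s1", "s2", "s2"]), "BM")
        assert s.n_excluded == 1
        assert s.n_queries == 2
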
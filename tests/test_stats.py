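"""Exact tests, per-residue comparisons, interaction and conservation stats."""

import numpy as np
import pytest

from tritract.homoaa import TNR, VARIANT, HomoAATract
from tritract.stats import (
    ConservationTrack,
    StatsError,
    binomial_composition_test,
    composition_analysis,
    length_analysis,
    mann_whitney_u,
    ppi_degree_comparison,
    ppi_degrees,
    tract_conservation_comparison,
)

from .oracles import binomial_two_tailed, mann_whitney_exact


class TestBinomialTest:
    def test_all_successes_at_half(self):
        assert binomial_composition_test(10, 10, 0.5) == pytest.approx(2 / 1024)

    def test_symmetric_two_of_two(self):
        assert binomial_composition_test(2, 2, 0.5) == pytest.approx(0.5)

    def test_modal_outcome_gives_p_one(self):
        # k at the mode: every outcome has probability <= pmf(k)
        assert binomial_composition_test(5, 10, 0.5) == pytest.approx(1.0)

    def test_degenerate_null(self):
        assert binomial_composition_test(0, 5, 0.0) == 1.0
        assert binomial_composition_test(3, 5, 0.0) == 0.0
        assert binomial_composition_test(5, 5, 1.0) == 1.0

    def test_invalid_counts_raise(self):
        with pytest.raises(StatsError):
            binomial_composition_test(5, 3, 0.5)

    @pytest.mark.parametrize("n", range(1, 13))
    def test_equals_pmf_enumeration_oracle(self, n):
        for p0 in np.arange(0.1, 0.95, 0.1):
            for k in range(n + 1):
                assert binomial_composition_test(k, n, float(p0)) == pytest.approx(
                    binomial_two_tailed(k, n, float(p0)), rel=1e-8, abs=1e-12
                )


class TestMannWhitney:
    def test_complete_separation_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings

    def test_identical_samples_with_ties(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert p >= 0.99

    def test_single_observation_per_class_equal(self):
        _, p = mann_whitney_u([7], [7])
        assert p == pytest.approx(1.0)

    def test_empty_sample_raises(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])

    def test_u_range_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, 6).tolist()
            y = rng.integers(0, 5, 5).tolist()
            u, p = mann_whitney_u(x, y)
            assert 0 <= u <= len(x) * len(y)
            assert 0 <= p <= 1

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_mode_equals_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 11 - n1))
        # lattice values force ties
        x = rng.integers(0, 4, n1).tolist()
        y = rng.integers(0, 4, n2).tolist()
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = mann_whitney_exact(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_power_on_shifted_samples(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            x = rng.normal(3, 1, 100)
            y = rng.normal(0, 1, 100)
            _, p = mann_whitney_u(x, y)
            hits += p < 0.05
        assert hits >= 38  # >= 95% of repetitions


def _tracts(spec):
    """spec: list of (protein, residue, length, class)."""
    out = []
    for i, (pid, res, length, cls) in enumerate(spec):
        out.append(
            HomoAATract(pid, res, 0, length, encoding_class=cls)
        )
    return out


class TestCompositionAnalysis:
    def test_counts_and_p0_definition(self):
        tracts = _tracts([
            ("p1", "Q", 8, TNR), ("p2", "Q", 9, TNR), ("p3", "Q", 7, VARIANT),
            ("p4", "A", 7, VARIANT), ("p5", "A", 7, VARIANT),
        ])
        sets = ({"p1", "p2"}, {"p3", "p4", "p5"}, {"p1", "p2", "p3", "p4", "p5"})
        results = composition_analysis(tracts, sets)
        by_res = {r.residue: r for r in results}
        assert by_res["Q"].n_tracts_total == 3 and by_res["Q"].n_tnr_tracts == 2
        assert by_res["Q"].p0 == pytest.approx(2 / 5)
        assert sum(r.n_tracts_total for r in results) == len(tracts)

    def test_recovery_of_elevated_residue(self):
        rng = np.random.default_rng(2)
        spec = []
        pid = 0
        for i in range(120):  # Q tracts at 60% repeat-encoded
            cls = TNR if rng.random() < 0.6 else VARIANT
            spec.append((f"q{pid}", "Q", 8, cls)); pid += 1
        for i in range(300):  # other residues at 20%
            res = "ANES"[i % 4]
            cls = TNR if rng.random() < 0.2 else VARIANT
            spec.append((f"o{pid}", res, 8, cls)); pid += 1
        tracts = _tracts(spec)
        tnr = {t.protein_id for t in tracts if t.encoding_class == TNR}
        var = {t.protein_id for t in tracts if t.encoding_class == VARIANT}
        results = composition_analysis(tracts, (tnr, var, tnr | var))
        q = next(r for r in results if r.residue == "Q")
        assert q.significant and q.log2_proportion_ratio > 0


class TestLengthAnalysis:
    def test_single_class_residue_reported_without_p(self):
        res = length_analysis(_tracts([("p1", "Q", 8, TNR), ("p2", "Q", 9, TNR)]))
        assert res[0].p_value is None and res[0].mean_variant is None

    def test_recovery_of_longer_repeat_encoded_tracts(self):
        rng = np.random.default_rng(3)
        spec = []
        for i in range(100):
            spec.append((f"a{i}", "Q", 6 + int(rng.geometric(1 / 7)), TNR))
        for i in range(100):
            spec.append((f"b{i}", "Q", 6 + int(rng.geometric(1 / 3)), VARIANT))
        res = length_analysis(_tracts(spec))[0]
        assert res.significant and res.log2_length_ratio > 0
        assert res.mean_tnr > res.mean_variant
        assert res.se_tnr is not None and res.se_variant is not None


class TestPPI:
    def test_duplicate_pairs_and_self_pairs_ignored(self):
        degrees = ppi_degrees(
            [("a", "b"), ("a", "b"), ("b", "a"), ("a", "c"), ("a", "a")],
            ["a", "b", "c", "d"],
        )
        assert degrees == {"a": 2, "b": 1, "c": 1, "d": 0}

    def test_empty_table_gives_p_one(self):
        sets = ({"a"}, {"b", "c"}, {"a", "b", "c"})
        table, u, p = ppi_degree_comparison([], sets)
        assert (table.degree == 0).all()
        assert p == 1.0

    def test_identical_degree_distributions_rarely_significant(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 100
        for _ in range(reps):
            tnr = {f"t{i}": int(rng.poisson(3)) for i in range(15)}
            var = {f"v{i}": int(rng.poisson(3)) for i in range(25)}
            pairs = []
            partner = 0
            for pid, deg in {**tnr, **var}.items():
                for _ in range(deg):
                    pairs.append((pid, f"x{partner}"))
                    partner += 1
            sets = (set(tnr), set(var), set(tnr) | set(var))
            _, _, p = ppi_degree_comparison(pairs, sets)
            hits += p < 0.05
        assert hits / reps <= 0.1


class TestConservation:
    def _track(self, intervals):
        return ConservationTrack({"chr1": intervals})

    def test_constant_track_gives_constant_means_and_p_one(self):
        track = self._track([(0, 1000, 0.8)])
        tracts = [
            HomoAATract("p1", "Q", 0, 8, encoding_class=TNR,
                        genomic_loci=[(10, 34)], sequence_id="chr1", strand="+"),
            HomoAATract("p2", "Q", 0, 8, encoding_class=VARIANT,
                        genomic_loci=[(100, 124)], sequence_id="chr1", strand="+"),
        ]
        table, u, p = tract_conservation_comparison(tracts, track)
        assert np.allclose(table.mean_score, 0.8)
        assert p == 1.0

    def test_split_locus_mean_is_length_weighted(self):
        track = self._track([(100, 103, 0.0), (200, 203, 1.0)])
        assert track.mean_score("chr1", [(100, 103), (200, 203)]) == pytest.approx(0.5)

    def test_uncovered_tract_excluded(self):
        track = self._track([(0, 10, 0.5)])
        tracts = [
            HomoAATract("p1", "Q", 0, 8, encoding_class=TNR,
                        genomic_loci=[(5000, 5024)], sequence_id="chr1", strand="+"),
            HomoAATract("p2", "Q", 0, 8, encoding_class=VARIANT,
                        genomic_loci=[(0, 9)], sequence_id="chr1", strand="+"),
        ]
        table, _, p = tract_conservation_comparison(tracts, track)
        assert len(table) == 1
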
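import itertools

import numpy as np
import pytest
from scipy import stats

from depscreen.codependency import (build_codependency_table,
                                    pairwise_correlation,
                                    top_k_codependencies)
from depscreen.errors import GeneLookupError, ValidationError
from depscreen.io_formats import EffectMatrix, GeneId, SeedList
from depscreen.synthetic_data import ModuleSpec, simulate_effect_matrix


def brute_force_ranking(matrix, seed_symbol, ranking="absolute",
                        min_pairs=3):
    """Independent oracle: scipy pearsonr per pair + full sort."""
    j = next(i for i, g in enumerate(matrix.genes)
             if g.symbol == seed_symbol)
    out = []
    for i, g in enumerate(matrix.genes):
        if i == j:
            continue
        x, y = matrix.values[:, j], matrix.values[:, i]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        r = stats.pearsonr(x[ok], y[ok]).statistic
        out.append((g, r))
    key = ((lambda t: (-abs(t[1]), t[0].sort_key)) if ranking == "absolute"
           else (lambda t: (-t[1], t[0].sort_key)))
    return sorted(out, key=key)


class TestPairwiseCorrelation:
    def test_self_correlation_is_one(self, small_matrix):
        assert pairwise_correlation(small_matrix, "A", "A",
                                    min_pairs=3) == 1.0

    def test_duplicate_profile_is_one(self, small_matrix):
        assert pairwise_correlation(small_matrix, "A", "B",
                                    min_pairs=3) == pytest.approx(1.0)

    def test_negated_profile_is_minus_one(self, small_matrix):
        assert pairwise_correlation(small_matrix, "A", "C",
                                    min_pairs=3) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # a=(1,2,3,4), b=(2,1,4,3): cov*n = 3, sd products = 5 -> r = 0.6,
        # worked by hand from the covariance/sigma formula
        m = EffectMatrix(["w", "x", "y", "z"],
                         [GeneId("A"), GeneId("B")],
                         np.array([[1.0, 2.0], [2.0, 1.0],
                                   [3.0, 4.0], [4.0, 3.0]]))
        assert pairwise_correlation(m, "A", "B", min_pairs=3) == \
            pytest.approx(0.6, abs=1e-12)

    def test_unknown_gene_names_symbol(self, small_matrix):
        with pytest.raises(GeneLookupError, match="NOPE"):
            pairwise_correlation(small_matrix, "A", "NOPE")

    def test_min_pairs_yields_nan(self, small_matrix):
        m = small_matrix
        m.values[2:, 3] = np.nan  # D observed on 2 lines only
        assert np.isnan(pairwise_correlation(m, "A", "D", min_pairs=3))

    def test_constant_profile_yields_nan(self):
        m = EffectMatrix(["a", "b", "c", "d"],
                         [GeneId("A"), GeneId("K")],
                         np.column_stack([np.arange(4.0),
                                          np.full(4, 0.1)]))
        assert np.isnan(pairwise_correlation(m, "A", "K", min_pairs=3))

    def test_symmetry_exact(self):
        rng = np.random.default_rng(17)
        values = rng.standard_normal((30, 8))
        values[rng.random((30, 8)) < 0.2] = np.nan
        genes = [GeneId(f"S{i}") for i in range(8)]
        m = EffectMatrix([f"L{i}" for i in range(30)], genes, values)
        for a, b in itertools.combinations(range(8), 2):
            ga, gb = genes[a].symbol, genes[b].symbol
            assert pairwise_correlation(m, ga, gb, min_pairs=3) == \
                pairwise_correlation(m, gb, ga, min_pairs=3)

    def test_positive_affine_invariance(self, small_matrix):
        m = small_matrix
        before = [pairwise_correlation(m, "A", g, min_pairs=3)
                  for g in "BCDE"]
        m.values[:, 0] = 3.7 * m.values[:, 0] - 11.0
        after = [pairwise_correlation(m, "A", g, min_pairs=3)
                 for g in "BCDE"]
        np.testing.assert_allclose(after, before, atol=1e-12)


class TestTopK:
    def test_k_exceeding_universe(self, small_matrix):
        entries = top_k_codependencies(small_matrix, "A", k=10, min_pairs=3)
        assert len(entries) == 4  # all partners, self excluded
        assert all(e.partner.symbol != "A" for e in entries)

    def test_perfect_correlate_ranks_first(self, small_matrix):
        entries = top_k_codependencies(small_matrix, "A", k=3, min_pairs=3)
        assert entries[0].partner.symbol == "B"
        assert entries[0].r == pytest.approx(1.0)
        assert entries[0].rank == 1

    def test_absolute_ranking_keeps_negative_correlates(self, small_matrix):
        entries = top_k_codependencies(small_matrix, "A", k=2, min_pairs=3)
        assert {e.partner.symbol for e in entries} == {"B", "C"}

    def test_signed_ranking_demotes_negative_correlates(self, small_matrix):
        entries = top_k_codependencies(small_matrix, "A", k=4, min_pairs=3,
                                       ranking="signed_positive")
        assert entries[-1].partner.symbol == "C"

    def test_tie_break_is_symbol_then_entrez(self):
        # three identical partner profiles -> identical r, order by name
        base = np.arange(6.0)
        values = np.column_stack([base, base + 1, base + 2, base + 3])
        genes = [GeneId("SEED", 1), GeneId("ZZ", 1), GeneId("AA", 9),
                 GeneId("AA", 2)]
        m = EffectMatrix([f"L{i}" for i in range(6)], genes, values)
        entries = top_k_codependencies(m, GeneId("SEED", 1), k=3, min_pairs=3)
        assert [(e.partner.symbol, e.partner.entrez_id) for e in entries] == \
            [("AA", 2), ("AA", 9), ("ZZ", 1)]

    @pytest.mark.parametrize("ranking", ["absolute", "signed_positive"])
    def test_matches_exhaustive_sort_oracle(self, ranking):
        members = tuple(f"G{i + 1:04d}" for i in range(8))
        matrix, _ = simulate_effect_matrix(
            30, 60, [ModuleSpec(members, loading=1.0)],
            noise_sd=0.5, missing_rate=0.05, rng_seed=23)
        for seed_symbol in ("G0001", "G0015"):
            got = top_k_codependencies(matrix, seed_symbol, k=5,
                                       ranking=ranking, min_pairs=10)
            expected = brute_force_ranking(matrix, seed_symbol,
                                           ranking=ranking, min_pairs=10)[:5]
            assert [(e.partner, e.rank) for e in got] == \
                [(g, i + 1) for i, (g, _) in enumerate(expected)]
            np.testing.assert_allclose([e.r for e in got],
                                       [r for _, r in expected], atol=1e-12)

    def test_seed_absent_raises(self, small_matrix):
        with pytest.raises(GeneLookupError):
            top_k_codependencies(small_matrix, "MISSING", k=3)


class TestBuildTable:
    def test_single_seed_single_list(self, small_matrix):
        t = build_codependency_table(
            small_matrix, SeedList([GeneId("A")]), k=3, min_pairs=3)
        assert len(t.lists) == 1

    def test_identical_profiles_have_mirrored_lists(self, small_matrix):
        t = build_codependency_table(
            small_matrix, SeedList([GeneId("A"), GeneId("B")]), k=10,
            min_pairs=3)
        (la, lb) = (t.lists[GeneId("A", 1)], t.lists[GeneId("B", 2)])
        assert {e.partner.symbol for e in la} - {"B"} == \
            {e.partner.symbol for e in lb} - {"A"}

    def test_absent_seeds_skipped_and_logged(self, small_matrix, caplog):
        with caplog.at_level("WARNING", logger="depscreen.codependency"):
            t = build_codependency_table(
                small_matrix, SeedList([GeneId("A"), GeneId("GHOST")]),
                k=2, min_pairs=3)
        assert [g.symbol for g in t.skipped_seeds] == ["GHOST"]
        assert "skipped" in caplog.text

    def test_no_seed_present_is_error(self, small_matrix):
        with pytest.raises(ValidationError):
            build_codependency_table(
                small_matrix, SeedList([GeneId("GHOST")]), k=2)
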
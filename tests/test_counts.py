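"""Family weighting, substitution counting, log-odds estimation, pipeline."""

import numpy as np
import pytest

import substmat as sm
from substmat.counts import (
    Family,
    FamilyMember,
    LogOddsParams,
    UngappedPairBlock,
    WeightedCounts,
    count_substitutions,
    estimate_log_odds,
    family_weight,
)
from substmat.synth import SubstitutionProcess, simulate_families, skewed_frequencies

AA = sm.CANONICAL_ALPHABET


def idx(residue):
    return AA.index(residue)


class TestFamilyWeight:
    @pytest.mark.parametrize("n,expected", [(2, 1.0), (3, 1 / 3), (100, 2 / 9900)])
    def test_weight_formula(self, n, expected):
        assert family_weight(n).weight == pytest.approx(expected)

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            family_weight(1)


class TestCounting:
    def test_identical_columns_accumulate_on_diagonal(self):
        counts = count_substitutions(
            [UngappedPairBlock("f", "AA", "AA")], {"f": family_weight(2, "f")}
        )
        assert counts.f[idx("A"), idx("A")] == 2
        assert counts.total == 2

    def test_unordered_pair_convention(self):
        counts = count_substitutions(
            [UngappedPairBlock("f", "AR", "RA")], {"f": family_weight(2, "f")}
        )
        assert counts.f[idx("A"), idx("R")] == 2
        assert counts.f[idx("R"), idx("A")] == 2
        assert counts.total == 2

    def test_family_total_mass_equals_block_length(self):
        """n=3: three pairwise blocks of length L jointly weigh exactly L."""
        L = 7
        blocks = [
            UngappedPairBlock("f", "A" * L, "R" * L),
            UngappedPairBlock("f", "A" * L, "N" * L),
            UngappedPairBlock("f", "R" * L, "N" * L),
        ]
        counts = count_substitutions(blocks, {"f": family_weight(3, "f")})
        # oracle: unweighted column count divided by the number of pairs
        unweighted = sum(b.length for b in blocks)
        assert counts.total == pytest.approx(unweighted / 3)
        assert counts.total == pytest.approx(L)

    def test_families_of_different_size_contribute_equal_mass(self):
        small = count_substitutions(
            [UngappedPairBlock("s", "ARND", "ARND")], {"s": family_weight(2, "s")}
        )
        big = count_substitutions(
            [UngappedPairBlock("b", "ARND", "ARND")] * 6, {"b": family_weight(4, "b")}
        )
        assert small.total == pytest.approx(big.total)

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            count_substitutions([UngappedPairBlock("f", "A", "A")], {})

    def test_gap_character_rejected(self):
        with pytest.raises(ValueError):
            UngappedPairBlock("f", "A-", "AR")


class TestLogOdds:
    def test_two_letter_toy_example(self):
        f = np.zeros((20, 20))
        f[idx("A"), idx("A")] = 9
        f[idx("R"), idx("R")] = 9
        f[idx("A"), idx("R")] = f[idx("R"), idx("A")] = 2
        m = estimate_log_odds(WeightedCounts(f=f), LogOddsParams(pseudocount=0))
        assert m["A", "A"] == 2
        assert m["R", "R"] == 2
        assert m["A", "R"] == -5

    def test_counts_at_expected_frequencies_score_zero(self):
        p = skewed_frequencies()
        f = 2 * np.outer(p, p) * 1000
        np.fill_diagonal(f, p**2 * 1000)
        m = estimate_log_odds(
            WeightedCounts(f=f), LogOddsParams(pseudocount=0, rounding="none")
        )
        assert np.allclose(m.scores, 0.0, atol=1e-9)

    def test_doubling_counts_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        f = np.abs(rng.normal(1, 1, (20, 20))) + 0.1
        f = f + f.T
        m1 = estimate_log_odds(WeightedCounts(f=f), LogOddsParams(pseudocount=0))
        m2 = estimate_log_odds(WeightedCounts(f=2 * f), LogOddsParams(pseudocount=0))
        assert np.array_equal(m1.scores, m2.scores)

    def test_zero_cell_without_pseudocount_names_pair(self):
        f = np.zeros((20, 20))
        f[idx("A"), idx("A")] = 5
        f[idx("R"), idx("R")] = 5
        # A and R observed but never substituting for each other
        with pytest.raises(ValueError, match=r"\('A', 'R'\)"):
            estimate_log_odds(WeightedCounts(f=f), LogOddsParams(pseudocount=0))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_log_odds(WeightedCounts(f=np.zeros((20, 20))))

    def test_output_symmetric_and_integer(self):
        rng = np.random.default_rng(2)
        f = np.abs(rng.normal(1, 1, (20, 20))) + 0.05
        f = f + f.T
        m = estimate_log_odds(WeightedCounts(f=f))
        assert np.array_equal(m.scores, m.scores.T)
        assert m.integer_valued


def equal_length_families(n_fams=6, n_members=3, length=400, divergence=0.35, seed=0):
    process = SubstitutionProcess(skewed_frequencies(), divergence)
    toys = simulate_families(n_fams, n_members, length, process, seed=seed)
    return [t.family for t in toys], toys[0].pair_process


class TestBuildMatrix:
    def test_identical_members_all_filtered(self):
        fam = Family(
            "f",
            [FamilyMember("a", "ARNDCQEGHILKM"), FamilyMember("b", "ARNDCQEGHILKM")],
        )
        with pytest.raises(ValueError, match="empty counts"):
            sm.build_matrix([fam], identity_threshold=0.62)

    def test_no_filter_yields_diagonal_dominant_matrix(self):
        fam = Family(
            "f",
            [FamilyMember("a", "ARNDCQEGHILKM"), FamilyMember("b", "ARNDCQEGHILKM")],
        )
        matrix, report = sm.build_matrix([fam], identity_threshold=1.0)
        assert report.pairs_aligned == 1
        observed = [i for i, a in enumerate(AA) if a in "ARNDCQEGHILKM"]
        diag = matrix.scores[observed, observed]
        assert (diag > 0).all()

    def test_lowering_threshold_never_retains_more_pairs(self):
        families, _ = equal_length_families(n_fams=4, divergence=0.2, seed=3)
        kept = []
        for thr in [1.0, 0.62, 0.4, 0.0]:
            try:
                _, report = sm.build_matrix(families, identity_threshold=thr)
                kept.append(report.pairs_aligned)
            except ValueError:
                kept.append(0)
        assert all(x >= y for x, y in zip(kept, kept[1:]))

    def test_small_family_skipped_with_warning(self):
        families, _ = equal_length_families(n_fams=2, seed=4)
        families.append(Family("lonely", [FamilyMember("only", "ARND")]))
        with pytest.warns(UserWarning, match="lonely"):
            _, report = sm.build_matrix(families, identity_threshold=1.0)
        assert report.n_families_used == 2

    def test_deterministic_rebuild(self):
        families, _ = equal_length_families(n_fams=3, seed=5)
        m1, r1 = sm.build_matrix(families)
        m2, r2 = sm.build_matrix(families)
        assert np.array_equal(m1.scores, m2.scores)
        assert vars(r1) == vars(r2)

    def test_recovers_generator_log_odds(self):
        families, pair_process = equal_length_families(
            n_fams=25, n_members=3, length=1200, seed=6
        )
        matrix, _ = sm.build_matrix(families)
        analytic = pair_process.analytic_log_odds()
        assert np.abs(matrix.scores - analytic.scores).max() <= 1

    def test_unrounded_error_shrinks_with_data(self):
        process = SubstitutionProcess(skewed_frequencies(), 0.35)
        errors = []
        for n_fams, length in [(4, 300), (40, 1500)]:
            toys = simulate_families(n_fams, 3, length, process, seed=7)
            matrix, _ = sm.build_matrix(
                [t.family for t in toys],
                params=LogOddsParams(rounding="none"),
            )
            analytic = toys[0].pair_process.analytic_log_odds(rounding=False)
            errors.append(np.abs(matrix.scores - analytic.scores).max())
        assert errors[1] < errors[0]


@pytest.fixture(scope="module")
def families():
    fams, _ = equal_length_families(n_fams=6, length=250, seed=8)
    return fams


class TestConvergence:

    def test_full_subset_has_zero_difference(self, families):
        records = sm.convergence_curve(families, [6], replicates=3, seed=0)
        assert records[0]["mean"] == 0.0
        assert records[0]["std"] == 0.0

    def test_single_replicate_has_zero_std(self, families):
        records = sm.convergence_curve(families, [2, 4], replicates=1, seed=1)
        assert all(r["std"] == 0.0 for r in records)

    def test_bad_subset_size_rejected(self, families):
        with pytest.raises(ValueError):
            sm.convergence_curve(families, [0], replicates=1)
        with pytest.raises(ValueError):
            sm.convergence_curve(families, [99], replicates=1)

    def test_seeded_reproducibility(self, families):
        r1 = sm.convergence_curve(families, [2, 3], replicates=5, seed=9)
        r2 = sm.convergence_curve(families, [2, 3], replicates=5, seed=9)
        assert r1 == r2
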
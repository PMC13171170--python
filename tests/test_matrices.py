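"""Matrix container, NCBI-format I/O, and comparison statistics."""

import numpy as np
import pytest

import substmat as sm
from substmat.matrices import MatrixFormatError, MatrixSymmetryError, parse_matrix

from conftest import random_matrix


class TestParsing:
    def test_blosum62_spot_values(self, b62):
        assert b62["A", "A"] == 4
        assert b62["W", "W"] == 11
        assert b62["A", "R"] == -1
        assert b62.integer_valued

    def test_extended_codes_dropped(self, b62):
        # append B/Z/X/* rows and columns to a canonical table
        header = list(sm.CANONICAL_ALPHABET) + ["B", "Z", "X", "*"]
        lines = ["   " + " ".join(header)]
        for i, a in enumerate(header):
            if a in sm.CANONICAL_ALPHABET:
                row = [str(int(b62.scores[i, j])) for j in range(20)] + ["0", "0", "0", "-4"]
            else:
                row = ["0"] * 20 + ["1", "1", "1", "1"]
            lines.append(a + " " + " ".join(row))
        m = parse_matrix("\n".join(lines))
        assert m.alphabet == sm.CANONICAL_ALPHABET
        assert np.array_equal(m.scores, b62.scores)

    def test_asymmetric_input_names_pair(self, b62):
        text = sm.write_matrix(b62)
        lines = text.splitlines()
        # corrupt the (A, R) entry in the A row only
        fields = lines[2].split()
        fields[2] = "99"
        lines[2] = " ".join(fields)
        with pytest.raises(MatrixSymmetryError, match=r"\(A,R\)"):
            parse_matrix("\n".join(lines))

    def test_missing_residue_is_format_error(self, b62):
        text = "\n".join(
            line for line in sm.write_matrix(b62).splitlines() if not line.startswith("W")
        )
        with pytest.raises(MatrixFormatError, match="W"):
            parse_matrix(text)

    def test_comments_ignored(self, b62):
        text = "# a comment\n\n" + sm.write_matrix(b62)
        assert np.array_equal(parse_matrix(text).scores, b62.scores)

    def test_round_trip_integer_exact(self, standard_matrices):
        for name, m in standard_matrices.items():
            again = parse_matrix(sm.write_matrix(m), name=name)
            assert np.array_equal(again.scores, m.scores)

    def test_round_trip_float_within_tolerance(self, rng):
        m = random_matrix(rng, integer=False)
        again = parse_matrix(sm.write_matrix(m))
        assert np.allclose(again.scores, m.scores, atol=1e-4)


class TestEmbeddedTables:
    """The embedded standard tables match independently distributed copies."""

    @pytest.mark.parametrize("name", ["BLOSUM45", "BLOSUM62", "PAM250"])
    def test_matches_biopython(self, name, standard_matrices):
        from Bio.Align import substitution_matrices

        ref = substitution_matrices.load(name)
        idx = [ref.alphabet.index(a) for a in sm.CANONICAL_ALPHABET]
        expected = np.array(ref)[np.ix_(idx, idx)]
        assert np.array_equal(standard_matrices[name].scores, expected)

    def test_pam120_matches_biotite(self, standard_matrices):
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        alph = bseq.ProteinSequence.alphabet
        ref = balign.SubstitutionMatrix(alph, alph, "PAM120").score_matrix()
        idx = [alph.encode(a) for a in sm.CANONICAL_ALPHABET]
        expected = np.asarray(ref)[np.ix_(idx, idx)]
        assert np.array_equal(standard_matrices["PAM120"].scores, expected)

    def test_blosum80_is_half_bit_variant(self, standard_matrices):
        # the half-bit table differs from the 1/3-bit one Biopython ships
        m = standard_matrices["BLOSUM80"]
        assert m["A", "A"] == 5 and m["W", "W"] == 11


class TestUnitMatrix:
    @pytest.mark.parametrize(
        "match,mismatch", [(5, 0), (1, 0), (5, -1)]
    )
    def test_values(self, match, mismatch):
        m = sm.unit_matrix(match, mismatch)
        assert np.all(np.diag(m.scores) == match)
        off = m.scores[~np.eye(20, dtype=bool)]
        assert np.all(off == mismatch)
        assert off.size == 380


class TestCorrelation:
    def test_self_correlation(self, b62):
        assert sm.pearson_correlation(b62, b62) == pytest.approx(1.0)

    def test_negation(self, b62):
        neg = sm.SubstitutionMatrix(name="-B62", scores=-b62.scores)
        assert sm.pearson_correlation(b62, neg) == pytest.approx(-1.0)

    def test_unit_matrix_vs_blosum62(self, b62):
        corr = sm.pearson_correlation(sm.unit_matrix(1, 0), b62)
        assert round(corr, 2) == 0.72

    def test_symmetry(self, b62, standard_matrices):
        pam = standard_matrices["PAM250"]
        assert sm.pearson_correlation(b62, pam) == pytest.approx(
            sm.pearson_correlation(pam, b62)
        )

    def test_affine_invariance(self, b62, standard_matrices, rng):
        pam = standard_matrices["PAM250"]
        base = sm.pearson_correlation(b62, pam)
        for a, b in [(2.0, 0.0), (0.5, 3.0), (10.0, -7.0)]:
            scaled = sm.SubstitutionMatrix(name="s", scores=a * pam.scores + b)
            assert sm.pearson_correlation(b62, scaled) == pytest.approx(base)

    def test_unique_vectorization_differs(self, b62):
        full = sm.pearson_correlation(sm.unit_matrix(1, 0), b62, "full")
        unique = sm.pearson_correlation(sm.unit_matrix(1, 0), b62, "unique")
        assert full != pytest.approx(unique)

    def test_constant_matrix_rejected(self, b62):
        with pytest.raises(ValueError, match="constant"):
            sm.pearson_correlation(sm.unit_matrix(1, 1), b62)


class TestEvolutionaryDistance:
    def test_unit_5_minus1(self):
        assert sm.evolutionary_distance(sm.unit_matrix(5, -1)) == pytest.approx(5.0)

    def test_unit_5_0_undefined(self):
        assert sm.evolutionary_distance(sm.unit_matrix(5, 0)) is None

    def test_scaling_invariance(self, standard_matrices):
        for m in standard_matrices.values():
            base = sm.evolutionary_distance(m)
            scaled = sm.SubstitutionMatrix(name="s", scores=3.5 * m.scores)
            assert sm.evolutionary_distance(scaled) == pytest.approx(base)


class TestIdenticalFraction:
    def test_identical(self, b62):
        assert sm.identical_fraction(b62, b62) == 1.0

    def test_unit_matrices_share_only_diagonal(self):
        frac = sm.identical_fraction(sm.unit_matrix(5, 0), sm.unit_matrix(5, -1))
        assert frac == pytest.approx(20 / 210)

    def test_single_changed_entry(self, b62):
        scores = b62.scores.copy()
        scores[0, 1] += 1
        scores[1, 0] += 1
        changed = sm.SubstitutionMatrix(name="c", scores=scores)
        assert sm.identical_fraction(b62, changed) == pytest.approx(209 / 210)

    def test_symmetric_in_arguments(self, b62, standard_matrices):
        pam = standard_matrices["PAM250"]
        assert sm.identical_fraction(b62, pam) == sm.identical_fraction(pam, b62)

    def test_requires_integer_matrices(self, b62, rng):
        with pytest.raises(ValueError, match="integer"):
            sm.identical_fraction(b62, random_matrix(rng, integer=False))


class TestPca:
    def test_duplicates_get_identical_coordinates(self, b62, standard_matrices):
        coords, _ = sm.matrix_pca([b62, b62, standard_matrices["PAM250"]])
        assert np.allclose(coords[0], coords[1])

    def test_two_matrices_span_one_component(self, b62, standard_matrices):
        _, evr = sm.matrix_pca([b62, standard_matrices["PAM250"]])
        assert evr[0] == pytest.approx(1.0)
        assert evr[1] == pytest.approx(0.0, abs=1e-9)

    def test_explained_variance_ordered_and_bounded(self, standard_matrices):
        _, evr = sm.matrix_pca(list(standard_matrices.values()))
        assert evr[0] >= evr[1] >= 0
        assert evr.sum() <= 1 + 1e-12

    def test_shift_leaves_pairwise_distances(self, standard_matrices):
        ms = list(standard_matrices.values())
        shifted = [
            sm.SubstitutionMatrix(name=m.name, scores=m.scores + 7.0) for m in ms
        ]
        c1, _ = sm.matrix_pca(ms)
        c2, _ = sm.matrix_pca(shifted)
        d1 = np.linalg.norm(c1[:, None] - c1[None, :], axis=-1)
        d2 = np.linalg.norm(c2[:, None] - c2[None, :], axis=-1)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_against_brute_force_eigendecomposition(self, standard_matrices):
        ms = list(standard_matrices.values())[:5]
        X = np.stack([m.unique_entries() for m in ms])
        Xc = X - X.mean(axis=0)
        # brute-force: pairwise distances in the top-2 eigenspace of the Gram matrix
        gram = Xc @ Xc.T
        w, v = np.linalg.eigh(gram)
        proj = v[:, ::-1][:, :2] * np.sqrt(np.maximum(w[::-1][:2], 0.0))
        coords, _ = sm.matrix_pca(ms)
        d_expected = np.linalg.norm(proj[:, None] - proj[None, :], axis=-1)
        d_actual = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d_actual, d_expected, atol=1e-8)

    def test_requires_two_matrices(self, b62):
        with pytest.raises(ValueError):
            sm.matrix_pca([b62])


def test_symmetry_enforced_on_construction():
    scores = np.zeros((20, 20))
    scores[0, 1] = 1.0
    with pytest.raises(MatrixSymmetryError):
        sm.SubstitutionMatrix(name="bad", scores=scores)


def test_summarize_reports_table_row(b62, standard_matrices):
    row = sm.summarize(standard_matrices["PAM250"], reference=b62)
    assert row.evo_dist == pytest.approx(3.9, abs=0.05)
    assert round(100 * row.corr_to_reference) == 84
    assert 0 <= row.identical_fraction <= 1
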
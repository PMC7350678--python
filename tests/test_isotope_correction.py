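"""Natural-abundance correction: formula parsing, isotope-pattern arithmetic
against a brute-force enumeration oracle, and NNLS deconvolution."""

import itertools

import numpy as np
import pytest

from autoplot import (DEFAULT_ISOTOPES, TracerSpec, ValidationError,
                      build_correction_matrix, correct_mid,
                      natural_distribution, parse_formula)


class TestFormulaParsing:
    @pytest.mark.parametrize("text, expected", [
        ("C10H16N5O13P3", {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3}),  # ATP
        ("C10H17N3O6S", {"C": 10, "H": 17, "N": 3, "O": 6, "S": 1}),     # GSH
        ("CH4", {"C": 1, "H": 4}),
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ])
    def test_known_formulas(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["SiO2", "NaCl", "C6H5Br", "", "123", "c3"])
    def test_unsupported_or_malformed(self, bad):
        with pytest.raises(ValidationError):
            parse_formula(bad)


def enumeration_oracle(formula, tracer, labelled, purity, carbon_only):
    """Exhaustive enumeration over every per-atom isotope assignment.

    Each atom independently carries one of its isotope options; the molecule's
    mass-shift distribution is the sum over all assignments of the product of
    per-atom probabilities. Only feasible for a handful of atoms.
    """
    symbol = {"C13": "C", "N15": "N", "H2": "H"}[tracer]
    atoms = []
    for element, count in formula.items():
        options = [(0, 1.0 - sum(a for _, a in DEFAULT_ISOTOPES[element]))]
        options += [(s, a) for s, a in DEFAULT_ISOTOPES[element]]
        n_natural = count - (labelled if element == symbol else 0)
        if element == symbol:
            atoms += [[(1, purity), (0, 1.0 - purity)]] * labelled
        if element == symbol or not carbon_only:
            atoms += [options] * n_natural
        # non-tracer elements are invisible in carbon_only mode
    dist = {}
    for combo in itertools.product(*atoms):
        shift = sum(s for s, _ in combo)
        prob = np.prod([p for _, p in combo])
        dist[shift] = dist.get(shift, 0.0) + prob
    out = np.zeros(max(dist) + 1)
    for shift, prob in dist.items():
        out[shift] = prob
    return out


class TestNaturalDistribution:
    def test_three_carbon_molecule(self):
        """Binomial(3, 1.1%): the M+1 species of a 3-carbon molecule like
        pyruvate is about 3% of the pool."""
        dist = natural_distribution("C3", carbon_only=True)
        p = 0.011
        expected = [(1 - p) ** 3, 3 * p * (1 - p) ** 2, 3 * p ** 2 * (1 - p),
                    p ** 3]
        np.testing.assert_allclose(dist, expected, rtol=1e-12)
        assert dist[1] == pytest.approx(0.0323, abs=1e-4)

    def test_ten_carbon_molecule(self):
        """Binomial(10, 1.1%): M+1 of a 10-carbon molecule (ATP) is ~10%."""
        dist = natural_distribution("C10", carbon_only=True)
        assert dist[1] == pytest.approx(10 * 0.011 * 0.989 ** 9, rel=1e-12)
        assert dist[1] == pytest.approx(0.0996, abs=5e-4)

    def test_delta_distribution_without_natural_abundance(self):
        isotopes = {e: () for e in DEFAULT_ISOTOPES}
        dist = natural_distribution("C5", TracerSpec("C13", 1.0), labelled=3,
                                    isotopes=isotopes, carbon_only=True)
        expected = np.zeros(len(dist))
        expected[3] = 1.0
        np.testing.assert_allclose(dist, expected)

    @pytest.mark.parametrize("formula, labelled, purity, carbon_only", [
        ({"C": 3}, 0, 1.0, True),
        ({"C": 3}, 2, 0.97, True),
        ({"C": 2, "O": 2}, 1, 0.99, False),
        ({"C": 1, "H": 1, "N": 1, "O": 1, "S": 1}, 0, 1.0, False),
        ({"C": 2, "S": 2, "P": 2}, 2, 0.95, False),
        ({"N": 3, "O": 2}, 1, 0.98, False),
    ])
    def test_matches_enumeration_oracle(self, formula, labelled, purity,
                                        carbon_only):
        tracer_name = "N15" if "C" not in formula else "C13"
        oracle = enumeration_oracle(formula, tracer_name, labelled, purity,
                                    carbon_only)
        dist = natural_distribution(formula, TracerSpec(tracer_name, purity),
                                    labelled, carbon_only=carbon_only)
        n = min(len(oracle), len(dist))
        np.testing.assert_allclose(dist[:n], oracle[:n], atol=1e-12)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_purity_monotonicity(self):
        """Lower purity moves mass from the nominal shift to lower shifts."""
        high = natural_distribution("C6", TracerSpec("C13", 1.0), labelled=4,
                                    carbon_only=True)
        low = natural_distribution("C6", TracerSpec("C13", 0.9), labelled=4,
                                   carbon_only=True)
        # cumulative mass below any shift can only grow as purity drops
        assert all(low[:k + 1].sum() >= high[:k + 1].sum() - 1e-15
                   for k in range(len(high)))

    def test_labelled_beyond_atom_count_is_error(self):
        with pytest.raises(ValidationError):
            natural_distribution("C3", labelled=4)


class TestCorrectionMatrix:
    def test_identity_without_natural_abundance(self):
        isotopes = {e: () for e in DEFAULT_ISOTOPES}
        cm = build_correction_matrix("C4", TracerSpec("C13", 1.0),
                                     isotopes=isotopes, carbon_only=True)
        np.testing.assert_allclose(cm.matrix, np.eye(5))

    def test_column_zero_top_entry(self):
        cm = build_correction_matrix("C3", carbon_only=True)
        assert cm.matrix[0, 0] == pytest.approx(0.989 ** 3, rel=1e-12)

    def test_probability_bounds(self):
        cm = build_correction_matrix("C10H16N5O13P3", TracerSpec("C13", 0.98),
                                     carbon_only=False)
        assert np.all(cm.matrix >= 0) and np.all(cm.matrix <= 1)
        assert np.all(cm.matrix.sum(axis=0) <= 1 + 1e-12)


class TestCorrectMid:
    def test_identity_matrix_is_noop(self):
        isotopes = {e: () for e in DEFAULT_ISOTOPES}
        cm = build_correction_matrix("C3", TracerSpec("C13", 1.0),
                                     isotopes=isotopes, carbon_only=True)
        measured = np.array([5.0, 2.0, 1.0, 0.5])
        corrected, residual = correct_mid(measured, cm)
        np.testing.assert_allclose(corrected, measured)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_forward_simulation_round_trip(self):
        """correct_mid(matrix @ x) recovers x for random non-negative x."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            n_c = int(rng.integers(3, 11))
            purity = float(rng.uniform(0.95, 1.0))
            cm = build_correction_matrix({"C": n_c}, TracerSpec("C13", purity),
                                         carbon_only=True)
            x = rng.dirichlet(np.ones(n_c + 1))
            corrected, _ = correct_mid(cm.matrix @ x, cm)
            worst = max(worst, np.abs(corrected - x).max())
        assert worst < 1e-6

    def test_all_zero_measured_corrects_to_zero(self):
        cm = build_correction_matrix("C3", carbon_only=True)
        corrected, residual = correct_mid(np.zeros(4), cm)
        np.testing.assert_array_equal(corrected, 0.0)
        assert residual == 0.0

    def test_nan_entries_warn_and_become_zero(self):
        cm = build_correction_matrix("C2", carbon_only=True)
        with pytest.warns(UserWarning, match="missing"):
            corrected, _ = correct_mid(np.array([1.0, np.nan, 0.0]), cm)
        assert np.all(corrected >= 0)

    def test_natural_abundance_only_signal_collapses_to_m0(self):
        """A pure natural-abundance pattern for a 10-carbon compound corrects
        to an essentially unlabelled state (everything in M+0)."""
        cm = build_correction_matrix("C10H16N5O13P3", carbon_only=True)
        measured = 1e7 * cm.matrix[:, 0]
        corrected, _ = correct_mid(measured, cm)
        assert corrected[0] / corrected.sum() >= 0.999

    def test_signal_conservation_within_truncation(self):
        """The corrected total can only exceed the measured total by the
        truncated tail mass (column sums are <= 1)."""
        cm = build_correction_matrix("C6", TracerSpec("C13", 0.99),
                                     carbon_only=True)
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, cm.n_labelled)
        measured = cm.matrix @ x
        corrected, _ = correct_mid(measured, cm)
        assert corrected.sum() >= measured.sum() - 1e-9
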
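import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from npfrag.chem import ElementComposition, MONOISOTOPIC_MASS, monoisotopic_mass
from npfrag.errors import ConfigurationError
from npfrag.formulas import (
    decompose_mass,
    default_neutral_losses,
    effective_tolerance,
    infer_formulas,
    mass_error_score,
    neutral_loss_score,
    rdbe,
)
from npfrag.spectra import Spectrum, normalize_spectrum


class TestMassErrorScore:
    def test_zero_error_scores_one(self):
        assert mass_error_score(100.0, 100.0) == 1.0

    def test_error_equal_to_delta(self):
        assert mass_error_score(100.005, 100.0, 0.005) == pytest.approx(
            math.exp(-0.5)
        )

    def test_error_twice_delta(self):
        assert mass_error_score(100.010, 100.0, 0.005) == pytest.approx(
            math.exp(-2.0)
        )

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ConfigurationError):
            mass_error_score(1.0, 1.0, 0.0)

    @given(st.floats(min_value=1e-6, max_value=0.1))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_in_sign(self, err):
        assert mass_error_score(100 + err, 100.0) == pytest.approx(
            mass_error_score(100 - err, 100.0)
        )

    @given(
        st.floats(min_value=0.0, max_value=0.05),
        st.floats(min_value=1e-4, max_value=0.05),
    )
    @settings(max_examples=30, deadline=None)
    def test_strictly_decreasing_in_error(self, err, extra):
        a = mass_error_score(100 + err, 100.0)
        b = mass_error_score(100 + err + extra, 100.0)
        assert b < a


class TestInferFormulas:
    @pytest.mark.parametrize(
        "mz,adduct,expected",
        [
            (285.2064, "[M-H]-", "C16H30O4"),
            (294.0837, "[M+FA-H]-", "C9H15NO7"),
            (210.0767, "[M-H]-", "C10H13NO4"),
        ],
    )
    def test_published_precursor_examples(self, mz, adduct, expected):
        cands = infer_formulas(mz, "negative", [adduct], tol_mda=5)
        assert expected in [c.composition.formula() for c in cands]

    def test_sorted_by_score(self):
        cands = infer_formulas(285.2064, "negative", tol_mda=5)
        scores = [c.mass_error_score for c in cands]
        assert scores == sorted(scores, reverse=True)

    def test_empty_result_is_allowed(self):
        assert infer_formulas(19.5, "negative", ["[M-H]-"], tol_mda=1) == []

    def test_reference_library_lookup(self):
        ref = [
            (ElementComposition.from_formula(f), monoisotopic_mass(
                ElementComposition.from_formula(f)))
            for f in ("C16H30O4", "C6H12O6")
        ]
        cands = infer_formulas(
            285.2064, "negative", ["[M-H]-"], tol_mda=5, reference=ref
        )
        assert [c.composition.formula() for c in cands] == ["C16H30O4"]

    def test_larger_tolerance_window_wins(self):
        # at m/z 1000, 10 ppm = 10 mDa > 5 mDa
        assert effective_tolerance(1000.0, 5.0, 10.0) == pytest.approx(0.01)
        assert effective_tolerance(100.0, 5.0, 10.0) == pytest.approx(0.005)


class TestDecomposeMass:
    def test_agrees_with_exhaustive_search(self):
        """Bounded decomposition equals a plain brute-force grid scan."""
        bounds = {"C": 15, "H": 30, "N": 4, "O": 8, "P": 1, "S": 1}
        target, tol = 180.0634, 0.005  # glucose mass region

        def oracle():
            out = set()
            for c, n, o, p, s in itertools.product(
                range(bounds["C"] + 1),
                range(bounds["N"] + 1),
                range(bounds["O"] + 1),
                range(bounds["P"] + 1),
                range(bounds["S"] + 1),
            ):
                heavy = (
                    c * MONOISOTOPIC_MASS["C"]
                    + n * MONOISOTOPIC_MASS["N"]
                    + o * MONOISOTOPIC_MASS["O"]
                    + p * MONOISOTOPIC_MASS["P"]
                    + s * MONOISOTOPIC_MASS["S"]
                )
                for h in range(bounds["H"] + 1):
                    mass = heavy + h * MONOISOTOPIC_MASS["H"]
                    if abs(mass - target) > tol:
                        continue
                    comp = ElementComposition.from_dict(
                        {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s}
                    )
                    if comp.is_empty:
                        continue
                    r = rdbe(comp)
                    if r < 0 or abs(r - round(r)) > 1e-9:
                        continue
                    out.add(comp.counts)
            return out

        got = {c.counts for c in decompose_mass(target, tol, bounds)}
        assert got == oracle()

    def test_glucose_found(self):
        comps = decompose_mass(180.0634, 0.005)
        assert "C6H12O6" in [c.formula() for c in comps]


def _spec(peaks):
    return normalize_spectrum(
        Spectrum(id="s", precursor_mz=500.0, ion_mode="negative", peaks=tuple(peaks))
    )


class TestNeutralLossScore:
    def test_no_matching_differences(self):
        s = _spec([(100.0, 1.0), (137.0, 1.0)])
        assert neutral_loss_score(s) == 0.0

    def test_single_water_loss_pair(self):
        s = _spec([(100.0, 1.0), (118.010565, 1.0)])
        # equal normalized intensities 0.5/0.5, exact difference -> MES 1
        assert neutral_loss_score(s) == pytest.approx(0.5, abs=1e-6)

    def test_never_exceeds_one(self):
        losses = default_neutral_losses()
        peaks = [(100.0 + e.mass, 1.0) for e in losses[:8]] + [(100.0, 1.0)]
        s = _spec(peaks)
        assert neutral_loss_score(s) <= 1.0
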
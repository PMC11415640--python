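import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npfrag.chem import ElementComposition, parse_molecule
from npfrag.errors import ConfigurationError
from npfrag.fragmenter import CleavageSet, FragmentIon
from npfrag.fixtures import simulate_spectrum
from npfrag.scoring import (
    BdeIntensityModel,
    CandidateScore,
    cosine_score,
    explained_intensity,
    final_score,
    fragment_mes,
    match_peaks,
    meta_score,
    predict_spectrum,
    rank_candidates,
    rt_score,
    structure_score,
)
from npfrag.spectra import Spectrum, normalize_spectrum


def _ion(mz, formula="C6H5O", charge=-1, bonds=None):
    return FragmentIon(
        composition=ElementComposition.from_formula(formula, charge),
        theoretical_mz=mz,
        polarity="negative" if charge < 0 else "positive",
        h_shift_total=0,
        neutral_loss=ElementComposition(),
        depth=1,
        cleavage=None if bonds is None else CleavageSet(bonds, "acyclic", len(bonds), 0),
        n_bonds_cleaved=0 if bonds is None else len(bonds),
    )


def _spec(peaks, mode="negative", precursor=300.0):
    return normalize_spectrum(
        Spectrum("q", precursor, mode, tuple(peaks))
    )


class TestMatchPeaks:
    def test_no_fragment_in_tolerance(self):
        s = _spec([(100.0, 1.0)])
        assert match_peaks(s, [_ion(150.0)]) == []

    def test_exact_match_has_mes_one(self):
        s = _spec([(100.0, 1.0)])
        matches = match_peaks(s, [_ion(100.0)])
        assert len(matches) == 1
        assert matches[0].mes == 1.0

    def test_one_peak_one_fragment(self):
        # two fragments near one peak: only the nearest is used
        s = _spec([(100.0, 1.0)])
        far, near = _ion(100.010), _ion(100.002)
        matches = match_peaks(s, [far, near])
        assert len(matches) == 1
        assert matches[0].fragment is near

    def test_requires_normalized_spectrum(self):
        s = Spectrum("q", 300.0, "negative", ((100.0, 1.0),))
        with pytest.raises(ConfigurationError):
            match_peaks(s, [_ion(100.0)])

    def test_syringic_fixture_matches_all_four_printed_peaks(
        self, syringic_fragments_d3
    ):
        s = _spec(
            [(182.0217, 55.0), (166.9999, 20.0), (123.0072, 100.0), (95.0131, 40.0)],
            precursor=197.0455,
        )
        matches = match_peaks(s, syringic_fragments_d3)
        assert len(matches) >= 4


class TestSubScores:
    def test_all_matched_zero_error(self):
        s = _spec([(100.0, 1.0), (150.0, 1.0)])
        matches = match_peaks(s, [_ion(100.0), _ion(150.0)])
        assert structure_score(matches) == pytest.approx(1.0)
        assert fragment_mes(matches) == pytest.approx(1.0)

    def test_no_matches_scores_zero(self):
        assert structure_score([]) == 0.0
        assert fragment_mes([]) == 0.0

    def test_partial_match(self):
        s = _spec([(100.0, 0.6), (150.0, 0.4)])
        frag = _ion(100.0 + 0.013365)  # engineered error -> MES 0.8 at 20 mDa
        matches = match_peaks(s, [frag], tol_mda=20, tol_ppm=None)
        assert structure_score(matches) == pytest.approx(0.6)
        assert fragment_mes(matches) == pytest.approx(0.8, abs=1e-3)

    def test_explained_intensity_equals_s1_of_own_fragments(
        self, syringic, syringic_fragments_d3
    ):
        s = _spec(
            [(182.0217, 55.0), (123.0072, 100.0), (95.0131, 40.0)],
            precursor=197.0455,
        )
        matches = match_peaks(s, syringic_fragments_d3)
        assert explained_intensity(s, syringic_fragments_d3) == pytest.approx(
            structure_score(matches)
        )

    def test_meta_score_levels(self):
        assert [meta_score(k) for k in range(6)] == [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        with pytest.raises(ConfigurationError):
            meta_score(7)

    def test_rt_score_closed_forms(self):
        assert rt_score(5.0, 5.0) == pytest.approx(1 / (1 + math.exp(-1)))
        assert rt_score(5.0, 5.1, theta=0.1) == pytest.approx(0.5)

    def test_final_score_all_ones(self):
        assert final_score(1, 1, 1, 1, 1, 1) == pytest.approx(3.4)
        assert final_score(0, 0, 0, 0, 0, 0) == 0.0

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=6, max_size=6
        ),
        st.integers(min_value=0, max_value=5),
        st.floats(min_value=0.0, max_value=0.3),
    )
    @settings(max_examples=50, deadline=None)
    def test_final_score_monotone_in_each_subscore(self, scores, which, bump):
        which = which % 6
        bumped = list(scores)
        bumped[which] += bump
        assert final_score(*bumped) >= final_score(*scores)

    def test_candidate_score_final_formula(self):
        cs = CandidateScore(0.9, 0.8, 0.7, 0.6, 0.4, 0.0)
        assert cs.final == pytest.approx(0.9 + 0.1 * 0.8 + 0.2 * 0.7 + 0.1 * 0.6 + 0.4)


class _FixedBde(BdeIntensityModel):
    """Deterministic per-bond energies for arithmetic tests."""

    def __init__(self, energies):
        super().__init__(n_estimators=1)
        self._energies = np.asarray(energies, dtype=float)
        self._trained = True

    def predict(self, features):
        return self._energies[: len(features)]


class TestPredictSpectrum:
    def test_equal_bde_gives_equal_intensities(self):
        mol = parse_molecule("CCO")
        frags = [_ion(29.0, bonds=(0,)), _ion(31.0, bonds=(1,))]
        peaks = predict_spectrum(mol, frags, _FixedBde([300.0, 300.0]))
        assert [i for _, i in peaks] == pytest.approx([0.5, 0.5])

    def test_inverse_proportionality(self):
        mol = parse_molecule("CCO")
        frags = [_ion(29.0, bonds=(0,)), _ion(31.0, bonds=(1,))]
        peaks = dict(predict_spectrum(mol, frags, _FixedBde([100.0, 300.0])))
        assert peaks[29.0] == pytest.approx(0.75)
        assert peaks[31.0] == pytest.approx(0.25)

    def test_zero_fragments(self):
        mol = parse_molecule("CCO")
        assert predict_spectrum(mol, [], _FixedBde([1.0])) == []

    def test_untrained_model_errors(self):
        mol = parse_molecule("CCO")
        with pytest.raises(ConfigurationError):
            predict_spectrum(mol, [_ion(29.0, bonds=(0,))], BdeIntensityModel())


class TestCosineScore:
    def test_identical_spectra(self):
        s = _spec([(100.0, 0.3), (150.0, 0.7)])
        assert cosine_score(s, [(100.0, 0.3), (150.0, 0.7)]) == pytest.approx(1.0)

    def test_disjoint_spectra(self):
        s = _spec([(100.0, 0.5), (150.0, 0.5)])
        assert cosine_score(s, [(300.0, 0.5), (350.0, 0.5)]) == 0.0

    def test_empty_prediction(self):
        s = _spec([(100.0, 1.0)])
        assert cosine_score(s, []) == 0.0

    def test_matches_manual_cosine(self):
        s = _spec([(100.0, 3.0), (150.0, 4.0)])  # normalized to 3/7, 4/7
        predicted = [(100.0, 0.6), (150.0, 0.8)]
        a = np.array([3 / 7, 4 / 7])
        b = np.array([0.6, 0.8])
        manual = float((a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert cosine_score(s, predicted) == pytest.approx(manual, abs=1e-6)


class TestRanking:
    def test_ranking_invariant_to_input_order(self, panel, panel_fragments_d1):
        mol = panel[0]
        spec = simulate_spectrum(mol, "negative", seed=5)
        cands = [(c, panel_fragments_d1[c.meta.source_id]["negative"]) for c in panel]
        first = rank_candidates(spec, cands)
        second = rank_candidates(spec, list(reversed(cands)))
        assert [r.molecule.meta.source_id for r in first] == [
            r.molecule.meta.source_id for r in second
        ]

    def test_subscores_bounded(self, panel, panel_fragments_d1, bde_model):
        mol = panel[3]
        spec = simulate_spectrum(
            mol, "negative", seed=9, noise_sd_mda=5.0, n_decoy_peaks=2
        )
        cands = [(c, panel_fragments_d1[c.meta.source_id]["negative"]) for c in panel]
        for rc in rank_candidates(spec, cands, bde_model=bde_model):
            for value in (rc.score.s1, rc.score.s2, rc.score.s3, rc.score.s4, rc.score.s5):
                assert 0.0 <= value <= 1.0 + 1e-9
            assert 0.0 <= rc.score.s0 <= 2.0 + 1e-9

    def test_meta_score_can_be_disabled(self, panel, panel_fragments_d1):
        from npfrag.scoring import ScoringConfig

        mol = panel[0]
        spec = simulate_spectrum(mol, "negative", seed=5)
        cands = [(c, panel_fragments_d1[c.meta.source_id]["negative"]) for c in panel]
        ranked = rank_candidates(spec, cands, ScoringConfig(use_meta=False))
        assert all(rc.score.s4 == 0.0 for rc in ranked)
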
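"""Fragment-peak matching under tolerance, and candidate scoring."""

import pytest

from fragrank.constants import PROTON_MASS
from fragrank.chem_core import parse_structure
from fragrank.fragmenter import FragmenterConfig
from fragrank.fixtures import SimulationConfig, simulate_spectrum
from fragrank.matching_scoring import (
    MatchParams,
    ScoreParams,
    fragment_and_match,
    peak_weight,
    score_candidates,
    score_spectrum,
    within_tolerance,
)
from fragrank.rearrangements import default_rules
from fragrank.spectra import Peak, Spectrum


class TestWithinTolerance:
    def test_exact_match(self):
        p = MatchParams(mzabs=0.0, mzppm=0.0)
        assert within_tolerance(272.0680, 272.0680, p)

    def test_ppm_only_window(self):
        p = MatchParams(mzabs=0.0, mzppm=10.0)
        # 10 ppm of 272.068 is about 2.7 mDa
        assert within_tolerance(272.0680 + 0.0026, 272.0680, p)
        assert not within_tolerance(272.0680 + 0.0030, 272.0680, p)

    def test_combined_window_at_100(self):
        p = MatchParams(mzabs=0.01, mzppm=50.0)
        assert within_tolerance(100.0 + 0.0149, 100.0, p)
        assert not within_tolerance(100.0 + 0.0151, 100.0, p)

    def test_negative_tolerances_rejected(self):
        with pytest.raises(ValueError):
            MatchParams(mzabs=-0.01)


class TestPeakWeight:
    def test_zero_intensity_zero_weight(self):
        assert peak_weight(Peak(100.0, 0.0)) == 0.0

    def test_reference_value(self):
        w = peak_weight(Peak(100.0, 100.0), ScoreParams())
        assert w == pytest.approx(100 ** 0.6 * 100 ** 3, rel=1e-9)

    def test_mass_power_law(self):
        w1 = peak_weight(Peak(100.0, 5.0))
        w2 = peak_weight(Peak(200.0, 5.0))
        assert w2 / w1 == pytest.approx(8.0)


class TestFragmentAndMatch:
    def test_self_spectrum_fully_explained(self, toy):
        mol = toy["phenol"]
        spec = simulate_spectrum(mol, SimulationConfig(seed=5, n_peaks=5))
        out = fragment_and_match(
            mol, spec, FragmenterConfig(max_depth=2), MatchParams(mzabs=0.001, mzppm=10.0)
        )
        assert len(out.matches) == len(spec.peaks)

    def test_proton_offset_applied(self, toy):
        mol = toy["phenol"]
        spec = simulate_spectrum(mol, SimulationConfig(seed=5, n_peaks=5))
        out = fragment_and_match(
            mol, spec, FragmenterConfig(max_depth=2), MatchParams(mzabs=0.001, mzppm=10.0)
        )
        for m in out.matches:
            assert m.ion_mass == pytest.approx(m.fragment.neutral_mass + PROTON_MASS)

    def test_unreachably_light_peak_stays_unmatched(self, toy):
        mol = toy["phenol"]
        spec = Spectrum([Peak(5.0, 100.0)])
        out = fragment_and_match(mol, spec, FragmenterConfig(max_depth=2), MatchParams())
        assert out.matches == []

    def test_empty_spectrum_warns_and_matches_nothing(self, toy, caplog):
        with caplog.at_level("WARNING"):
            out = fragment_and_match(toy["phenol"], Spectrum([]), FragmenterConfig(), MatchParams())
        assert out.matches == [] and out.total_fragments == 0

    def test_epicatechin_water_loss_explains_dehydrated_ion(self, toy):
        # the [M+H-H2O]+ signal needs the rearrangement rule: plain bond
        # disconnection cannot remove OH plus a remote ring hydrogen
        mol = toy["epicatechin"]
        mz = 290.0790 + PROTON_MASS - 18.0106
        spec = Spectrum([Peak(mz, 100.0)])
        params = MatchParams(mzabs=0.002, mzppm=10.0)
        without = fragment_and_match(mol, spec, FragmenterConfig(max_depth=2), params)
        with_rules = fragment_and_match(
            mol, spec, FragmenterConfig(max_depth=2), params, default_rules()
        )
        assert without.matches == []
        assert len(with_rules.matches) == 1
        assert with_rules.matches[0].fragment.loss_tag == "H2O"

    def test_intrinsic_charge_matched_as_is_with_penalty(self):
        # quaternary ammonium: permanently charged, no proton needed
        mol = parse_structure("C[N+](C)(C)C", "smiles", id="tetramethylammonium")
        frag_mass = 3 * 12.0 + 14.0030740052 + 9 * 1.0078250319  # C3H9N+ piece
        spec = Spectrum([Peak(frag_mass, 100.0)])
        out = fragment_and_match(
            mol, spec, FragmenterConfig(max_depth=1, min_mass=20), MatchParams(mzabs=0.002, mzppm=10)
        )
        assert len(out.matches) == 1
        match = out.matches[0]
        assert match.intrinsic_charge
        assert match.ion_mass == pytest.approx(match.fragment.neutral_mass)
        assert match.effective_bde > match.fragment.bde

    def test_each_peak_explained_once(self, toy):
        mol = toy["glucose"]
        spec = simulate_spectrum(mol, SimulationConfig(seed=3, n_peaks=6))
        out = fragment_and_match(
            mol, spec, FragmenterConfig(max_depth=2), MatchParams(mzabs=0.001, mzppm=10.0)
        )
        assert len({m.peak for m in out.matches}) == len(out.matches)


class TestScoreCandidates:
    def test_single_candidate_with_matches(self):
        assert score_candidates([(10.0, 500.0)]) == [pytest.approx(0.5)]

    def test_identical_candidates_tie(self):
        scores = score_candidates([(10.0, 400.0), (10.0, 400.0)])
        assert scores[0] == scores[1]

    def test_superset_of_peaks_scores_no_lower(self):
        # same mean bond enthalpy, strictly larger weighted peak count
        scores = score_candidates([(15.0, 400.0), (10.0, 400.0)])
        assert scores[0] >= scores[1]

    def test_no_matches_anywhere_all_zero(self):
        assert score_candidates([(0.0, 0.0), (0.0, 0.0)]) == [0.0, 0.0]

    def test_zero_bde_term_when_no_bonds_broken(self):
        assert score_candidates([(10.0, 0.0)]) == [1.0]

    def test_bounds(self):
        raw = [(0.0, 900.0), (5.0, 100.0), (10.0, 450.0)]
        for s in score_candidates(raw):
            assert -0.5 <= s <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_candidates([])


class TestScoreSpectrum:
    def test_candidate_order_invariance(self, toy):
        mols = [toy["phenol"], toy["benzene"], toy["aniline"]]
        spec = simulate_spectrum(toy["phenol"], SimulationConfig(seed=5, n_peaks=5))
        params = MatchParams(mzabs=0.002, mzppm=10.0)
        fwd = score_spectrum(mols, spec, FragmenterConfig(max_depth=2), params)
        rev = score_spectrum(list(reversed(mols)), spec, FragmenterConfig(max_depth=2), params)
        assert {c.candidate_id: c.score for c in fwd} == {
            c.candidate_id: c.score for c in rev
        }

    def test_unmatched_candidate_keeps_zero_terms(self, toy):
        spec = simulate_spectrum(toy["phenol"], SimulationConfig(seed=5, n_peaks=5))
        scored = score_spectrum(
            [toy["phenol"], toy["propane"]],
            spec,
            FragmenterConfig(max_depth=2),
            MatchParams(mzabs=0.001, mzppm=10.0),
        )
        propane = next(c for c in scored if c.candidate_id == "propane")
        assert propane.weight == 0.0 and propane.mean_bde == 0.0
        assert propane.explained_peaks == 0
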
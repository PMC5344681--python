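"""Spectrum preprocessing, diagnostic triggering and the two search modes."""

import numpy as np
import pytest

from adprscan.masses import (
    ADENINE_ION_MZ,
    C13_C12,
    ModifiedPeptide,
    theoretical_fragments,
)
from adprscan.search import (
    SearchParams,
    acquisition_decision,
    detect_diagnostic_ion,
    enumerate_placements,
    preprocess_spectrum,
    score_psm,
    search_localization_free,
    search_variable_mod,
)
from adprscan.simulate import NoiseModel, simulate_etd, simulate_hcd
from adprscan.spectra import Spectrum


def make_spectrum(peaks, mode="HCD", mz=500.0, charge=2, title="t"):
    return Spectrum.from_peaks(title, mz, charge, mode, peaks)


class TestPreprocess:
    def test_overfull_window_truncated_to_top_n(self):
        peaks = [(100.0 + i, 1.0 + i) for i in range(25)]
        out = preprocess_spectrum(make_spectrum(peaks), top_n=20)
        assert len(out) == 20
        assert out.intensity.min() == 6.0  # the 5 weakest are gone

    def test_underfull_window_untouched(self):
        peaks = [(100.0 + i, 1.0) for i in range(5)]
        assert len(preprocess_spectrum(make_spectrum(peaks), top_n=20)) == 5

    def test_windows_filtered_independently(self):
        # 3 peaks in [100, 200), 3 in [200, 300); keep top 2 of each
        peaks = [(100, 5), (110, 4), (120, 3), (210, 30), (220, 20), (230, 10)]
        out = preprocess_spectrum(make_spectrum(peaks), top_n=2)
        assert out.mz.tolist() == [100, 110, 210, 220]

    def test_order_preserved(self):
        peaks = [(100 + i, float(i % 7)) for i in range(40)]
        out = preprocess_spectrum(make_spectrum(peaks), top_n=10)
        assert np.all(np.diff(out.mz) > 0)

    def test_invalid_top_n(self):
        with pytest.raises(ValueError):
            preprocess_spectrum(make_spectrum([(100, 1)]), top_n=0)


class TestDiagnosticIon:
    def test_exact_peak_at_rank_one(self):
        s = make_spectrum([(ADENINE_ION_MZ, 100.0), (500.0, 50.0)])
        assert detect_diagnostic_ion(s) == (True, 1)

    def test_empty_spectrum(self):
        s = make_spectrum([])
        assert detect_diagnostic_ion(s) == (False, None)

    def test_offset_beyond_tolerance_not_detected(self):
        s = make_spectrum([(136.0686, 100.0)])  # ~50 ppm away
        present, _ = detect_diagnostic_ion(s, tol_ppm=10)
        assert not present

    def test_weak_peak_below_relative_threshold(self):
        s = make_spectrum([(ADENINE_ION_MZ, 1.0), (500.0, 100.0)])
        present, rank = detect_diagnostic_ion(s, min_relative_intensity=0.05)
        assert not present and rank == 2

    def test_etd_spectrum_rejected(self):
        s = make_spectrum([(ADENINE_ION_MZ, 100.0)], mode="ETD")
        with pytest.raises(ValueError, match="HCD"):
            detect_diagnostic_ion(s)


class TestAcquisitionDecision:
    def test_diagnostic_plus_multiple_charge_triggers(self):
        s = make_spectrum([(ADENINE_ION_MZ, 100.0)], charge=3)
        assert acquisition_decision(s)

    def test_singly_charged_precursor_never_triggers(self):
        s = make_spectrum([(ADENINE_ION_MZ, 100.0)], charge=1)
        assert not acquisition_decision(s)

    def test_no_diagnostic_no_trigger(self):
        s = make_spectrum([(500.0, 100.0)], charge=3)
        assert not acquisition_decision(s)


class TestScore:
    def test_perfect_match_scores_n_plus_one(self):
        theo = [100.0, 200.0, 300.0, 400.0]
        s = make_spectrum([(mz, 10.0) for mz in theo])
        score, count, frac = score_psm(s, theo, 20)
        assert (score, count, frac) == (5.0, 4, 1.0)

    def test_disjoint_spectrum_scores_zero(self):
        s = make_spectrum([(150.0, 10.0), (250.0, 10.0)])
        score, count, frac = score_psm(s, [100.0, 200.0], 20)
        assert score == 0.0

    def test_half_matched_half_intensity(self):
        s = make_spectrum([(100.0, 10.0), (200.0, 10.0), (999.0, 10.0), (888.0, 10.0)])
        score, count, frac = score_psm(s, [100.0, 200.0, 300.0, 400.0], 20)
        assert count == 2 and frac == pytest.approx(0.5)
        assert score == pytest.approx(2.5)

    def test_each_peak_used_once(self):
        # two theoretical ions near one peak: only one may claim it
        s = make_spectrum([(100.0, 10.0)])
        score, count, _ = score_psm(s, [100.0, 100.0005], 20)
        assert count == 1

    def test_score_monotone_in_matched_peaks(self):
        theo = [100.0, 200.0, 300.0]
        fewer = score_psm(make_spectrum([(100.0, 5.0)]), theo, 20)[0]
        more = score_psm(make_spectrum([(100.0, 5.0), (200.0, 5.0)]), theo, 20)[0]
        assert more > fewer


class TestLocalizationFree:
    def test_exactly_two_hypotheses_per_candidate(self, demo_proteins, adpr_peptide, zero_noise):
        syn = simulate_hcd(adpr_peptide, 2, zero_noise)
        res = search_localization_free([syn.spectrum], demo_proteins)
        assert res.stats["hypotheses_generated"] == 2 * res.stats["candidates"]
        assert res.stats["candidates"] > 0

    def test_round_trip_identifies_adpr_peptide(self, demo_proteins, adpr_peptide, zero_noise):
        syn = simulate_hcd(adpr_peptide, 2, zero_noise)
        res = search_localization_free([syn.spectrum], demo_proteins)
        top = res[0]
        assert top.rank == 1
        assert top.peptide.sequence == "DWSAEQIR"
        assert top.is_adpr_hypothesis

    def test_empty_spectrum_set(self, demo_proteins):
        assert list(search_localization_free([], demo_proteins)) == []

    def test_empty_database(self, adpr_peptide, zero_noise):
        syn = simulate_hcd(adpr_peptide, 2, zero_noise)
        assert list(search_localization_free([syn.spectrum], [])) == []


class TestVariableMod:
    def test_hypothesis_counts(self, adpr):
        assert len(enumerate_placements("AKAAA", adpr, "S", 1)) == 0 + 1  # no site
        assert len(enumerate_placements("ASAAA", adpr, "S", 1)) == 2
        assert len(enumerate_placements("ASASAS", adpr, "S", 1)) == 4

    def test_round_trip_places_adpr_on_true_serine(self, demo_proteins, adpr, zero_noise):
        pep = ModifiedPeptide("DWSAEQIR", placements={3: adpr})
        syn = simulate_etd(pep, 3, zero_noise, title="vm")
        res = search_variable_mod([syn.spectrum], demo_proteins)
        top = res[0]
        assert top.peptide.sequence == "DWSAEQIR"
        assert sorted(top.peptide.placements) == [3]

    def test_isotope_offset_recovers_displaced_precursor(self, demo_proteins, adpr, zero_noise):
        pep = ModifiedPeptide("DWSAEQIR", placements={3: adpr})
        syn = simulate_etd(pep, 3, zero_noise, title="iso")
        for k in (1, 2, 3):
            shifted = Spectrum(
                "iso", syn.spectrum.precursor_mz + k * C13_C12 / 3, 3, "ETD",
                mz=syn.spectrum.mz, intensity=syn.spectrum.intensity)
            res = search_variable_mod([shifted], demo_proteins)
            assert res[0].peptide.sequence == "DWSAEQIR"
            assert res[0].isotope_offset == k

    def test_combinatorial_cap_skips_with_warning(self, demo_proteins, zero_noise, adpr):
        pep = ModifiedPeptide("DWSAEQIR", placements={3: adpr})
        syn = simulate_etd(pep, 3, zero_noise)
        params = SearchParams(max_hypotheses_per_peptide=1)
        with pytest.warns(UserWarning, match="exceed cap"):
            res = search_variable_mod([syn.spectrum], demo_proteins, params)
        assert len(res) == 0
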
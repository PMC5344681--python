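"""Site localization, serine validation and confidence filtering."""

import numpy as np
import pytest

from adprscan.localize import (
    SiteLocalization,
    ValidationThresholds,
    filter_confident,
    localization_probabilities,
    localize_spectrum,
    site_determining_ions,
    validate_serine_site,
)
from adprscan.masses import ModifiedPeptide, theoretical_fragments
from adprscan.peptides import PARP1_START, h3_wt_peptide, parp1_wt_peptide
from adprscan.search import PSM, search_variable_mod
from adprscan.simulate import NoiseModel, simulate_etd
from adprscan.spectra import Spectrum


def unlocalized(p: ModifiedPeptide) -> ModifiedPeptide:
    return ModifiedPeptide(p.sequence, n_term=p.n_term, c_term=p.c_term)


class TestLocalization:
    def test_h3_serine10_localized_with_high_probability(self, zero_noise, adpr):
        p = h3_wt_peptide()
        syn = simulate_etd(p, 3, zero_noise)
        loc = localize_spectrum(syn.spectrum, unlocalized(p), adpr, "ST", protein_start=1)
        assert loc.best_site == 10
        assert loc.protein_site() == 10
        assert loc.best_probability > 0.9
        assert loc.best_site_label == "S10"

    def test_parp1_third_serine_maps_to_protein_507(self, zero_noise, adpr):
        p = parp1_wt_peptide(site=14)  # third serine of the construct
        syn = simulate_etd(p, 4, zero_noise)
        loc = localize_spectrum(syn.spectrum, unlocalized(p), adpr, "S",
                                protein_start=PARP1_START)
        assert loc.protein_site() == 507

    def test_probabilities_normalized_and_bounded(self, adpr):
        rng = np.random.default_rng(11)
        peaks = np.sort(rng.uniform(150, 1500, 80))
        s = Spectrum("r", 600.0, 3, "ETD", mz=peaks, intensity=np.ones(80))
        loc = localize_spectrum(s, ModifiedPeptide("AKSGSTLRSK"), adpr, "ST")
        assert sum(loc.probabilities) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= p <= 1 for p in loc.probabilities)

    def test_no_evidence_gives_uniform_probabilities(self, adpr):
        s = Spectrum("e", 600.0, 2, "ETD")
        loc = localize_spectrum(s, ModifiedPeptide("AKSGSTLR"), adpr, "ST")
        assert loc.probabilities == pytest.approx([1 / 3] * 3)

    def test_full_loss_only_evidence_gives_uniform_probabilities(self, adpr):
        """HCD peaks at fully stripped fragment masses carry no positional
        information and must be disregarded."""
        p = ModifiedPeptide("AKSGSTLR", placements={3: adpr})
        full_loss_mz = [f.mz for f in theoretical_fragments(p, "HCD", 1)
                        if f.mod_state == "full_loss"]
        s = Spectrum.from_peaks("fl", 600.0, 2, "HCD",
                                [(mz, 50.0) for mz in full_loss_mz])
        loc = localize_spectrum(s, ModifiedPeptide("AKSGSTLR"), adpr, "ST")
        assert loc.probabilities == pytest.approx([1 / 3] * 3)

    def test_no_candidate_residue_rejected(self, adpr):
        s = Spectrum("e", 600.0, 2, "ETD")
        with pytest.raises(ValueError, match="candidate"):
            localize_spectrum(s, ModifiedPeptide("AKGGLR"), adpr, "ST")

    def test_psm_wrapper_requires_modification(self):
        psm = PSM("t", ModifiedPeptide("AKSGLR"), 1.0, 1, 0.1, 0.0, 0, False)
        with pytest.raises(ValueError, match="modification"):
            localization_probabilities(psm, "ST")

    def test_search_then_localize_round_trip(self, demo_proteins, adpr, zero_noise):
        pep = ModifiedPeptide("STGDVNKFEQLAR", placements={1: adpr})
        syn = simulate_etd(pep, 3, zero_noise, title="rt")
        res = search_variable_mod([syn.spectrum], demo_proteins)
        loc = localization_probabilities(res[0], "ST")
        assert loc.best_site == 1
        # protein coordinate: peptide starts at DEMO1 residue 23
        assert loc.protein_site() == 23


class TestSiteDeterminingIons:
    def test_complete_ladder_discriminates_adjacent_sites(self, zero_noise, adpr):
        p = ModifiedPeptide("AKSSGLR", placements={3: adpr})
        syn = simulate_etd(p, 3, zero_noise)
        a = p
        b = ModifiedPeptide("AKSSGLR", placements={4: adpr})
        n_a, n_b = site_determining_ions(a, b, syn.spectrum)
        assert n_a >= 1
        assert n_b == 0  # wrong placement finds no supporting mod-carrying ions

    def test_empty_spectrum_counts_zero(self, adpr):
        s = Spectrum("e", 600.0, 2, "ETD")
        a = ModifiedPeptide("AKSSGLR", placements={3: adpr})
        b = ModifiedPeptide("AKSSGLR", placements={4: adpr})
        assert site_determining_ions(a, b, s) == (0, 0)

    def test_full_loss_only_spectrum_counts_zero(self, adpr):
        a = ModifiedPeptide("AKSSGLR", placements={3: adpr})
        b = ModifiedPeptide("AKSSGLR", placements={4: adpr})
        full_loss_mz = [f.mz for f in theoretical_fragments(a, "HCD", 1)
                        if f.mod_state == "full_loss"]
        s = Spectrum.from_peaks("fl", 600.0, 2, "HCD",
                                [(mz, 50.0) for mz in full_loss_mz])
        assert site_determining_ions(a, b, s) == (0, 0)

    def test_identical_placements_rejected(self, adpr):
        s = Spectrum("e", 600.0, 2, "ETD")
        a = ModifiedPeptide("AKSSGLR", placements={3: adpr})
        with pytest.raises(ValueError, match="identical"):
            site_determining_ions(a, a, s)

    def test_removing_a_site_determining_ion_weakens_the_true_site(self, zero_noise, adpr):
        p = ModifiedPeptide("AKSGSTLR", placements={3: adpr})
        syn = simulate_etd(p, 3, zero_noise)
        base = ModifiedPeptide("AKSGSTLR")
        loc_full = localize_spectrum(syn.spectrum, base, adpr, "ST")
        # strip one discriminating intact ion (c3, charge 1) from the spectrum
        c3 = [f.mz for f in theoretical_fragments(p, "ETD", 1)
              if f.series == "c" and f.index == 3][0]
        keep = np.abs(syn.spectrum.mz - c3) > 1e-9
        weakened = Spectrum("w", syn.spectrum.precursor_mz, 3, "ETD",
                            mz=syn.spectrum.mz[keep],
                            intensity=syn.spectrum.intensity[keep])
        loc_weak = localize_spectrum(weakened, base, adpr, "ST")
        advantage_full = loc_full.best_probability - max(
            p for p, s in zip(loc_full.probabilities, loc_full.candidate_sites) if s != 3)
        advantage_weak = loc_weak.probabilities[loc_weak.candidate_sites.index(3)] - max(
            p for p, s in zip(loc_weak.probabilities, loc_weak.candidate_sites) if s != 3)
        assert advantage_weak <= advantage_full


class TestSerineValidation:
    def test_zero_noise_h3_passes(self, zero_noise, adpr):
        p = h3_wt_peptide()
        syn = simulate_etd(p, 3, zero_noise)
        loc = localize_spectrum(syn.spectrum, unlocalized(p), adpr, "ST", protein_start=1)
        passed, reasons = validate_serine_site(loc, syn.spectrum)
        assert passed and reasons == []

    def test_full_loss_only_evidence_fails_with_reason(self, adpr):
        p = ModifiedPeptide("AKSGSTLR", placements={3: adpr})
        full_loss_mz = [f.mz for f in theoretical_fragments(p, "HCD", 1)
                        if f.mod_state == "full_loss"]
        s = Spectrum.from_peaks("fl", 600.0, 2, "HCD",
                                [(mz, 50.0) for mz in full_loss_mz])
        loc = localize_spectrum(s, ModifiedPeptide("AKSGSTLR"), adpr, "S")
        passed, reasons = validate_serine_site(loc, s)
        assert not passed
        assert "no_intact_or_phosphoribose_evidence" in reasons

    def test_empty_spectrum_fails_all_clauses(self, adpr):
        s = Spectrum("e", 600.0, 2, "ETD")
        loc = localize_spectrum(s, ModifiedPeptide("AKSGSTLR"), adpr, "S")
        passed, reasons = validate_serine_site(loc, s)
        assert not passed
        assert set(reasons) == {
            "no_intact_or_phosphoribose_evidence",
            "insufficient_site_determining_ions",
            "low_localization_probability",
        }

    def test_non_serine_best_site_rejected(self, zero_noise, adpr):
        p = ModifiedPeptide("AKTGGLR", placements={3: adpr})
        syn = simulate_etd(p, 3, zero_noise)
        loc = localize_spectrum(syn.spectrum, ModifiedPeptide("AKTGGLR"), adpr, "T")
        with pytest.raises(ValueError, match="not serine"):
            validate_serine_site(loc, syn.spectrum)


class TestFilterConfident:
    def _entry(self, score, ppm, prob, title="t", adpr=None):
        pep = ModifiedPeptide("AKSGLR", placements={3: adpr})
        psm = PSM(title, pep, score, int(score), 0.2, ppm, 0, True)
        loc = SiteLocalization(
            psm=psm, candidate_sites=[3], probabilities=[1.0], best_site=3,
            n_site_determining_ions=[2], placements=[pep])
        loc.probabilities = [prob, 1 - prob] if prob < 1 else [1.0]
        loc.candidate_sites = [3, 5][: len(loc.probabilities)]
        loc.n_site_determining_ions = [2] * len(loc.probabilities)
        return psm, loc

    def test_thresholds_applied(self, adpr):
        good = self._entry(50, 1.0, 0.95, "a", adpr)
        bad_ppm = self._entry(50, 3.5, 0.95, "b", adpr)
        bad_prob = self._entry(50, 1.0, 0.85, "c", adpr)
        bad_score = self._entry(5, 1.0, 0.95, "d", adpr)
        kept = filter_confident([good, bad_ppm, bad_prob, bad_score])
        assert kept == [good]

    def test_boundary_ppm_is_exclusive(self, adpr):
        at_three = self._entry(50, 3.0, 0.95, "x", adpr)
        assert filter_confident([at_three]) == []

    def test_empty_input(self):
        assert filter_confident([]) == []
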
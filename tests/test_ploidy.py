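"""Allele-frequency spectra, ploidy classification, cohort screen."""

import numpy as np
import pytest

from clonetrace import (
    AlleleFrequencySpectrum,
    PloidyParams,
    build_spectrum,
    call_genotypes,
    classify_ploidy,
    cohort_ploidy_screen,
    simulate_allele_depths,
    simulate_population,
    triallelic_fraction,
)
from clonetrace.genotype import Allelism, Call, GenotypeCalls
from conftest import SMALL_PLOIDY, small_config


def spectrum_from_values(values, bin_width=0.02):
    values = np.asarray(values, dtype=float)
    edges = np.linspace(0, 1, int(round(1 / bin_width)) + 1)
    counts, _ = np.histogram(values, bins=edges)
    return AlleleFrequencySpectrum("s", values, edges, counts)


def calls_with(call_codes, allelism_codes, alt_fraction=None, ref_in_pair=True):
    n = len(call_codes)
    call = np.asarray(call_codes, dtype=np.int8)
    ref = np.zeros(n, dtype=np.int8)
    allele1 = np.where(call == Call.HET, 0 if ref_in_pair else 1, 0).astype(np.int8)
    allele2 = np.where(call == Call.HET, 1 if ref_in_pair else 2, 0).astype(np.int8)
    af = np.full(n, 0.5) if alt_fraction is None else np.asarray(alt_fraction, float)
    return GenotypeCalls(
        sample_id="manual",
        positions=np.arange(1, n + 1, dtype=np.int64),
        ref=ref,
        call=call,
        allele1=allele1,
        allele2=allele2,
        alt_fraction=af,
        allelism=np.asarray(allelism_codes, dtype=np.int8),
        depth=np.full(n, 30, dtype=np.int64),
    )


class TestBuildSpectrum:
    def test_empty_calls_give_empty_spectrum_and_indeterminate(self):
        calls = calls_with([], [])
        spectrum = build_spectrum(calls)
        assert spectrum.n_het_sites == 0
        assert spectrum.modal_peak is None
        pc = classify_ploidy(spectrum)
        assert pc.classification == "indeterminate"

    def test_hom_calls_are_discarded(self):
        calls = calls_with(
            [Call.HET, Call.HOM_ALT, Call.HOM_REF, Call.HET],
            [Allelism.BIALLELIC] * 4,
            alt_fraction=[0.4, 1.0, 0.0, 0.6],
        )
        spectrum = build_spectrum(calls)
        assert spectrum.n_het_sites == 2
        assert np.allclose(sorted(spectrum.frequencies), [0.4, 0.6])

    def test_histogram_counts_sum_to_frequency_count(self, small_calls):
        spectrum = build_spectrum(small_calls[0])
        assert spectrum.counts.sum() == spectrum.n_het_sites
        assert np.all((spectrum.frequencies > 0) & (spectrum.frequencies < 1))

    def test_spectrum_invariant_under_site_permutation(self, small_calls):
        calls = small_calls[1]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(calls))
        shuffled = GenotypeCalls(
            calls.sample_id,
            calls.positions.copy(),  # positions stay sorted; data shuffled
            calls.ref[perm],
            calls.call[perm],
            calls.allele1[perm],
            calls.allele2[perm],
            calls.alt_fraction[perm],
            calls.allelism[perm],
            calls.depth[perm],
        )
        a, b = build_spectrum(calls), build_spectrum(shuffled)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestModalPeaks:
    def test_simulated_diploid_peaks_at_one_half(self):
        """Binomial(depth, 1/2) read sampling puts the modal histogram bin
        at 0.5 (to one decimal at bin width 0.02)."""
        cfg = small_config(base_error=0.0, read_depth_mean=50.0)
        truth = simulate_population(cfg)
        # pick a diploid whose planted haplotypes actually segregate
        diploid = next(
            g
            for g in truth.non_founders
            if g.ploidy == 2 and (g.haplotypes[0] != g.haplotypes[1]).sum() > 50
        )
        prof = simulate_allele_depths(diploid, truth, 50.0, 0.0, cfg.seed)
        spectrum = build_spectrum(call_genotypes(prof))
        assert spectrum.n_het_sites > 50
        assert round(spectrum.modal_peak, 1) == 0.5

    def test_simulated_triploid_peaks_at_one_third_with_secondary_at_two_thirds(self):
        cfg = small_config(founder_AB_divergence=0.1, base_error=0.0)
        truth = simulate_population(cfg)
        prof = simulate_allele_depths(truth.founder, truth, 30.0, 0.0, cfg.seed)
        spectrum = build_spectrum(call_genotypes(prof))
        # at this reduced site count the modal bin can land one bin off 1/3;
        # the exact 0.33 claim is asserted at full scale in the acceptance suite
        assert abs(spectrum.modal_peak - 1 / 3) <= 0.03
        # the founder's reference is its own A haplotype: the whole mass
        # sits near 1/3, none near 1/2
        near_third = np.abs(spectrum.frequencies - 1 / 3) <= 0.08
        assert near_third.mean() > 0.5

    def test_nonfounder_triploid_shows_both_peaks(self, small_truth, small_calls):
        tri = next(
            g for g in small_truth.non_founders if g.ploidy == 3
        )
        calls = next(c for c in small_calls if c.sample_id == tri.sample_id)
        spectrum = build_spectrum(calls)
        in3 = np.abs(spectrum.frequencies - 1 / 3) <= 0.08
        in23 = np.abs(spectrum.frequencies - 2 / 3) <= 0.08
        assert in3.sum() > 0 and (in3.sum() + in23.sum()) / spectrum.n_het_sites > 0.5


class TestClassify:
    def test_peak_at_one_third_classifies_triploid(self):
        """Read sampling at a triploid het site is Binomial(depth, 1/3); with
        Poisson-mixed depths the highest-mass 0.02 bin straddles 1/3 (modal
        midpoint 0.33), and the window-mass rule calls triploid. The sample
        size is set so the modal bin's expected lead exceeds 3 SDs."""
        rng = np.random.default_rng(1)
        d = np.maximum(rng.poisson(30, size=30_000), 10)
        freqs = rng.binomial(d, 1 / 3) / d
        pc = classify_ploidy(spectrum_from_values(freqs[(freqs > 0) & (freqs < 1)]))
        assert pc.classification == "triploid"
        assert pc.modal_peak == 0.33

    def test_peak_at_one_half_classifies_diploid(self):
        rng = np.random.default_rng(1)
        d = np.maximum(rng.poisson(30, size=30_000), 10)
        freqs = rng.binomial(d, 0.5) / d
        pc = classify_ploidy(spectrum_from_values(freqs[(freqs > 0) & (freqs < 1)]))
        assert pc.classification == "diploid"
        assert round(pc.modal_peak, 1) == 0.5

    def test_few_het_sites_are_indeterminate(self):
        pc = classify_ploidy(spectrum_from_values([0.5] * 10), PloidyParams())
        assert pc.classification == "indeterminate"

    def test_classification_robust_to_bin_width(self, small_calls):
        """The window-mass rule is bin-free: varying display bin width over
        [0.01, 0.04] never changes the classification."""
        for calls in (small_calls[0], small_calls[3]):
            outcomes = set()
            for bw in (0.01, 0.02, 0.04):
                spectrum = build_spectrum(calls, bin_width=bw)
                outcomes.add(classify_ploidy(spectrum, SMALL_PLOIDY).classification)
            assert len(outcomes) == 1


class TestTriallelicFraction:
    def test_all_biallelic_gives_zero(self):
        calls = calls_with([Call.HET] * 4, [Allelism.BIALLELIC] * 4)
        assert triallelic_fraction(calls) == 0.0

    def test_one_in_four_gives_a_quarter(self):
        calls = calls_with(
            [Call.HET] * 4,
            [Allelism.TRIALLELIC] + [Allelism.BIALLELIC] * 3,
        )
        assert triallelic_fraction(calls) == pytest.approx(0.25)

    def test_simulated_triploid_fraction_negligible(self, small_truth):
        cfg = small_config(base_error=0.0)
        truth = simulate_population(cfg)
        prof = simulate_allele_depths(truth.founder, truth, 30.0, 0.0, cfg.seed)
        assert triallelic_fraction(call_genotypes(prof)) < 0.01


class TestCohortScreen:
    def test_small_cohort_recovers_planted_ploidy(self, small_truth, small_profiles):
        table = cohort_ploidy_screen(small_profiles, None, SMALL_PLOIDY)
        truth_ploidy = {g.sample_id: g.ploidy for g in small_truth.genomes}
        confident = table[table.classification != "indeterminate"]
        assert len(confident) > 8
        for _, row in confident.iterrows():
            expected = "triploid" if truth_ploidy[row["sample"]] == 3 else "diploid"
            assert row["classification"] == expected

    def test_single_diploid_cohort(self, small_truth, small_profiles):
        diploid_prof = next(
            p
            for p, g in zip(small_profiles, small_truth.genomes)
            if g.ploidy == 2 and (g.haplotypes[0] != g.haplotypes[1]).sum() > 100
        )
        table = cohort_ploidy_screen([diploid_prof], None, SMALL_PLOIDY)
        assert list(table.classification) == ["diploid"]

    def test_zero_depth_cohort_all_indeterminate(self, small_truth):
        profs = [
            simulate_allele_depths(g, small_truth, 0.0, 0.0, seed=1)
            for g in small_truth.genomes[:3]
        ]
        table = cohort_ploidy_screen(profs, None, SMALL_PLOIDY)
        assert set(table.classification) == {"indeterminate"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_ploidy_screen([])
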
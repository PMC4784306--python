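"""Frequency model, forward simulator and allele painting checks.

The forward simulator is the oracle for the tract-dating model, so its
distributional properties are tested hardest: exact tract partitioning,
ancestry-fraction conservation, and the exponential tract-length law in
its regime of validity (large population, long chromosomes).
"""
import numpy as np
import pytest
from scipy import stats

from mosaictrace import simulate, vcfio
from mosaictrace.simulate import (Pulse, PulseHistory, paint_alleles,
                                  sample_ref_freqs, simulate_admixed_forward,
                                  simulate_panel)
from mosaictrace.tracts import Tract, AncestryPath

from conftest import PULSE_EUR, PULSE_T


def hudson_fst(f1, f2):
    """Brute-force Hudson FST from two population frequency vectors."""
    num = (f1 - f2) ** 2
    den = f1 * (1 - f2) + f2 * (1 - f1)
    return num.sum() / den.sum()


class TestRefFreqs:
    def test_zero_differentiation_limit(self):
        ft = sample_ref_freqs(10_000, ["P"], 1e-4, seed=0)
        assert np.mean(np.abs(ft.freq("P") - ft.p_anc)) < 0.02

    def test_hudson_fst_recovers_parameter(self):
        ft = sample_ref_freqs(50_000, ["A", "B"], 0.15, seed=1)
        assert abs(hudson_fst(ft.freq("A"), ft.freq("B")) - 0.15) < 0.03

    def test_seed_determinism(self):
        a = sample_ref_freqs(500, ["A", "B"], 0.1, seed=7)
        b = sample_ref_freqs(500, ["A", "B"], 0.1, seed=7)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        np.testing.assert_array_equal(a.pos, b.pos)

    @pytest.mark.parametrize("bad_fst", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_fst_rejected(self, bad_fst):
        with pytest.raises(ValueError):
            sample_ref_freqs(10, ["A"], bad_fst)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_ref_freqs(10, ["A"], 0.1, anc_freq_bounds=(0.0, 0.95))

    def test_positions_strictly_increasing_per_chrom(self, gmap4):
        ft = sample_ref_freqs(2000, ["A"], 0.1, seed=3, genetic_map=gmap4)
        for c in set(ft.chrom):
            assert np.all(np.diff(ft.pos[ft.chrom == c]) > 0)


class TestPanel:
    def test_fixed_site_is_fixed(self, gmap4):
        ft = sample_ref_freqs(50, ["P"], 0.2, seed=0, genetic_map=gmap4)
        ft.freqs[:, 0] = 1.0
        t = simulate_panel(ft, "P", 20, seed=1)
        assert np.all(t.haplotypes == 1)

    def test_binomial_sampling(self, gmap4):
        ft = sample_ref_freqs(200, ["P"], 0.2, seed=0, genetic_map=gmap4)
        ft.freqs[:, 0] = 0.3
        t = simulate_panel(ft, "P", 2000, seed=2)
        assert abs(t.haplotypes.mean() - 0.3) < 0.03

    def test_seed_determinism(self, ref_freqs4):
        a = simulate_panel(ref_freqs4, "AFR", 6, seed=5)
        b = simulate_panel(ref_freqs4, "AFR", 6, seed=5)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_bad_n_hap(self, ref_freqs4):
        with pytest.raises(ValueError):
            simulate_panel(ref_freqs4, "AFR", 0)
        with pytest.raises(ValueError):
            simulate_panel(ref_freqs4, "AFR", 3)


class TestPulseHistory:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PulseHistory("A", (Pulse(5, "B", 0.1), Pulse(9, "C", 0.1)))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            PulseHistory("A", (Pulse(5, "B", 1.0),))

    def test_expected_fractions_compose(self):
        h = PulseHistory("A", (Pulse(13, "B", 0.119), Pulse(10, "C", 0.116)))
        f = h.expected_fractions()
        assert f["C"] == pytest.approx(0.116)
        assert f["B"] == pytest.approx(0.119 * (1 - 0.116))
        assert sum(f.values()) == pytest.approx(1.0)


class TestForwardSimulator:
    def test_tract_partition_invariant(self, two_way_paths, gmap22):
        for p in two_way_paths:
            p.validate(gmap22.lengths())

    def test_minor_tract_mean_length(self, two_way_paths):
        from mosaictrace.tract_dating import extract_tracts
        ts = extract_tracts(two_way_paths)
        lens = ts.lengths("EUR", uncensored_only=True)
        expected = 1.0 / ((1.0 - PULSE_EUR) * PULSE_T)
        assert len(lens) > 500
        assert abs(lens.mean() - expected) / expected < 0.15

    def test_fraction_conservation(self, two_way_paths):
        fracs = np.array([p.lengths_by_label().get("EUR", 0.0) / p.total_length()
                          for p in two_way_paths])
        # tolerance covers sampling noise plus Wright-Fisher drift of the
        # population-wide fraction (sd ~ sqrt(m(1-m) T / 2N) ~ 0.03)
        assert abs(fracs.mean() - PULSE_EUR) < 0.04

    def test_tract_lengths_exponential_in_asymptotic_regime(self):
        # the Exponential((1-m)T) law is the large-population, long-
        # chromosome limit: pop 2000 keeps drift mixing small and 10 M
        # chromosomes keep the uncensored-conditioning bias ~ mean/L small
        gmap = vcfio.GeneticMap.uniform(n_chrom=4, morgans=10.0)
        hist = PulseHistory("AFR", (Pulse(PULSE_T, "EUR", PULSE_EUR),))
        paths = simulate_admixed_forward(hist, gmap, pop_size=2000, n_out=60,
                                         seed=2024)
        from mosaictrace.tract_dating import extract_tracts
        lens = extract_tracts(paths).lengths("EUR", uncensored_only=True)
        assert len(lens) >= 2000
        rate = (1.0 - PULSE_EUR) * PULSE_T
        assert stats.kstest(lens, "expon", args=(0, 1.0 / rate)).pvalue > 0.01

    def test_dosage_unbiased_across_replicates(self):
        # one observation per independent simulation: within one pedigree
        # haplotype fractions share the population's drift, so only
        # replicate means are exchangeable for a t-test
        gmap = vcfio.GeneticMap.uniform(n_chrom=6, morgans=1.5)
        hist = PulseHistory("AFR", (Pulse(6, "EUR", 0.25),))
        means = []
        for i in range(12):
            paths = simulate_admixed_forward(hist, gmap, pop_size=120, n_out=18,
                                             seed=900 + i)
            means.append(np.mean([p.lengths_by_label().get("EUR", 0.0)
                                  / p.total_length() for p in paths]))
        assert len(means) * 18 >= 200
        assert stats.ttest_1samp(means, 0.25).pvalue > 0.01

    def test_pulse_at_one_generation(self, gmap4):
        # one post-pulse meiosis: migrant fraction conserved and junction
        # density bounded by the single meiosis's crossover rate
        hist = PulseHistory("A", (Pulse(1, "B", 0.3),))
        paths = simulate_admixed_forward(hist, gmap4, pop_size=300, n_out=200,
                                         seed=5)
        frac = np.mean([p.lengths_by_label().get("B", 0.0) / p.total_length()
                        for p in paths])
        assert abs(frac - 0.3) < 0.05
        n_junc = sum(len(tr) - 1 for p in paths for tr in p.tracts.values())
        total_len = sum(p.total_length() for p in paths)
        assert n_junc / total_len < 1.0      # at most Poisson(1/Morgan) junctions

    def test_seed_determinism(self, gmap4):
        hist = PulseHistory("A", (Pulse(3, "B", 0.2),))
        a = simulate_admixed_forward(hist, gmap4, pop_size=60, n_out=4, seed=9)
        b = simulate_admixed_forward(hist, gmap4, pop_size=60, n_out=4, seed=9)
        assert [p.tracts for p in a] == [p.tracts for p in b]

    def test_small_pop_warns(self, gmap4):
        hist = PulseHistory("A", (Pulse(2, "B", 0.2),))
        with pytest.warns(UserWarning):
            simulate_admixed_forward(hist, gmap4, pop_size=20, n_out=4, seed=0)

    def test_empty_map_rejected(self):
        hist = PulseHistory("A", (Pulse(2, "B", 0.2),))
        with pytest.raises(ValueError):
            simulate_admixed_forward(hist, vcfio.GeneticMap({}, {}), n_out=2)

    def test_founding_generation_must_cover_pulses(self, gmap4):
        hist = PulseHistory("A", (Pulse(5, "B", 0.2),))
        with pytest.raises(ValueError):
            simulate_admixed_forward(hist, gmap4, pop_size=60, n_out=2, seed=0,
                                     founding_generation=3)


class TestPaintAlleles:
    def test_fully_differentiated_freqs_read_truth(self, gmap4):
        ft = sample_ref_freqs(400, ["A", "B"], 0.2, seed=0, genetic_map=gmap4)
        ft.freqs[:, 0] = 0.0     # ancestry A never carries the derived allele
        ft.freqs[:, 1] = 1.0
        lengths = gmap4.lengths()
        half = {c: [Tract(0.0, L / 2, "A"), Tract(L / 2, L, "B")]
                for c, L in lengths.items()}
        paths = [AncestryPath(half), AncestryPath.single("A", lengths)]
        t = paint_alleles(paths, ft, seed=1)
        for c in gmap4.chroms:
            m = ft.chrom == c
            is_b = ft.gpos[m] >= lengths[c] / 2
            np.testing.assert_array_equal(t.haplotypes[m, 0], is_b.astype(np.int8))
            assert np.all(t.haplotypes[m, 1] == 0)

    def test_single_ancestry_path_matches_panel_law(self, gmap4):
        ft = sample_ref_freqs(20_000, ["A", "B"], 0.2, seed=4, genetic_map=gmap4)
        paths = [AncestryPath.single("A", gmap4.lengths()) for _ in range(40)]
        painted = paint_alleles(paths, ft, seed=5)
        panel = simulate_panel(ft, "A", 40, seed=6)
        f1 = painted.haplotypes.mean(axis=1)
        f2 = panel.haplotypes.mean(axis=1)
        assert stats.ks_2samp(f1, f2).pvalue > 0.01

    def test_seed_determinism(self, gmap4, ref_freqs4):
        paths = [AncestryPath.single("AFR", gmap4.lengths())] * 2
        a = paint_alleles(paths, ref_freqs4, seed=3)
        b = paint_alleles(paths, ref_freqs4, seed=3)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_unknown_ancestry_rejected(self, gmap4, ref_freqs4):
        paths = [AncestryPath.single("MARS", gmap4.lengths())] * 2
        with pytest.raises(KeyError):
            paint_alleles(paths, ref_freqs4, seed=0)


def test_mixture_dosages_match_marginal_law(ref_freqs4):
    g = simulate.simulate_admixture_dosages([0.5, 0.3, 0.2], ref_freqs4, seed=8)
    theta = ref_freqs4.freqs @ np.array([0.5, 0.3, 0.2])
    assert g.shape == (ref_freqs4.n_sites,)
    assert abs(g.mean() - 2 * theta.mean()) < 0.05
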
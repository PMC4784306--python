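"""Windowed-PCA painting: window models, HMM smoothing, calling, masking."""
import itertools

import numpy as np
import pytest

from mosaictrace import simulate, vcfio
from mosaictrace.ancestry_paint import (WindowPosterior, call_ancestry,
                                        fit_reference_pca, global_fractions,
                                        hmm_posteriors, mask_genome,
                                        paint_haplotypes, window_loglik)
from mosaictrace.tracts import UNASSIGNED, AncestryPath, Tract

from conftest import make_table


@pytest.fixture(scope="module")
def painted_world(gmap4):
    """Panels + admixed queries with truth, painted end to end."""
    rng = np.random.default_rng(404)
    freqs = simulate.sample_ref_freqs(4000, ["AFR", "EUR", "NAT"], 0.15,
                                      rng=rng, genetic_map=gmap4)
    panels = {p: simulate.simulate_panel(freqs, p, 60, rng=rng)
              for p in ("AFR", "EUR", "NAT")}
    refs = vcfio.merge_samples(list(panels.values()))
    hist = simulate.PulseHistory(
        "AFR", (simulate.Pulse(6, "EUR", 0.2), simulate.Pulse(4, "NAT", 0.15)))
    paths = simulate.simulate_admixed_forward(hist, gmap4, pop_size=200,
                                              n_out=8, rng=rng)
    queries = simulate.paint_alleles(paths, freqs, rng=rng,
                                     sample_prefix="Q_", population="Q")
    panel_map = {p: panels[p].samples for p in panels}
    post, calls = paint_haplotypes(refs, panel_map, queries, gmap4)
    return dict(freqs=freqs, refs=refs, panel_map=panel_map, queries=queries,
                paths=paths, post=post, calls=calls)


class TestReferencePCA:
    def test_loadings_reproduce_reference_scores(self, ref_freqs4, gmap4):
        panels = {p: simulate.simulate_panel(ref_freqs4, p, 20, seed=i)
                  for i, p in enumerate(("AFR", "EUR"))}
        refs = vcfio.merge_samples(list(panels.values()))
        model = fit_reference_pca(refs, {p: panels[p].samples for p in panels},
                                  gmap4, window_size=30)
        w = model.windows[0]
        X = refs.haplotypes[w.sites].T.astype(float)
        scores = (X - w.col_means) @ w.loadings
        # projecting the class means' own panels back must reproduce them
        recon = np.vstack([scores[:20].mean(axis=0), scores[20:].mean(axis=0)])
        np.testing.assert_allclose(recon, w.class_means, atol=1e-9)

    def test_oversized_window_gives_single_window_per_chrom(self, ref_freqs4, gmap4):
        panels = {p: simulate.simulate_panel(ref_freqs4, p, 20, seed=i)
                  for i, p in enumerate(("AFR", "EUR"))}
        refs = vcfio.merge_samples(list(panels.values()))
        model = fit_reference_pca(refs, {p: panels[p].samples for p in panels},
                                  gmap4, window_size=10 ** 6)
        assert model.n_windows == len(gmap4.chroms)

    def test_fully_differentiated_panels_classify_perfectly(self, gmap4):
        ft = simulate.sample_ref_freqs(300, ["A", "B"], 0.2, seed=2,
                                       genetic_map=gmap4)
        ft.freqs[:, 0] = 0.0
        ft.freqs[:, 1] = 1.0
        pa = simulate.simulate_panel(ft, "A", 12, seed=3)
        pb = simulate.simulate_panel(ft, "B", 12, seed=4, sample_prefix="B_")
        refs = vcfio.merge_samples([pa, pb])
        model = fit_reference_pca(refs, {"A": pa.samples, "B": pb.samples},
                                  gmap4, window_size=30)
        query = np.zeros(300, dtype=np.int8)          # a pure-A haplotype
        ll = window_loglik(query, model)
        assert np.all(np.argmax(ll, axis=1) == 0)

    def test_monomorphic_window_flagged_uninformative(self, gmap4):
        ft = simulate.sample_ref_freqs(60, ["A", "B"], 0.2, seed=5,
                                       genetic_map=gmap4)
        ft.freqs[:, :] = 1.0                          # every panel fixed
        pa = simulate.simulate_panel(ft, "A", 10, seed=6)
        pb = simulate.simulate_panel(ft, "B", 10, seed=7, sample_prefix="B_")
        refs = vcfio.merge_samples([pa, pb])
        model = fit_reference_pca(refs, {"A": pa.samples, "B": pb.samples},
                                  gmap4, window_size=30)
        assert not any(w.informative for w in model.windows)
        ll = window_loglik(np.ones(60, dtype=np.int8), model)
        np.testing.assert_array_equal(ll, 0.0)

    def test_too_few_reference_haplotypes_rejected(self, ref_freqs4, gmap4):
        pa = simulate.simulate_panel(ref_freqs4, "AFR", 2, seed=8)
        pb = simulate.simulate_panel(ref_freqs4, "EUR", 20, seed=9,
                                     sample_prefix="E_")
        refs = vcfio.merge_samples([pa, pb])
        with pytest.raises(ValueError):
            fit_reference_pca(refs, {"AFR": pa.samples, "EUR": pb.samples},
                              gmap4, n_pcs=2)

    def test_hand_checked_gaussian_density(self):
        # one 1-PC window scored against N(mu, v) must equal the closed form
        from mosaictrace.ancestry_paint import ReferencePCA, WindowModel
        w = WindowModel("1", np.arange(2), 0.5, np.array([0.5, 0.5]),
                        np.array([[1.0], [0.0]]), np.array([[0.3], [-0.3]]),
                        np.array([0.04]), True)
        model = ReferencePCA([w], ["X", "Y"], 2, 1)
        ll = window_loglik(np.array([1, 0], dtype=np.int8), model)
        s = 0.5  # (1 - 0.5) * 1.0 + (0 - 0.5) * 0.0
        for k, mu in enumerate((0.3, -0.3)):
            expect = -0.5 * ((s - mu) ** 2 / 0.04 + np.log(2 * np.pi * 0.04))
            assert ll[0, k] == pytest.approx(expect, abs=1e-12)


class TestHMM:
    def brute_force_posteriors(self, ll, mids, rho, pi):
        """Exhaustive path enumeration over all K^T state sequences."""
        T, K = ll.shape
        stay = np.exp(-rho * np.diff(mids))
        post = np.zeros((T, K))
        for seq in itertools.product(range(K), repeat=T):
            lp = np.log(pi[seq[0]]) + ll[0, seq[0]]
            for t in range(1, T):
                tr = stay[t - 1] * (seq[t] == seq[t - 1]) \
                    + (1 - stay[t - 1]) * pi[seq[t]]
                lp += np.log(tr) + ll[t, seq[t]]
            for t in range(T):
                post[t, seq[t]] += np.exp(lp)
        return post / post.sum(axis=1, keepdims=True)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        ll = rng.normal(size=(5, 3))
        mids = np.sort(rng.random(5))
        pi = np.array([0.5, 0.3, 0.2])
        got = hmm_posteriors(ll, mids, ["1"] * 5, switch_rate=4.0, priors=pi)
        want = self.brute_force_posteriors(ll, mids, 4.0, pi)
        np.testing.assert_allclose(got.posteriors, want, atol=1e-9)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(13)
        ll = rng.normal(size=(40, 3))
        got = hmm_posteriors(ll, np.linspace(0, 1, 40), ["1"] * 40)
        np.testing.assert_allclose(got.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_switch_rate_pools_all_windows(self):
        rng = np.random.default_rng(14)
        ll = rng.normal(size=(6, 2))
        got = hmm_posteriors(ll, np.linspace(0, 1, 6), ["1"] * 6,
                             switch_rate=0.0)
        pooled = np.exp(ll.sum(axis=0) - ll.sum(axis=0).max())
        pooled /= pooled.sum()
        np.testing.assert_allclose(got.posteriors,
                                   np.tile(pooled, (6, 1)), atol=1e-9)

    def test_infinite_switch_rate_decouples_windows(self):
        rng = np.random.default_rng(15)
        ll = rng.normal(size=(6, 2))
        pi = np.array([0.7, 0.3])
        got = hmm_posteriors(ll, np.linspace(0, 1, 6), ["1"] * 6,
                             switch_rate=1e9, priors=pi)
        want = pi * np.exp(ll - ll.max(axis=1, keepdims=True))
        want /= want.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(got.posteriors, want, atol=1e-9)

    def test_non_finite_loglik_rejected(self):
        with pytest.raises(ValueError):
            hmm_posteriors(np.array([[0.0, -np.inf]]), [0.5], ["1"])


class TestCalling:
    def make_post(self, rows, mids=None):
        rows = np.asarray(rows, dtype=float)
        mids = np.linspace(0.1, 0.9, len(rows)) if mids is None else mids
        return WindowPosterior("h", np.array(["1"] * len(rows), dtype=object),
                               np.asarray(mids), rows, ["A", "B", "C"])

    def test_threshold_examples(self, gmap4):
        post = self.make_post([[0.85, 0.10, 0.05], [0.79, 0.11, 0.10]])
        path = call_ancestry(post, gmap4, ["A", "B", "C"], threshold=0.8)
        assert path.tracts["1"][0].label == "A"
        assert path.tracts["1"][1].label == UNASSIGNED

    def test_exact_threshold_passes(self, gmap4):
        post = self.make_post([[0.8, 0.1, 0.1]])
        path = call_ancestry(post, gmap4, ["A", "B", "C"], threshold=0.8)
        assert path.tracts["1"][0].label == "A"

    def test_uniform_call_merges_to_whole_chromosome(self, gmap4):
        post = self.make_post([[0.9, 0.05, 0.05]] * 7)
        path = call_ancestry(post, gmap4, ["A", "B", "C"])
        assert len(path.tracts["1"]) == 1
        t = path.tracts["1"][0]
        assert (t.start, t.end, t.label) == (0.0, 1.0, "A")

    def test_boundaries_at_midpoints(self, gmap4):
        post = self.make_post([[0.9, 0.1, 0.0], [0.1, 0.9, 0.0]],
                              mids=[0.2, 0.6])
        path = call_ancestry(post, gmap4, ["A", "B", "C"])
        assert path.tracts["1"][0].end == pytest.approx(0.4)

    def test_threshold_bounds(self, gmap4):
        post = self.make_post([[0.9, 0.05, 0.05]])
        with pytest.raises(ValueError):
            call_ancestry(post, gmap4, ["A", "B", "C"], threshold=0.2)


class TestEndToEnd:
    def test_window_call_accuracy_against_truth(self, painted_world, gmap4):
        # on strongly differentiated panels (FST 0.15, 30-SNP windows) at
        # least 95% of assigned windows must match the simulated truth
        post = painted_world["post"]
        paths = painted_world["paths"]
        hids = list(post)
        correct = total = 0
        for hid, truth in zip(hids, paths):
            wp = post[hid]
            best = np.argmax(wp.posteriors, axis=1)
            called = wp.posteriors[np.arange(len(best)), best] >= 0.8
            labels = np.array(wp.labels, dtype=object)[best]
            for c in set(wp.chroms.tolist()):
                m = wp.chroms == c
                truth_lab = truth.label_at(str(c), wp.mid_morgans[m])
                ok = called[m]
                correct += np.sum((labels[m] == truth_lab) & ok)
                total += np.sum(ok)
        assert total > 0
        assert correct / total >= 0.95

    def test_global_fractions_recover_truth(self, painted_world):
        calls = list(painted_world["calls"].values())
        got = global_fractions(calls)
        want = global_fractions(painted_world["paths"])
        for k in ("AFR", "EUR", "NAT"):
            assert got[k] == pytest.approx(want[k], abs=0.03)
        assigned = sum(v for k, v in got.items() if k != UNASSIGNED)
        assert assigned == pytest.approx(1.0)

    def test_masking_bookkeeping_is_exact(self, painted_world, gmap4):
        # masking on the truth paths must null exactly the non-AFR sites
        queries = painted_world["queries"]
        paths = painted_world["paths"]
        truth_calls = {h: p for h, p in zip(queries.haplotype_ids(), paths)}
        masked = mask_genome(queries, truth_calls, "AFR", gmap4)
        gpos = queries.gpos(gmap4)
        for h, hid in enumerate(queries.haplotype_ids()):
            keep = np.zeros(queries.n_sites, dtype=bool)
            for c in set(queries.chrom.tolist()):
                m = queries.chrom == c
                keep[m] = truth_calls[hid].label_at(str(c), gpos[m]) == "AFR"
            col = masked.haplotypes[:, h]
            assert np.all(col[~keep] == -1)
            np.testing.assert_array_equal(col[keep],
                                          queries.haplotypes[:, h][keep])

    def test_mask_with_no_target_ancestry_blanks_haplotype(self, painted_world,
                                                           gmap4):
        queries = painted_world["queries"]
        hid = queries.haplotype_ids()[0]
        calls = {hid: AncestryPath.single("EUR", gmap4.lengths())}
        masked = mask_genome(queries, calls, "AFR", gmap4)
        assert np.all(masked.haplotypes[:, 0] == -1)
        np.testing.assert_array_equal(masked.haplotypes[:, 1],
                                      queries.haplotypes[:, 1])


class TestGlobalFractions:
    def test_single_ancestry_genome(self, gmap4):
        path = AncestryPath.single("AFR", gmap4.lengths())
        got = global_fractions([path])
        assert got["AFR"] == 1.0
        assert got[UNASSIGNED] == 0.0

    def test_zero_assigned_raises(self, gmap4):
        path = AncestryPath.single(UNASSIGNED, gmap4.lengths())
        with pytest.raises(ValueError):
            global_fractions([path])
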
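"""Single-causal multi-trait fine-mapping, annotation priors, colocalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from pleiofine import finemap as fm, simulate as sim

from conftest import draw_z


class TestLogAbf:
    def test_zero_z_negative(self):
        n = 10_000
        r = 0.04 / (0.04 + 1 / n)
        assert fm.log_abf(0.0, n) == pytest.approx(0.5 * np.log(1 - r))
        assert fm.log_abf(0.0, n) < 0

    def test_point_null_prior_gives_zero(self):
        assert fm.log_abf(5.0, 10_000, w_prior=0.0) == 0.0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            fm.log_abf(1.0, 0)

    def test_matches_quadrature_oracle(self):
        """ABF equals the two-Gaussian marginal likelihood ratio by quadrature.

        With beta_hat = z * se, se = 1/sqrt(n): the alternative's marginal
        likelihood integrates N(beta_hat; b, se^2) against the effect prior
        N(b; 0, w); the null is N(beta_hat; 0, se^2).
        """
        z, n, w = 5.0, 10_000, 0.04
        se = 1 / np.sqrt(n)
        bhat = z * se

        def integrand(b):
            return stats.norm.pdf(bhat, b, se) * stats.norm.pdf(b, 0, np.sqrt(w))

        alt, _ = integrate.quad(integrand, -5, 5, epsabs=1e-14, epsrel=1e-12)
        null = stats.norm.pdf(bhat, 0, se)
        assert fm.log_abf(z, n, w) == pytest.approx(np.log(alt / null), abs=1e-6)


class TestMultitraitPP:
    def test_dominant_snp(self):
        m = 20
        ids = [f"s{i}" for i in range(m)]
        z = np.zeros(m)
        z[7] = 10.0
        cs = fm.multitrait_pp(
            "sig", ids, {"a": z, "b": z}, {"a": 20_000, "b": 30_000}
        )
        assert cs.top_snp == "s7"
        assert cs.top_pp > 0.999

    def test_perfect_ld_pair_symmetric(self):
        ids = ["s0", "s1", "s2"]
        z = np.array([6.0, 6.0, 0.0])
        cs = fm.multitrait_pp("sig", ids, {"a": z}, {"a": 20_000})
        assert cs.pp[0] == pytest.approx(cs.pp[1])
        assert set(cs.set95) >= {"s0", "s1"}

    def test_pp_normalized_and_set95_minimal(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(30)]
        z = rng.standard_normal(30) * 2
        cs = fm.multitrait_pp("sig", ids, {"a": z}, {"a": 10_000})
        assert cs.pp.sum() == pytest.approx(1.0)
        order = np.argsort(-cs.pp, kind="stable")
        k = len(cs.set95)
        assert cs.pp[order[:k]].sum() >= 0.95
        assert cs.pp[order[: k - 1]].sum() < 0.95

    def test_relabeling_and_null_trait_invariance(self):
        ids = [f"s{i}" for i in range(10)]
        z = np.linspace(-2, 5, 10)
        base = fm.multitrait_pp("sig", ids, {"a": z}, {"a": 20_000})
        # an all-zero trait under a point-null effect prior contributes
        # log ABF = 0 everywhere, hence cannot move the posteriors
        np.testing.assert_allclose(fm.log_abf(np.zeros(10), 5_000, w_prior=0.0), 0.0)
        relabeled = fm.multitrait_pp("sig", ids, {"zzz": z}, {"zzz": 20_000})
        np.testing.assert_allclose(base.pp, relabeled.pp)

    def test_coverage_of_planted_causal(self, small_panel, small_V):
        """95% credible sets cover the planted causal in >= 93% of signals;
        the causal attains top PP in >= 80%."""
        V, Lv = small_V
        rng = np.random.default_rng(1)
        n_eff = {"a": 40_000, "b": 60_000}
        ids = small_panel.snp_ids
        m = len(ids)
        reps = 500
        covered = top = 0
        for _ in range(reps):
            j = int(rng.integers(m))
            zt = {}
            for t, n in n_eff.items():
                target = rng.uniform(5, 9)
                beta = np.zeros(m)
                beta[j] = target / np.sqrt(n)
                zt[t] = draw_z(Lv, rng, np.sqrt(n) * (V @ beta))
            cs = fm.multitrait_pp("sig", ids, zt, n_eff)
            covered += ids[j] in cs.set95
            top += cs.top_snp == ids[j]
        assert covered / reps >= 0.93
        assert top / reps >= 0.80


class TestAnnotateSnps:
    def _snps(self, positions):
        return pd.DataFrame({"chrom": "5", "pos": positions})

    def test_inside_peak(self, tmp_path):
        bed = tmp_path / "a.bed"
        p = 1000
        bed.write_text(f"5\t{p - 11}\t{p + 9}\n")  # 0-based half-open around p
        (track,) = fm.annotate_snps(self._snps([p]), {"t": bed})
        assert track.indicator[0] == 1

    def test_half_open_end_excluded(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("5\t100\t200\n")
        snps = self._snps([100, 101, 200, 201])
        (track,) = fm.annotate_snps(snps, {"t": bed})
        # 1-based 101..200 inside [100, 200); 1-based 201 (0-based 200) outside
        np.testing.assert_array_equal(track.indicator, [0, 1, 1, 0])

    def test_malformed_line_skipped(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("5\t100\t200\n5\tfoo\tbar\n5\t300\t250\n")
        (track,) = fm.annotate_snps(self._snps([150]), {"t": bed})
        assert len(track.intervals) == 1

    def test_matches_intervaltree_oracle(self, tmp_path):
        from intervaltree import IntervalTree

        rng = np.random.default_rng(2)
        peaks = []
        for _ in range(60):
            s = int(rng.integers(0, 10_000))
            peaks.append((s, s + int(rng.integers(1, 300))))
        bed = tmp_path / "a.bed"
        bed.write_text("".join(f"5\t{s}\t{e}\n" for s, e in peaks))
        positions = rng.integers(1, 11_000, 500)
        (track,) = fm.annotate_snps(self._snps(positions), {"t": bed})
        tree = IntervalTree.from_tuples(peaks)
        oracle = np.array([1 if tree[p - 1] else 0 for p in positions])
        np.testing.assert_array_equal(track.indicator, oracle)


class TestAnnotationPrior:
    def test_gamma_zero_recovers_uniform(self):
        rng = np.random.default_rng(3)
        m = 50
        A = (rng.random(m) < 0.2).astype(np.int8)
        model = fm.AnnotationModel(["t"], np.zeros(1))
        prior = model.prior(A[:, None])
        np.testing.assert_allclose(prior, np.full(m, 1 / m))
        ids = [f"s{i}" for i in range(m)]
        z = rng.standard_normal(m) * 2
        with_prior = fm.multitrait_pp("s", ids, {"a": z}, {"a": 10_000}, prior=prior)
        uniform = fm.multitrait_pp("s", ids, {"a": z}, {"a": 10_000})
        np.testing.assert_allclose(with_prior.pp, uniform.pp, atol=1e-12)

    def test_constant_annotation_nonidentifiable(self):
        m = 30
        tracks = [fm.AnnotationTrack("const", [], np.ones(m, dtype=np.int8))]
        lb = [np.zeros(m)]
        with pytest.warns(UserWarning, match="constant"):
            model = fm.fit_annotation_prior(lb, tracks)
        assert model.gamma[0] == 0.0

    def test_duplicated_signals_give_same_gamma(self):
        rng = np.random.default_rng(4)
        m = 60
        A = (rng.random(m) < 0.15).astype(np.int8)
        A[10] = 1
        lb = np.zeros(m)
        lb[10] = 8.0
        tracks = [fm.AnnotationTrack("t", [], A)]
        one = fm.fit_annotation_prior([lb], tracks)
        two = fm.fit_annotation_prior([lb, lb.copy()], tracks)
        assert one.gamma[0] == pytest.approx(two.gamma[0], abs=1e-4)

    def test_enrichment_recovered_and_pp_improves(self, small_panel, small_V):
        """Causals always inside peaks covering ~10% of SNPs: fitted gamma > 0
        and the causal SNP's mean PP strictly increases vs the uniform prior."""
        V, Lv = small_V
        rng = np.random.default_rng(5)
        m = len(small_panel.snp_ids)
        ids = small_panel.snp_ids
        in_peak = (rng.random(m) < 0.10).astype(np.int8)
        causal_pool = np.flatnonzero(in_peak)
        n = 40_000
        signals, causals = [], []
        for _ in range(12):
            j = int(rng.choice(causal_pool))
            beta = np.zeros(m)
            beta[j] = 6.5 / np.sqrt(n)
            z = draw_z(Lv, rng, np.sqrt(n) * (V @ beta))
            signals.append(fm.log_abf(z, n))
            causals.append(j)
        tracks = [fm.AnnotationTrack("open_chromatin", [], in_peak)]
        model = fm.fit_annotation_prior(signals, tracks)
        assert model.gamma[0] > 0
        prior = model.prior(in_peak[:, None].astype(float))
        pp_uniform, pp_annot = [], []
        for lb, j in zip(signals, causals):
            pu = np.exp(lb - lb.max())
            pu /= pu.sum()
            pa = prior * np.exp(lb - lb.max())
            pa /= pa.sum()
            pp_uniform.append(pu[j])
            pp_annot.append(pa[j])
        assert np.mean(pp_annot) > np.mean(pp_uniform)


class TestColocalization:
    def test_posteriors_normalize(self):
        rng = np.random.default_rng(6)
        pp = fm.colocalize_pair(
            rng.standard_normal(50), rng.standard_normal(50), 10_000, 20_000
        )
        assert sum(pp.values()) == pytest.approx(1.0)

    def test_shared_signal_high_pp4(self, small_V):
        V, Lv = small_V
        rng = np.random.default_rng(7)
        m = V.shape[0]
        n1, n2 = 40_000, 60_000
        pp4s = []
        for _ in range(100):
            j = int(rng.integers(m))
            beta = np.zeros(m)
            beta[j] = 8.0 / np.sqrt(n1)
            z1 = draw_z(Lv, rng, np.sqrt(n1) * (V @ beta))
            beta2 = np.zeros(m)
            beta2[j] = 8.0 / np.sqrt(n2)
            z2 = draw_z(Lv, rng, np.sqrt(n2) * (V @ beta2))
            pp4s.append(fm.colocalize_pair(z1, z2, n1, n2)["PP4"])
        assert np.median(pp4s) > 0.9

    def test_distinct_signals_high_pp3(self, small_V):
        V, Lv = small_V
        rng = np.random.default_rng(8)
        m = V.shape[0]
        n1, n2 = 40_000, 60_000
        # pick SNP pairs with r^2 < 0.01
        pp3s = []
        for _ in range(100):
            while True:
                j1, j2 = rng.integers(m, size=2)
                if V[j1, j2] ** 2 < 0.01:
                    break
            b1 = np.zeros(m)
            b1[j1] = 8.0 / np.sqrt(n1)
            b2 = np.zeros(m)
            b2[j2] = 8.0 / np.sqrt(n2)
            z1 = draw_z(Lv, rng, np.sqrt(n1) * (V @ b1))
            z2 = draw_z(Lv, rng, np.sqrt(n2) * (V @ b2))
            pp3s.append(fm.colocalize_pair(z1, z2, n1, n2)["PP3"])
        assert np.median(pp3s) > 0.9

    def test_few_snps_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            fm.colocalize_pair(np.ones(5), np.ones(5), 1000, 1000)
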
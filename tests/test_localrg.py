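"""Local SNP-heritability and local genetic covariance/correlation estimators."""

import numpy as np
import pytest
from scipy import stats

from pleiofine import ldref, localrg, simulate as sim
from pleiofine.overlap import OverlapMatrix

from conftest import draw_z


@pytest.fixture(scope="module")
def ld(small_panel):
    return ldref.compute_ld(small_panel)


class TestLocalH2:
    def test_null_expectation_gives_zero(self, ld):
        # z engineered so the quadratic form equals q exactly
        v = ld.eigvecs[:, 0] * np.sqrt(ld.eigvals[0] * ld.q)
        h2, _ = localrg.local_h2(v, 50_000, ld)
        assert h2 == pytest.approx(0.0, abs=1e-10)

    def test_zero_z_gives_negative_floor(self, ld):
        n = 50_000
        h2, _ = localrg.local_h2(np.zeros(ld.m), n, ld)
        assert h2 == pytest.approx(-ld.q / (n - ld.q))

    def test_rank_exceeding_sample_size_error(self, ld):
        with pytest.raises(ValueError, match="rank exceeds sample size"):
            localrg.local_h2(np.zeros(ld.m), ld.q - 1, ld)

    def test_recovery_of_planted_h2(self, ld, small_V):
        """Mean estimate over 500 replicates within 2 MC SE of h2 = 0.001."""
        V, Lv = small_V
        n = 50_000
        rng = np.random.default_rng(21)
        beta = np.zeros(ld.m)
        beta[[10, 40, 70]] = 1.0
        beta *= np.sqrt(0.001 / (beta @ V @ beta))
        mean_z = np.sqrt(n) * (V @ beta)
        ests = np.array(
            [localrg.local_h2(draw_z(Lv, rng, mean_z), n, ld)[0] for _ in range(500)]
        )
        se = ests.std(ddof=1) / np.sqrt(500)
        assert abs(ests.mean() - 0.001) < 2 * se


class TestLocalRcov:
    def test_algebraic_identity_with_h2_at_full_overlap(self, ld):
        """Same trait twice with c = 1: the covariance and heritability
        estimators coincide up to their denominators, rho = h2 (n - q) / n."""
        rng = np.random.default_rng(3)
        z = rng.standard_normal(ld.m)
        n = 30_000
        h2, _ = localrg.local_h2(z, n, ld)
        rho, _ = localrg.local_rcov(z, z, n, n, ld, c=1.0)
        assert rho == pytest.approx(h2 * (n - ld.q) / n)

    def test_type_one_error_calibration(self, ld, small_V):
        """Independent null traits: rejection rate at alpha=0.05 in [0.04, 0.065]."""
        V, Lv = small_V
        n1, n2 = 40_000, 60_000
        rng = np.random.default_rng(22)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            z1 = draw_z(Lv, rng)
            z2 = draw_z(Lv, rng)
            rho, var_rho = localrg.local_rcov(z1, z2, n1, n2, ld, c=0.0)
            p = 2 * stats.norm.sf(abs(rho) / np.sqrt(var_rho))
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.065

    def test_recovery_of_planted_rho(self, ld, small_V):
        """Traits sharing identical causal effects: mean within 2 MC SE of 5e-4."""
        V, Lv = small_V
        n = 50_000
        rng = np.random.default_rng(23)
        beta = np.zeros(ld.m)
        beta[[15, 55, 85]] = 1.0
        beta *= np.sqrt(0.0005 / (beta @ V @ beta))
        mean_z = np.sqrt(n) * (V @ beta)
        ests = np.empty(500)
        for r in range(500):
            z1 = draw_z(Lv, rng, mean_z)
            z2 = draw_z(Lv, rng, mean_z)
            ests[r] = localrg.local_rcov(z1, z2, n, n, ld, c=0.0)[0]
        se = ests.std(ddof=1) / np.sqrt(500)
        assert abs(ests.mean() - 0.0005) < 2 * se

    def test_sign_symmetry(self, ld, small_V):
        V, Lv = small_V
        rng = np.random.default_rng(24)
        z1, z2 = draw_z(Lv, rng), draw_z(Lv, rng)
        n1, n2 = 30_000, 30_000
        rho, var = localrg.local_rcov(z1, z2, n1, n2, ld)
        rho_neg, var_neg = localrg.local_rcov(z1, -z2, n1, n2, ld)
        assert rho_neg == pytest.approx(-rho)
        assert var_neg == pytest.approx(var)


class TestLocalRgRatio:
    def test_perfect_correlation(self):
        assert localrg.local_rg(0.002, 0.002, 0.002) == (1.0, None)

    def test_undefined_on_nonpositive_h2(self):
        rg, reason = localrg.local_rg(0.001, -0.0002, 0.003)
        assert rg is None and "nonpositive" in reason

    def test_clamped_when_noise_pushes_over_one(self):
        rg, reason = localrg.local_rg(0.004, 0.001, 0.001)
        assert rg == 1.0 and "clamped" in reason

    def test_recovery_of_planted_rg(self, ld, small_V):
        """Mixed shared/independent effects, planted rg = 0.5, 500 replicates."""
        V, Lv = small_V
        n = 100_000
        rng = np.random.default_rng(25)
        # plant exactly: build V-orthonormal directions u1, u2 (u_i' V u_j =
        # delta_ij) and mix a shared with an independent component
        vals, vecs = np.linalg.eigh(V)
        u1 = vecs[:, -1] / np.sqrt(vals[-1])
        u2 = vecs[:, -2] / np.sqrt(vals[-2])
        h2_target, rg_target = 0.004, 0.5
        b1 = np.sqrt(h2_target) * u1
        b2 = np.sqrt(h2_target) * (rg_target * u1 + np.sqrt(1 - rg_target**2) * u2)
        rho_true = float(b1 @ V @ b2)
        rg_true = rho_true / np.sqrt((b1 @ V @ b1) * (b2 @ V @ b2))
        m1, m2 = np.sqrt(n) * (V @ b1), np.sqrt(n) * (V @ b2)
        ests = np.empty(500)
        for r in range(500):
            z1, z2 = draw_z(Lv, rng, m1), draw_z(Lv, rng, m2)
            h2_1 = localrg.local_h2(z1, n, ld)[0]
            h2_2 = localrg.local_h2(z2, n, ld)[0]
            rho = localrg.local_rcov(z1, z2, n, n, ld)[0]
            rg, _ = localrg.local_rg(rho, h2_1, h2_2)
            ests[r] = rg
        se = ests.std(ddof=1) / np.sqrt(500)
        assert abs(ests.mean() - rg_true) < 2 * se
        assert rg_true == pytest.approx(0.5, abs=1e-9)


class TestScanBlocks:
    def test_bonferroni_thresholds(self):
        assert localrg.bonferroni_threshold(1703) == pytest.approx(2.94e-5, abs=5e-8)
        assert localrg.bonferroni_threshold(1) == 0.05

    def test_null_z_rho_standard_normal(self, ld, small_V):
        """KS check of z_rho over 2,000 blocks: heritable traits with
        disjoint causal sets (c = 0, no shared effects)."""
        V, Lv = small_V
        rng = np.random.default_rng(26)
        n1, n2 = 40_000, 40_000
        # disjoint causal variants, zero genetic covariance by orthogonality
        vals, vecs = np.linalg.eigh(V)
        u1 = vecs[:, -1] / np.sqrt(vals[-1])
        u2 = vecs[:, -2] / np.sqrt(vals[-2])
        b1 = np.sqrt(0.001) * u1
        b2 = np.sqrt(0.001) * u2
        m1 = np.sqrt(n1) * (V @ b1)
        m2 = np.sqrt(n2) * (V @ b2)
        zs = np.empty(2000)
        for r in range(2000):
            z1, z2 = draw_z(Lv, rng, m1), draw_z(Lv, rng, m2)
            rho, var = localrg.local_rcov(z1, z2, n1, n2, ld)
            zs[r] = rho / np.sqrt(var)
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_single_planted_block_flagged(self):
        """20-block genome, one block with shared signal: that block and only
        that block is flagged in >= 95% of replicates."""
        reps = 200
        n_blocks = 20
        m_per = 20
        # a large panel keeps cross-block sampling LD (~1/sqrt(n_panel)) from
        # leaking planted effects into null blocks
        traits = [sim.TraitSpec("a", 40_000, 40_000), sim.TraitSpec("b", 40_000, 40_000)]
        cfg = sim.SimConfig(
            seed=31, m_snps=n_blocks * m_per, n_panel=8000, ld_rho=0.5,
            block_sizes=[m_per] * n_blocks, traits=traits,
        )
        panel = sim.simulate_panel(cfg)
        blocks = sim.blocks_of(cfg)
        target_block = 7
        idx = target_block * m_per + np.array([5, 14])
        hits = misses = 0
        for rep in range(reps):
            cfg_r = sim.SimConfig(
                seed=1000 + rep, m_snps=cfg.m_snps, n_panel=cfg.n_panel,
                ld_rho=0.5, block_sizes=[m_per] * n_blocks, traits=traits,
                causals=[
                    sim.CausalSpec(int(i), {
                        "a": 10.0 / np.sqrt(traits[0].n_eff),
                        "b": 10.0 / np.sqrt(traits[1].n_eff),
                    })
                    for i in idx
                ],
            )
            tables, _ = sim.simulate_sumstats(panel, cfg_r)
            results, thr = localrg.scan_blocks(tables, panel, blocks)
            sig = {r.block.block_id for r in results if r.significant}
            if sig == {blocks[target_block].block_id}:
                hits += 1
            else:
                misses += 1
        assert hits / reps >= 0.95

    def test_pair_order_symmetry(self, small_panel):
        cfg = sim.SimConfig(
            seed=33, m_snps=100, n_panel=2000, ld_rho=0.7,
            traits=[sim.TraitSpec("a", 30_000, 30_000), sim.TraitSpec("b", 20_000, 20_000)],
        )
        tables, _ = sim.simulate_sumstats(small_panel, cfg)
        block = sim.blocks_of(
            sim.SimConfig(seed=11, m_snps=100, n_panel=1, traits=cfg.traits)
        )[0]
        fwd, _ = localrg.scan_blocks(tables, small_panel, [block])
        rev, _ = localrg.scan_blocks(tables[::-1], small_panel, [block])
        assert fwd[0].pval == pytest.approx(rev[0].pval)
        assert fwd[0].rho == pytest.approx(rev[0].rho)
        assert fwd[0].trait_pair == tuple(reversed(rev[0].trait_pair))
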
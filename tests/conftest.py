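"""Shared fixtures: small synthetic panels and summary-statistic tables."""

import numpy as np
import pytest

from pleiofine import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """100-SNP, 2,000-sample panel with moderate AR(1) LD."""
    cfg = sim.SimConfig(
        seed=11,
        m_snps=100,
        n_panel=2000,
        ld_rho=0.7,
        traits=[sim.TraitSpec("t1", 10_000, 10_000)],
    )
    return sim.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_V(small_panel):
    """Empirical LD of the small panel plus a square root for noise draws."""
    X = small_panel.dosage - small_panel.dosage.mean(axis=0, keepdims=True)
    Xs = X / X.std(axis=0)
    V = (Xs.T @ Xs) / small_panel.n_samples
    np.fill_diagonal(V, 1.0)
    V = (V + V.T) / 2.0
    vals, vecs = np.linalg.eigh(V)
    Lv = vecs * np.sqrt(np.clip(vals, 0, None))[None, :]
    return V, Lv


def draw_z(Lv, rng, mean=0.0):
    """One z-vector from N(mean, V) given a square root of V."""
    return mean + Lv @ rng.standard_normal(Lv.shape[1])
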
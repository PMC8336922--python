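"""Synthetic test bed: genotype panels, multi-trait summary statistics, annotations.

The generator produces exactly the data-generating process the regional
estimators assume:

* a diploid reference panel whose haplotypes come from an AR(1)-correlated
  latent Gaussian thresholded at frequency-specific cutoffs.  The chain's
  ``ld_rho`` parameter is the *target adjacent-SNP dosage correlation*; the
  latent correlation is found per pair by inverting the thresholded-binary
  correlation (a tetrachoric inversion), so planted LD levels carry through
  the discretization.  Allele frequencies follow a slow random walk along
  the chain, mirroring the empirical fact that tightly linked variants have
  similar frequencies;
* per-trait marginal z-scores z_t = sqrt(n_t) V beta_t + eps_t with V the
  panel's empirical LD and cross-trait noise Cov(eps_t, eps_t') = c_tt' V,
  where c_tt' = n_shared rho_p / sqrt(n_t n_t') models shared controls;
* binary annotation peaks placed around causal SNPs with a configurable
  enrichment probability, plus uniform background peaks.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri, owens_t

from pleiofine.ldref import GenotypePanel, LDBlock
from pleiofine.overlap import OverlapMatrix
from pleiofine.sumstats import SumStatTable

# emitted pairs are their own strand-canonical representation, so simulated
# marker IDs survive harmonization unchanged ((C,T) would canonicalize to
# (A,G), (G,T) to (A,C))
_ALLELE_PAIRS = [("A", "C"), ("A", "G")]


@dataclass
class TraitSpec:
    name: str
    n_cases: int
    n_controls: int

    @property
    def n_eff(self) -> float:
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class CausalSpec:
    """One causal variant: global SNP index and per-trait standardized effects."""

    index: int
    effects: dict[str, float]


@dataclass
class SimConfig:
    """Study conditions for one synthetic region (or multi-block genome)."""

    seed: int = 0
    m_snps: int = 3000
    n_panel: int = 5000
    ld_rho: float | list[float] = 0.9
    block_sizes: list[int] | None = None
    chrom: str = "5"
    pos_start: int = 1_000_000
    pos_spacing: int = 100
    freq_range: tuple[float, float] = (0.1, 0.9)
    freq_walk_sd: float = 0.02
    traits: list[TraitSpec] = field(default_factory=list)
    shared_controls: dict[tuple[str, str], int] = field(default_factory=dict)
    rho_p: float = 1.0
    c_override: np.ndarray | None = None  # direct cross-trait score correlation
    causals: list[CausalSpec] = field(default_factory=list)
    peak_width: int = 200
    enrichment_prob: float = 1.0
    n_background_peaks: int = 30

    def __post_init__(self):
        if self.block_sizes is None:
            self.block_sizes = [self.m_snps]
        if sum(self.block_sizes) != self.m_snps:
            raise ValueError("block sizes must sum to m_snps")
        if np.isscalar(self.ld_rho):
            self.ld_rho = [float(self.ld_rho)] * len(self.block_sizes)
        if len(self.ld_rho) != len(self.block_sizes):
            raise ValueError("need one ld_rho per block")
        names = {t.name for t in self.traits}
        for (a, b), ns in self.shared_controls.items():
            if a not in names or b not in names:
                raise ValueError(f"shared-control pair ({a}, {b}) names unknown trait")
            cap = min(
                next(t.n_controls for t in self.traits if t.name == a),
                next(t.n_controls for t in self.traits if t.name == b),
            )
            if ns > cap:
                raise ValueError(f"n_shared={ns} exceeds controls of pair ({a}, {b})")

    def trait(self, name: str) -> TraitSpec:
        return next(t for t in self.traits if t.name == name)


def _bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T (vectorized)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -0.9999999, 0.9999999)
    h = np.where(np.abs(h) < 1e-10, 1e-10, h)
    k = np.where(np.abs(k) < 1e-10, 1e-10, k)
    s = np.sqrt(1.0 - rho**2)
    a1 = (k / h - rho) / s
    a2 = (h / k - rho) / s
    delta = np.where(h * k > 0, 0.0, 0.5)
    return 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2) - delta


def _binary_corr(rho, a, b):
    """Correlation of 1{X<z_a}, 1{Y<z_b} under latent correlation rho."""
    h = ndtri(a)
    k = ndtri(b)
    p11 = _bvn_cdf(h, k, rho)
    return (p11 - a * b) / np.sqrt(a * (1 - a) * b * (1 - b))


def _latent_rho(target, a, b, iters: int = 60):
    """Invert the thresholded-binary correlation: vectorized bisection.

    Targets outside the attainable (Frechet) range are clipped with a
    warning.
    """
    target = np.asarray(target, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo_val = _binary_corr(np.full_like(target, -0.9999), a, b)
    hi_val = _binary_corr(np.full_like(target, 0.9999), a, b)
    clipped = np.clip(target, lo_val + 1e-9, hi_val - 1e-9)
    if np.any(np.abs(clipped - target) > 0.02):
        warnings.warn("some target LD values exceed the attainable range; clipped")
    lo = np.full_like(target, -0.9999)
    hi = np.full_like(target, 0.9999)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        val = _binary_corr(mid, a, b)
        lo = np.where(val < clipped, mid, lo)
        hi = np.where(val < clipped, hi, mid)
    return 0.5 * (lo + hi)


def _simulate_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.freq_range
    freqs = np.empty(config.m_snps)
    i = 0
    for size, rho in zip(config.block_sizes, config.ld_rho):
        if rho == 0:
            freqs[i : i + size] = rng.uniform(lo, hi, size)
        else:
            f = rng.uniform(lo, hi)
            for j in range(size):
                freqs[i + j] = f
                f = f + rng.normal(0, config.freq_walk_sd)
                # reflect off the range bounds so neighbors stay close
                if f > hi:
                    f = 2 * hi - f
                if f < lo:
                    f = 2 * lo - f
                f = float(np.clip(f, lo, hi))
        i += size
    return freqs


def simulate_panel(config: SimConfig) -> GenotypePanel:
    """Simulate the diploid genotype reference panel for one config."""
    rng = np.random.default_rng([config.seed, 0])
    m = config.m_snps
    freqs = _simulate_frequencies(config, rng)
    cut = ndtri(freqs)

    # latent AR(1) step correlations per adjacent pair, inverted per block
    step = np.zeros(m)  # step[j] links SNP j-1 -> j; block starts get 0
    i = 0
    for size, rho in zip(config.block_sizes, config.ld_rho):
        if size > 1 and rho != 0:
            idx = np.arange(i + 1, i + size)
            step[idx] = _latent_rho(
                np.full(size - 1, rho), freqs[idx - 1], freqs[idx]
            )
        i += size

    n_hap = 2 * config.n_panel
    latent = np.empty((n_hap, m))
    latent[:, 0] = rng.standard_normal(n_hap)
    noise = rng.standard_normal((n_hap, m))
    for j in range(1, m):
        r = step[j]
        latent[:, j] = r * latent[:, j - 1] + np.sqrt(1.0 - r**2) * noise[:, j]
    alleles_hap = (latent < cut[None, :]).astype(np.int8)
    dosage = (alleles_hap[0::2] + alleles_hap[1::2]).astype(float)

    # resample any monomorphic column (vanishing probability at default sizes)
    mono = np.flatnonzero(dosage.std(axis=0) == 0)
    if len(mono):
        warnings.warn(f"resampled {len(mono)} monomorphic variant(s)")
        for j in mono:
            hap = (rng.random((n_hap,)) < freqs[j]).astype(np.int8)
            while hap.min() == hap.max():
                hap = (rng.random((n_hap,)) < freqs[j]).astype(np.int8)
            dosage[:, j] = hap[0::2] + hap[1::2]

    pos = config.pos_start + config.pos_spacing * np.arange(m, dtype=np.int64)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    snp_ids, alleles = [], []
    for j in range(m):
        a_min, a_max = _ALLELE_PAIRS[pair_idx[j]]
        # effect (counted) allele is the canonical lexicographically smaller one
        snp_ids.append(f"{config.chrom}:{pos[j]}:{a_min}:{a_max}")
        alleles.append((a_max, a_min))  # (REF, ALT); dosage counts ALT
    samples = [f"S{i:05d}" for i in range(config.n_panel)]
    return GenotypePanel(
        samples,
        snp_ids,
        np.array([config.chrom] * m, dtype=object),
        pos,
        alleles,
        dosage,
    )


def blocks_of(config: SimConfig) -> list[LDBlock]:
    """The config's LD-block partition as 1-based inclusive blocks."""
    blocks = []
    i = 0
    for b, size in enumerate(config.block_sizes):
        start = config.pos_start + config.pos_spacing * i
        end = config.pos_start + config.pos_spacing * (i + size - 1)
        blocks.append(LDBlock(config.chrom, int(start), int(end), block_id=f"block{b}"))
        i += size
    return blocks


def overlap_target_matrix(config: SimConfig) -> OverlapMatrix:
    """Planted cross-trait null-score correlation c = n_s rho_p / sqrt(n1 n2)."""
    names = [t.name for t in config.traits]
    K = len(names)
    if config.c_override is not None:
        return OverlapMatrix(names, np.asarray(config.c_override, dtype=float))
    C = np.eye(K)
    for (a, b), ns in config.shared_controls.items():
        i, j = names.index(a), names.index(b)
        c = ns * config.rho_p / np.sqrt(config.trait(a).n_eff * config.trait(b).n_eff)
        C[i, j] = C[j, i] = c
    return OverlapMatrix(names, C)


def simulate_sumstats(
    panel: GenotypePanel, config: SimConfig
) -> tuple[list[SumStatTable], dict]:
    """Draw per-trait marginal summary statistics from the generative model.

    Returns the tables plus a ground-truth manifest (causal indices,
    effects, planted C, per-trait local heritability contribution).
    """
    rng = np.random.default_rng([config.seed, 1])
    m = panel.n_variants
    K = len(config.traits)
    names = [t.name for t in config.traits]

    X = panel.dosage - panel.dosage.mean(axis=0, keepdims=True)
    Xs = X / X.std(axis=0)
    n_pan = panel.n_samples

    C = overlap_target_matrix(config).C
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        off = C[np.triu_indices(K, 1)]
        raise ValueError(
            f"cross-trait covariance not positive definite; c values: {off}"
        ) from err

    B = np.zeros((m, K))
    for spec in config.causals:
        for trait, beta in spec.effects.items():
            B[spec.index, names.index(trait)] = beta

    n_eff = np.array([t.n_eff for t in config.traits])
    # V beta and noise ~ N(0, C (x) V) via the low-rank factor Xs / sqrt(n):
    # Cov(Xs' g / sqrt(n)) = Xs' Xs / n = V exactly, without forming V
    mean = (Xs.T @ (Xs @ B) / n_pan) * np.sqrt(n_eff)[None, :]
    eps = (Xs.T @ rng.standard_normal((n_pan, K)) / np.sqrt(n_pan)) @ Lc.T
    Z = mean + eps

    alt_freq = panel.dosage.mean(axis=0) / 2.0
    tables = []
    for k, t in enumerate(config.traits):
        se = 1.0 / np.sqrt(n_eff[k])
        z = Z[:, k]
        df = pd.DataFrame(
            {
                "snp_id": panel.snp_ids,
                "chrom": panel.chrom,
                "pos": panel.pos,
                "effect_allele": [a[1] for a in panel.alleles],
                "other_allele": [a[0] for a in panel.alleles],
                "eaf": alt_freq,
                "beta": z * se,
                "se": se,
                "pval": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
                "info": 1.0,
            }
        )
        tables.append(SumStatTable(t.name, t.n_cases, t.n_controls, df))

    XB = Xs @ B
    local_h2 = {names[k]: float(XB[:, k] @ XB[:, k] / n_pan) for k in range(K)}
    truth = {
        "seed": config.seed,
        "causal_indices": [s.index for s in config.causals],
        "causal_snp_ids": [panel.snp_ids[s.index] for s in config.causals],
        "effects": [
            {"index": s.index, "snp_id": panel.snp_ids[s.index], "effects": s.effects}
            for s in config.causals
        ],
        "C": C.tolist(),
        "local_h2": local_h2,
    }
    return tables, truth


def simulate_annotations(
    panel: GenotypePanel, config: SimConfig
) -> dict[str, list[tuple[str, int, int]]]:
    """Peak intervals (BED 0-based half-open) enriched around causal SNPs."""
    rng = np.random.default_rng([config.seed, 2])
    w = config.peak_width
    lo = int(panel.pos.min())
    hi = int(panel.pos.max())
    intervals: list[tuple[str, int, int]] = []
    for spec in config.causals:
        if rng.random() < config.enrichment_prob:
            p0 = int(panel.pos[spec.index]) - 1  # 0-based
            intervals.append((config.chrom, p0 - w // 2, p0 + w // 2 + 1))
    for _ in range(config.n_background_peaks):
        start = int(rng.integers(lo, hi)) - 1
        intervals.append((config.chrom, start, start + w))
    intervals.sort(key=lambda iv: iv[1])
    return {"causal_enriched": intervals}


def simulate_overlap_study(
    base: SimConfig, n_chunks: int = 20
) -> list[SumStatTable]:
    """Null multi-trait summary statistics spanning many independent LD chunks.

    Overlap estimation is a genome-wide exercise: its Monte-Carlo error is
    governed by the number of *independent* null SNPs, while any one panel
    yields at most ``n_panel`` independent noise dimensions (the rank of its
    empirical LD).  This helper therefore simulates ``n_chunks`` independent
    panels (seeds ``base.seed + i``, shifted positions) and concatenates the
    per-trait tables, emulating genome-wide data at desk scale.
    """
    parts: dict[str, list[pd.DataFrame]] = {t.name: [] for t in base.traits}
    span = base.m_snps * base.pos_spacing + base.pos_spacing
    for i in range(n_chunks):
        cfg = SimConfig(
            seed=base.seed + i,
            m_snps=base.m_snps,
            n_panel=base.n_panel,
            ld_rho=base.ld_rho if np.isscalar(base.ld_rho) else list(base.ld_rho),
            block_sizes=None if len(base.block_sizes) == 1 else list(base.block_sizes),
            chrom=base.chrom,
            pos_start=base.pos_start + i * span,
            pos_spacing=base.pos_spacing,
            freq_range=base.freq_range,
            freq_walk_sd=base.freq_walk_sd,
            traits=base.traits,
            shared_controls=base.shared_controls,
            rho_p=base.rho_p,
        )
        panel = simulate_panel(cfg)
        tables, _ = simulate_sumstats(panel, cfg)
        for t in tables:
            parts[t.trait_name].append(t.df)
    out = []
    for t in base.traits:
        df = pd.concat(parts[t.name], ignore_index=True)
        out.append(SumStatTable(t.name, t.n_cases, t.n_controls, df))
    return out


def write_bed(intervals: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_blocks_bed(blocks: list[LDBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.block_id}\n")


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a plain-text VCF 4.2 with GT fields."""
    gt_codes = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        dosage_int = np.rint(panel.dosage).astype(int)
        for j in range(panel.n_variants):
            ref, alt = panel.alleles[j]
            gts = "\t".join(gt_codes[dosage_int[:, j]])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def flagship_config(seed: int = 0) -> SimConfig:
    """The default end-to-end study conditions.

    Eight case-control traits with the sample-size spread of large cancer
    GWAS consortia, a 3,000-SNP region (the scale of the 5p15.33 LD block),
    three planted cross-trait causal variants -- one with opposite effect
    directions across traits -- and one pair of studies with shared
    controls.  Standardized effects are set to give per-trait marginal
    |z| around 8-12 at the causal SNPs.
    """
    traits = [
        TraitSpec("erneg_breast", 21_468, 100_564),
        TraitSpec("colorectal", 55_168, 65_160),
        TraitSpec("glioma", 12_488, 18_169),
        TraitSpec("lung", 29_266, 56_450),
        TraitSpec("melanoma", 12_814, 23_203),
        TraitSpec("ovarian", 22_406, 40_951),
        TraitSpec("pancreatic", 8_638, 12_217),
        TraitSpec("prostate", 79_166, 61_106),
    ]

    def z_to_beta(trait: TraitSpec, z: float) -> float:
        return z / np.sqrt(trait.n_eff)

    t = {x.name: x for x in traits}
    causals = [
        CausalSpec(
            index=1000,
            effects={
                "erneg_breast": z_to_beta(t["erneg_breast"], 12.0),
                "glioma": z_to_beta(t["glioma"], 10.0),
                "pancreatic": z_to_beta(t["pancreatic"], -8.0),
                "prostate": z_to_beta(t["prostate"], -12.0),
            },
        ),
        CausalSpec(
            index=2000,
            effects={
                "melanoma": z_to_beta(t["melanoma"], 9.0),
                "pancreatic": z_to_beta(t["pancreatic"], 9.0),
                "lung": z_to_beta(t["lung"], -10.0),
            },
        ),
        CausalSpec(
            index=400,
            effects={
                "erneg_breast": z_to_beta(t["erneg_breast"], 9.0),
                "prostate": z_to_beta(t["prostate"], -9.0),
            },
        ),
    ]
    # shared controls between the breast and ovarian studies, at the scale
    # reported for large consortium GWAS pairs (score correlation ~0.05)
    n_eff_bo = np.sqrt(t["erneg_breast"].n_eff * t["ovarian"].n_eff)
    shared = {("erneg_breast", "ovarian"): int(round(0.05 * n_eff_bo))}
    return SimConfig(
        seed=seed,
        m_snps=3000,
        n_panel=5000,
        ld_rho=0.9,
        traits=traits,
        shared_controls=shared,
        causals=causals,
        peak_width=200,
        enrichment_prob=1.0,
        n_background_peaks=40,
    )
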
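"""Single-causal-variant multi-trait fine-mapping, annotation priors, colocalization.

Under the one-causal-variant assumption, with per-trait z-scores already
conditioned on the region's other lead signals, the evidence that SNP j is
the causal variant is the product over traits of Wakefield-style
approximate Bayes factors.  On the standardized scale (effect prior
variance ``w_prior``, effect standard error 1/sqrt(n_eff)):

    log ABF = 1/2 log(1 - r) + z^2 r / 2,    r = w_prior / (w_prior + 1/n_eff)

Posterior probabilities of causality are the prior-weighted, normalized
per-SNP products; binary functional annotations enter through a softmax
prior whose enrichment coefficients are fitted by EM across signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)


def log_abf(z, n_eff: float, w_prior: float = 0.04):
    """Log approximate Bayes factor for one variant (vectorized over z)."""
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    z = np.asarray(z, dtype=float)
    r = w_prior / (w_prior + 1.0 / n_eff)
    out = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return float(out) if out.ndim == 0 else out


@dataclass
class AnnotationTrack:
    """One binary annotation (e.g. open chromatin peaks for a tissue)."""

    name: str
    intervals: list[tuple[str, int, int]]  # (chrom, start, end), BED 0-based half-open
    indicator: np.ndarray | None = None    # per-SNP {0,1}, set by annotate_snps


@dataclass
class AnnotationModel:
    """Softmax prior over a region's SNPs with per-annotation enrichments.

    prior_j proportional to exp(gamma0 + sum_t gamma_t a_jt), normalized over
    the region's SNPs.  gamma0 cancels in the normalization and is kept at 0;
    gamma = 0 recovers the uniform prior.
    """

    track_names: list[str]
    gamma: np.ndarray
    gamma0: float = 0.0
    loglik: float = float("nan")

    def prior(self, A: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        eta = self.gamma0 + A @ self.gamma
        return np.exp(eta - logsumexp(eta))


@dataclass
class CredibleSet:
    """Fine-mapping output for one signal."""

    signal: str
    traits: list[str]
    snp_ids: list[str]
    pp: np.ndarray
    set95: list[str]
    top_snp: str
    top_pp: float

    def __post_init__(self):
        if not np.isclose(self.pp.sum(), 1.0, atol=1e-8):
            raise ValueError("posterior probabilities must sum to 1")


def _credible_set(snp_ids: list[str], pp: np.ndarray, level: float = 0.95) -> list[str]:
    order = np.argsort(-pp, kind="stable")
    cum = np.cumsum(pp[order])
    k = int(np.searchsorted(cum, level - 1e-12) + 1)
    k = min(k, len(snp_ids))
    return [snp_ids[i] for i in order[:k]]


def multitrait_pp(
    signal: str,
    snp_ids: list[str],
    z_by_trait: dict[str, np.ndarray],
    n_eff_by_trait: dict[str, float],
    prior: np.ndarray | None = None,
    w_prior: float = 0.04,
    level: float = 0.95,
) -> CredibleSet:
    """Posterior probabilities of causality across traits for one signal.

    ``z_by_trait`` holds per-trait z-vectors aligned to ``snp_ids`` and
    already conditioned on the region's other lead SNPs; every SNP must be
    observed in every included trait.  ``prior`` is a per-SNP prior
    probability vector (uniform when None).
    """
    if not snp_ids:
        raise ValueError("empty SNP intersection")
    m = len(snp_ids)
    logbf = np.zeros(m)
    for trait, z in z_by_trait.items():
        z = np.asarray(z, dtype=float)
        if z.shape != (m,):
            raise ValueError(f"trait {trait}: z not aligned to snp_ids")
        if not np.isfinite(z).all():
            raise ValueError(f"trait {trait}: non-finite conditional z")
        logbf += log_abf(z, n_eff_by_trait[trait], w_prior)
    if prior is None:
        log_prior = np.zeros(m)
    else:
        prior = np.asarray(prior, dtype=float)
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
    logpost = log_prior + logbf
    pp = np.exp(logpost - logsumexp(logpost))
    pp /= pp.sum()
    set95 = _credible_set(snp_ids, pp, level)
    return CredibleSet(
        signal=signal,
        traits=sorted(z_by_trait),
        snp_ids=list(snp_ids),
        pp=pp,
        set95=set95,
        top_snp=set95[0],
        top_pp=float(pp.max()),
    )


def annotate_snps(snps: pd.DataFrame, bed_paths: dict[str, str] | list) -> list[AnnotationTrack]:
    """Binary annotation indicators by interval overlap.

    ``snps`` needs columns chrom and pos (1-based).  BED intervals are
    0-based half-open, so a 1-based position p is inside [start, end) iff
    start <= p - 1 < end.  Malformed lines are skipped with a log entry.
    """
    if not isinstance(bed_paths, dict):
        bed_paths = {str(p): p for p in bed_paths}
    chrom = snps["chrom"].astype(str).str.removeprefix("chr").to_numpy()
    pos0 = snps["pos"].to_numpy(dtype=np.int64) - 1
    tracks = []
    for name, path in bed_paths.items():
        intervals: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                try:
                    c, s, e = parts[0].removeprefix("chr"), int(parts[1]), int(parts[2])
                    if s >= e:
                        raise ValueError
                except (IndexError, ValueError):
                    logger.info("%s: skipped malformed interval line: %r", path, line)
                    continue
                intervals.append((c, s, e))
        indicator = np.zeros(len(snps), dtype=np.int8)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in intervals:
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            sel = chrom == c
            k = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = (k >= 0) & (pos0[sel] < ends[np.clip(k, 0, None)])
            indicator[np.flatnonzero(sel)[ok]] = 1
        tracks.append(AnnotationTrack(name=str(name), intervals=intervals, indicator=indicator))
    return tracks


def fit_annotation_prior(
    signal_logbfs: list[np.ndarray],
    tracks: list[AnnotationTrack],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> AnnotationModel:
    """Fit annotation enrichment coefficients by EM across signals.

    ``signal_logbfs`` holds, per signal, the summed-over-traits log Bayes
    factors aligned to the region's SNPs; ``tracks`` carry the region's
    binary indicators.  Maximizes sum_s log sum_j prior_j(gamma) BF_sj.
    Annotations constant across all SNPs are non-identifiable and their
    gamma is fixed at 0 with a warning.
    """
    A = np.column_stack([t.indicator for t in tracks]).astype(float)
    names = [t.name for t in tracks]
    m, n_tracks = A.shape
    for lb in signal_logbfs:
        if np.asarray(lb).shape != (m,):
            raise ValueError("signal log-BF vector not aligned to annotation matrix")
    constant = np.array([np.all(A[:, t] == A[0, t]) for t in range(n_tracks)])
    if constant.any():
        warnings.warn(
            f"annotations constant across SNPs, gamma fixed at 0: "
            f"{[names[t] for t in np.flatnonzero(constant)]}"
        )
    free = np.flatnonzero(~constant)
    LB = np.vstack([np.asarray(lb, dtype=float) for lb in signal_logbfs])
    S = LB.shape[0]

    def loglik(gamma_full: np.ndarray) -> float:
        eta = A @ gamma_full
        log_prior = eta - logsumexp(eta)
        return float(logsumexp(LB + log_prior[None, :], axis=1).sum())

    gamma = np.zeros(n_tracks)
    prev = loglik(gamma)
    for _ in range(max_iter):
        # E-step: per-signal posterior over SNPs
        eta = A @ gamma
        log_prior = eta - logsumexp(eta)
        W = LB + log_prior[None, :]
        PP = np.exp(W - logsumexp(W, axis=1, keepdims=True))
        pbar = PP.mean(axis=0)

        # M-step: softmax regression of pbar on the annotation columns
        if len(free):
            def neg_q(g_free):
                g = np.zeros(n_tracks)
                g[free] = g_free
                eta = A @ g
                return -(pbar @ eta - logsumexp(eta))

            def grad_q(g_free):
                g = np.zeros(n_tracks)
                g[free] = g_free
                eta = A @ g
                pr = np.exp(eta - logsumexp(eta))
                return -(A[:, free].T @ (pbar - pr))

            res = optimize.minimize(neg_q, gamma[free], jac=grad_q, method="BFGS")
            gamma = np.zeros(n_tracks)
            gamma[free] = res.x
        cur = loglik(gamma)
        if cur - prev < tol * S:
            prev = cur
            break
        prev = cur
    return AnnotationModel(track_names=names, gamma=gamma, loglik=prev)


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) with a >= b, -inf when they coincide."""
    if b >= a:
        return float("-inf")
    return a + np.log1p(-np.exp(b - a))


def colocalize_pair(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    maf: np.ndarray | None = None,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w_prior: float = 0.04,
) -> dict[str, float]:
    """Five-hypothesis Bayesian colocalization for two traits in one region.

    Hypotheses: H0 no causal variant; H1/H2 causal in trait 1/2 only; H3 two
    distinct causal variants; H4 one shared causal variant.  Per-SNP log
    ABFs are on the standardized scale, so ``maf`` is accepted for interface
    compatibility but does not enter the Bayes factors.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z-vectors must be aligned")
    if len(z1) < 10:
        warnings.warn("fewer than 10 SNPs: colocalization estimates are unstable")
    l1 = log_abf(z1, n1, w_prior)
    l2 = log_abf(z2, n2, w_prior)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _logdiff(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return {f"PP{i}": float(pp[i]) for i in range(5)}
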
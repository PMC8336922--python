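"""LD reference machinery: genotype panels, LD blocks, truncated pseudo-inverse.

Positions follow the genomics double convention: BED files on disk are
0-based half-open; every in-memory coordinate is 1-based inclusive.

The :class:`LDMatrix` carries the Pearson dosage correlation ``R`` together
with its eigendecomposition and a rank-``q`` pseudo-inverse.  Truncation is
required because a panel-estimated ``R`` over m SNPs has rank at most
min(m, n_panel - 1) and its small eigenvalues are dominated by sampling
noise; the retained rank feeds the quadratic-form estimators downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleiofine.sumstats import _chrom_sort_key, canonical_marker


@dataclass
class LDBlock:
    """One approximately independent LD block, 1-based inclusive bounds."""

    chrom: str
    start: int
    end: int
    block_id: str = ""

    def __post_init__(self):
        self.chrom = str(self.chrom).removeprefix("chr")
        if self.start > self.end:
            raise ValueError(f"block start {self.start} > end {self.end}")
        if not self.block_id:
            self.block_id = f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom).removeprefix("chr") == self.chrom and self.start <= pos <= self.end


@dataclass
class GenotypePanel:
    """Reference genotypes as a dosage matrix (individuals x variants)."""

    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: list[tuple[str, str]]
    dosage: np.ndarray  # (n_samples, n_variants), values in [0, 2]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset(self, snp_ids: list[str]) -> "GenotypePanel":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"variants not in panel: {missing[:5]}")
        idx = [index[s] for s in snp_ids]
        return GenotypePanel(
            self.sample_ids,
            [self.snp_ids[i] for i in idx],
            self.chrom[idx],
            self.pos[idx],
            [self.alleles[i] for i in idx],
            self.dosage[:, idx],
        )


@dataclass
class LDMatrix:
    """SNP-by-SNP correlation matrix with truncated eigendecomposition."""

    snp_ids: list[str]
    R: np.ndarray
    eigvals: np.ndarray = field(default=None)  # descending
    eigvecs: np.ndarray = field(default=None)  # columns match eigvals
    q: int | None = None
    R_pinv: np.ndarray | None = None
    n_samples: int | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("R shape does not match snp_ids")

    def ensure_eigen(self) -> None:
        """Compute the (descending) eigendecomposition once, on demand."""
        if self.eigvals is None:
            vals, vecs = np.linalg.eigh(self.R)
            order = np.argsort(vals)[::-1]
            self.eigvals = vals[order]
            self.eigvecs = vecs[:, order]

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def submatrix(self, snp_ids: list[str]) -> "LDMatrix":
        """Correlation submatrix for a subset of SNPs (no truncation carried)."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.R[np.ix_(idx, idx)], n_samples=self.n_samples)


def load_panel(vcf_path, sample_subset=None, region: LDBlock | None = None) -> GenotypePanel:
    """Load biallelic dosages from a VCF, mean-imputing missing genotypes.

    Uses the DS FORMAT field when present, otherwise the GT allele count.
    Monomorphic (zero-variance) variants are dropped.  ``region`` filters by
    1-based inclusive bounds; chromosome names are compared without a
    ``chr`` prefix.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), samples=sample_subset, gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples available in {vcf_path}")

    snp_ids, chroms, poss, alleles, cols = [], [], [], [], []
    for var in vcf:
        chrom = str(var.CHROM).removeprefix("chr")
        pos = var.POS
        if region is not None and not region.contains(chrom, pos):
            continue
        if len(var.ALT) != 1:
            continue
        fmts = var.FORMAT
        if "DS" in fmts:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            ds = np.where(np.isfinite(ds), ds, np.nan)
        else:
            gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown
            ds = np.where(gt == 3, np.nan, gt)
        if np.isnan(ds).any():
            mean = np.nanmean(ds)
            if np.isnan(mean):
                continue
            ds = np.where(np.isnan(ds), mean, ds)
        if np.var(ds) <= 0:
            continue
        snp_ids.append(
            var.ID or canonical_marker(chrom, pos, var.REF, var.ALT[0])
        )
        chroms.append(chrom)
        poss.append(pos)
        alleles.append((var.REF.upper(), var.ALT[0].upper()))
        cols.append(ds)
    if not cols:
        raise ValueError(f"no usable variants in {vcf_path} for region {region}")
    dosage = np.column_stack(cols)
    return GenotypePanel(samples, snp_ids, np.array(chroms, dtype=object),
                         np.array(poss, dtype=np.int64), alleles, dosage)


def compute_ld(
    panel: GenotypePanel,
    snp_ids: list[str] | None = None,
    var_frac: float = 0.995,
    q_max: int | None = None,
) -> LDMatrix:
    """Pearson dosage-correlation matrix for the given SNPs, with truncation.

    A single SNP yields the 1x1 matrix [1].
    """
    ld = panel_correlation(panel, snp_ids)
    return truncate_pinv(ld, var_frac=var_frac, q_max=q_max)


def panel_correlation(panel: GenotypePanel, snp_ids: list[str] | None = None) -> LDMatrix:
    """Pearson dosage correlation without eigendecomposition or truncation.

    Cheaper than :func:`compute_ld` when only R itself is needed (e.g. for
    conditional analysis); run :func:`truncate_pinv` later if required.
    """
    sub = panel if snp_ids is None else panel.subset(snp_ids)
    X = sub.dosage - sub.dosage.mean(axis=0, keepdims=True)
    sd = X.std(axis=0)
    if (sd <= 0).any():
        bad = [sub.snp_ids[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance variants in LD computation: {bad[:5]}")
    Xs = X / sd
    R = (Xs.T @ Xs) / X.shape[0]
    np.fill_diagonal(R, 1.0)
    return LDMatrix(sub.snp_ids, (R + R.T) / 2.0, n_samples=sub.n_samples)


def truncate_pinv(ld: LDMatrix, var_frac: float = 0.995, q_max: int | None = None) -> LDMatrix:
    """Set the retained rank ``q`` and the rank-q pseudo-inverse on ``ld``.

    q is the smallest k whose top-k eigenvalues reach ``var_frac`` of the
    total, capped by ``q_max`` and by n_samples - 1 when the panel size is
    known.  R_pinv = sum over the top q of v v^T / lambda.
    """
    ld.ensure_eigen()
    vals = np.clip(ld.eigvals, 0.0, None)
    total = vals.sum()
    if total <= 1e-10 or vals[0] <= 1e-10:
        raise ValueError("LD matrix has no positive eigenvalues")
    frac = np.cumsum(vals) / total
    q = int(np.searchsorted(frac, var_frac - 1e-12) + 1)
    if q_max is not None:
        q = min(q, int(q_max))
    if ld.n_samples is not None:
        q = min(q, ld.n_samples - 1)
    q = max(q, 1)
    # guard: never retain a numerically null eigenvalue
    while q > 1 and vals[q - 1] <= 1e-10:
        q -= 1
    V = ld.eigvecs[:, :q]
    ld.q = q
    ld.R_pinv = (V / vals[:q]) @ V.T
    return ld


def read_blocks(bed_path) -> list[LDBlock]:
    """Read an LD-block partition from a BED file (0-based half-open on disk).

    Returns 1-based inclusive :class:`LDBlock` objects sorted by position;
    overlapping blocks within a chromosome are a hard error.
    """
    blocks: list[LDBlock] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            blocks.append(LDBlock(chrom, start0 + 1, end0, block_id=name))
    blocks.sort(key=lambda b: (_chrom_sort_key(b.chrom), b.start))
    offenders = []
    for a, b in zip(blocks, blocks[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            offenders.append((a.block_id, b.block_id))
    if offenders:
        raise ValueError(f"overlapping LD blocks: {offenders}")
    return blocks


def export_ld(ld: LDMatrix, tsv_path, json_path) -> None:
    """Write R as TSV with a JSON sidecar holding the eigen-metadata."""
    pd.DataFrame(ld.R, index=ld.snp_ids, columns=ld.snp_ids).to_csv(tsv_path, sep="\t")
    meta = {
        "snp_ids": ld.snp_ids,
        "q": ld.q,
        "n_samples": ld.n_samples,
        "eigenvalues": [float(v) for v in ld.eigvals],
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)
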
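"""Cross-trait score correlation from shared controls, via tetrachoric correlation.

Two case-control GWAS that share controls produce correlated z-scores even
at null SNPs.  With both z-vectors dichotomized at zero, the probability
that a bivariate-normal pair shares its sign is 1/2 + asin(rho)/pi, so the
zero-threshold tetrachoric estimate inverts exactly:

    c_hat = sin(pi * (p_same - 1/2))

Polygenic signal would masquerade as overlap, so SNPs associated in either
trait (p < 0.1 by default) are masked out first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pleiofine.sumstats import SumStatTable

logger = logging.getLogger(__name__)


@dataclass
class OverlapMatrix:
    """Trait-by-trait correlation of null z-scores (diagonal exactly 1)."""

    trait_names: list[str]
    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        K = len(self.trait_names)
        if self.C.shape != (K, K):
            raise ValueError("C shape does not match trait names")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(self.C), 1.0):
            raise ValueError("C diagonal must be 1")
        if np.abs(self.C).max() > 1 + 1e-12:
            raise ValueError("C entries must lie in [-1, 1]")

    @classmethod
    def identity(cls, trait_names: list[str]) -> "OverlapMatrix":
        return cls(list(trait_names), np.eye(len(trait_names)))

    def pair(self, t1: str, t2: str) -> float:
        i, j = self.trait_names.index(t1), self.trait_names.index(t2)
        return float(self.C[i, j])

    def submatrix(self, names: list[str]) -> "OverlapMatrix":
        idx = [self.trait_names.index(n) for n in names]
        return OverlapMatrix(list(names), self.C[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.C, index=self.trait_names, columns=self.trait_names).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "OverlapMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def null_snp_mask(table: SumStatTable, p_threshold: float = 0.1) -> set[str]:
    """Marker IDs of putatively null SNPs (association p >= threshold)."""
    keep = table.df["pval"] >= p_threshold
    return set(table.df.loc[keep, "snp_id"])


def tetrachoric_pair(z1: np.ndarray, z2: np.ndarray, min_snps: int = 1000) -> float:
    """Zero-threshold tetrachoric correlation of two aligned z-vectors."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z-vectors must be aligned")
    if len(z1) < min_snps:
        raise ValueError(
            f"only {len(z1)} shared null SNPs; need at least {min_snps}"
        )
    p_same = np.mean(np.sign(z1) == np.sign(z2))
    if p_same in (0.0, 1.0):
        warnings.warn("all signs agree/disagree; tetrachoric estimate saturates at +/-1")
    return float(np.sin(np.pi * (p_same - 0.5)))


def overlap_matrix(
    tables: list[SumStatTable],
    p_threshold: float = 0.1,
    min_snps: int = 1000,
) -> OverlapMatrix:
    """All pairwise tetrachoric overlap estimates.

    Each pair is masked on the union of both traits' associated SNPs
    (either trait's p < ``p_threshold`` removes the SNP for that pair).
    Small estimates are retained numerically; no reporting threshold is
    applied here.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    names = [t.trait_name for t in tables]
    masks = [null_snp_mask(t, p_threshold) for t in tables]
    zs = [t.zscores() for t in tables]
    K = len(tables)
    C = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            shared = masks[i] & masks[j]
            shared &= set(zs[i].index) & set(zs[j].index)
            ids = sorted(shared)
            try:
                c = tetrachoric_pair(
                    zs[i].loc[ids].to_numpy(), zs[j].loc[ids].to_numpy(), min_snps
                )
            except ValueError as err:
                raise ValueError(f"pair ({names[i]}, {names[j]}): {err}") from err
            C[i, j] = C[j, i] = c
    return OverlapMatrix(names, C)
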
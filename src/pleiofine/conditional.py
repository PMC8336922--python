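"""Summary-statistic conditional association analysis against reference LD.

Works entirely in z-space: with standardized genotypes and a single
effective sample size per trait, the conditional z-score of SNP j given a
lead set S is the residual projection

    z_cond_j = (z_j - r_jS' R_SS^-1 z_S) / sqrt(1 - r_jS' R_SS^-1 r_Sj)

which matches individual-level least squares after regressing lead
genotypes out of both phenotype and SNP.  SNPs nearly collinear with the
lead set (projection > ``collinearity_max``) are flagged and reported as
missing rather than unstably inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from pleiofine.ldref import LDMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConditionalResult:
    """Per-SNP conditional statistics for one trait given a lead set."""

    trait_name: str
    lead_set: list[str]
    snp_ids: list[str]
    z_cond: np.ndarray          # NaN where collinear
    pval_cond: np.ndarray
    shrink_factor: np.ndarray   # 1 - r_jS' R_SS^-1 r_Sj
    collinear_flag: np.ndarray
    dropped_leads: list[str] = field(default_factory=list)

    def z_series(self) -> dict[str, float]:
        return dict(zip(self.snp_ids, self.z_cond))


def _prune_leads(ld: LDMatrix, lead_idx: list[int]) -> tuple[list[int], list[int]]:
    """Drop later leads perfectly correlated with an earlier one."""
    kept: list[int] = []
    dropped: list[int] = []
    for i in lead_idx:
        if any(abs(ld.R[i, j]) >= 1.0 - 1e-10 for j in kept):
            dropped.append(i)
        else:
            kept.append(i)
    return kept, dropped


def conditional_z(
    z: np.ndarray,
    ld: LDMatrix,
    lead_set: list[str],
    collinearity_max: float = 0.9,
) -> ConditionalResult:
    """Condition a trait's z-vector on a set of lead SNPs using reference LD.

    Lead SNPs get z_cond = 0 by definition.  A later lead perfectly
    correlated with an earlier one is dropped from the conditioning set
    with a warning.
    """
    z = np.asarray(z, dtype=float)
    index = {s: i for i, s in enumerate(ld.snp_ids)}
    missing = [s for s in lead_set if s not in index]
    if missing:
        raise KeyError(f"lead SNPs not in LD matrix: {missing}")
    lead_idx = [index[s] for s in lead_set]
    kept_idx, dropped_idx = _prune_leads(ld, lead_idx)
    dropped = [ld.snp_ids[i] for i in dropped_idx]
    if dropped:
        logger.warning("dropped perfectly collinear leads: %s", dropped)

    m = ld.m
    z_cond = z.copy()
    shrink = np.ones(m)
    collinear = np.zeros(m, dtype=bool)

    if kept_idx:
        S = np.array(kept_idx)
        R_SS = ld.R[np.ix_(S, S)]
        R_SS_inv = np.linalg.inv(R_SS)
        r_all = ld.R[:, S]                       # (m, |S|)
        proj = r_all @ R_SS_inv                  # (m, |S|)
        h = np.einsum("ij,ij->i", proj, r_all)   # r_jS' R_SS^-1 r_Sj
        num = z - proj @ z[S]
        shrink = 1.0 - h
        collinear = h > collinearity_max
        with np.errstate(invalid="ignore", divide="ignore"):
            z_cond = num / np.sqrt(np.clip(shrink, 0.0, None))
        z_cond[collinear] = np.nan
        z_cond[S] = 0.0
        shrink = np.clip(shrink, 0.0, None)
        shrink[S] = 0.0
        collinear[S] = False
    for i in lead_idx:
        z_cond[i] = 0.0

    with np.errstate(invalid="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(z_cond))
    pval = np.where(np.isnan(z_cond), np.nan, np.clip(pval, np.nextafter(0, 1), 1.0))
    return ConditionalResult(
        trait_name="",
        lead_set=[ld.snp_ids[i] for i in kept_idx],
        snp_ids=list(ld.snp_ids),
        z_cond=z_cond,
        pval_cond=pval,
        shrink_factor=shrink,
        collinear_flag=collinear,
        dropped_leads=dropped,
    )


def stepwise_select(
    z: np.ndarray,
    ld: LDMatrix,
    p_enter: float = 5e-8,
    collinearity_max: float = 0.9,
    pos: np.ndarray | None = None,
    max_leads: int = 50,
) -> list[str]:
    """Greedy forward selection of conditionally independent lead SNPs.

    Repeatedly adds the SNP with the smallest conditional p-value while
    that p-value is below ``p_enter``.  Ties on p are broken by larger |z|,
    then by lower chromosome position (``pos``, defaulting to input order).
    """
    z = np.asarray(z, dtype=float)
    if pos is None:
        pos = np.arange(ld.m)
    leads: list[str] = []
    for _ in range(max_leads):
        res = conditional_z(z, ld, leads, collinearity_max=collinearity_max)
        zc = np.where(np.isnan(res.z_cond), 0.0, res.z_cond)
        in_leads = np.isin(ld.snp_ids, leads)
        zc = np.where(in_leads, 0.0, zc)
        pv = np.where(np.isnan(res.pval_cond), 1.0, res.pval_cond)
        pv = np.where(in_leads, 1.0, pv)
        order = np.lexsort((pos, -np.abs(zc), pv))
        best = order[0]
        if pv[best] >= p_enter:
            break
        leads.append(ld.snp_ids[best])
    else:
        logger.warning("stepwise selection hit max_leads=%d", max_leads)
    return leads
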
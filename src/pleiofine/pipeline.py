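"""Iterative conditional + subset-meta-analysis loop for one genomic region.

Each iteration (1) conditions every trait's regional summary statistics on
the lead SNPs accumulated so far (a trait skips leads absent from its own
data), (2) runs the two-sided subset-based meta-analysis over all SNPs
observed in at least two traits, and (3) harvests the SNP with the smallest
adjusted p-value if it clears genome-wide significance; otherwise the loop
stops and records the best non-significant candidate.  The harvested leads
are the region's conditionally independent cross-trait signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleiofine.conditional import conditional_z
from pleiofine.ldref import GenotypePanel, LDBlock, LDMatrix, panel_correlation
from pleiofine.overlap import OverlapMatrix
from pleiofine.subsetmeta import Calibration, calibrate_null, subset_meta_scan
from pleiofine.sumstats import SumStatTable

logger = logging.getLogger(__name__)


@dataclass
class LeadSignal:
    """One harvested independent cross-trait signal (iteration 0 = initiation)."""

    iteration: int
    snp_id: str
    pval_adj: float
    T: float
    pos_subset: tuple[str, ...]
    neg_subset: tuple[str, ...]
    marginal_p: dict[str, float | None]
    conditional_z: dict[str, float | None]


@dataclass
class StopRecord:
    """Best remaining SNP when the loop fell below genome-wide significance."""

    iteration: int
    snp_id: str | None
    pval_adj: float | None


@dataclass
class PipelineState:
    tables: dict[str, SumStatTable]
    lds: dict[str, LDMatrix]
    z_marg: dict[str, pd.Series]
    overlap: OverlapMatrix
    stop_p: float = 5e-8
    max_iter: int = 25
    collinearity_max: float = 0.9
    calib_draws: int = 100_000
    seed: int = 0
    leads: list[LeadSignal] = field(default_factory=list)
    stop: StopRecord | None = None
    _calibrations: dict[tuple, Calibration] = field(default_factory=dict)

    @property
    def lead_ids(self) -> list[str]:
        return [s.snp_id for s in self.leads]


def build_state(
    tables: list[SumStatTable],
    panel: GenotypePanel,
    region: LDBlock,
    overlap: OverlapMatrix | None = None,
    stop_p: float = 5e-8,
    max_iter: int = 25,
    calib_draws: int = 100_000,
    seed: int = 0,
) -> PipelineState:
    """Restrict harmonized tables to the region/panel and precompute LD."""
    if overlap is None:
        overlap = OverlapMatrix.identity([t.trait_name for t in tables])
    panel_ids = set(panel.snp_ids)
    kept: dict[str, SumStatTable] = {}
    lds: dict[str, LDMatrix] = {}
    z_marg: dict[str, pd.Series] = {}
    for t in tables:
        df = t.df
        in_region = [
            (sid in panel_ids) and region.contains(c, int(p))
            for sid, c, p in zip(df["snp_id"], df["chrom"], df["pos"])
        ]
        sub = SumStatTable(
            t.trait_name, t.n_cases, t.n_controls,
            df[np.asarray(in_region, dtype=bool)].reset_index(drop=True),
        )
        if len(sub) == 0:
            logger.warning("trait %s has no SNPs in region; excluded", t.trait_name)
            continue
        kept[t.trait_name] = sub
        z_marg[t.trait_name] = sub.zscores()
    # conditioning needs R only; share one matrix across traits with the
    # same SNP universe instead of eigendecomposing per trait
    ld_cache: dict[tuple[str, ...], LDMatrix] = {}
    for name, sub in kept.items():
        key = tuple(sub.df["snp_id"])
        if key not in ld_cache:
            ld_cache[key] = panel_correlation(panel, list(key))
        lds[name] = ld_cache[key]
    counts: dict[str, int] = {}
    for t in kept.values():
        for s in t.df["snp_id"]:
            counts[s] = counts.get(s, 0) + 1
    if not any(v >= 2 for v in counts.values()):
        raise ValueError("no SNPs shared by at least two traits in the region")
    return PipelineState(
        tables=kept,
        lds=lds,
        z_marg=z_marg,
        overlap=overlap.submatrix(list(kept)),
        stop_p=stop_p,
        max_iter=max_iter,
        calib_draws=calib_draws,
        seed=seed,
    )


def _conditional_scores(state: PipelineState) -> dict[str, dict[str, float]]:
    """Per-trait conditional z for every SNP, NaN-free (missing = absent key)."""
    scores: dict[str, dict[str, float]] = {}
    leads = state.lead_ids
    for name, table in state.tables.items():
        ld = state.lds[name]
        have = set(ld.snp_ids)
        leads_t = [l for l in leads if l in have]
        z = state.z_marg[name].loc[list(ld.snp_ids)].to_numpy()
        res = conditional_z(z, ld, leads_t, collinearity_max=state.collinearity_max)
        scores[name] = {
            s: float(v) for s, v in zip(res.snp_ids, res.z_cond) if np.isfinite(v)
        }
    return scores


def run_iteration(state: PipelineState) -> LeadSignal | StopRecord:
    """One condition-then-meta-analyze pass; mutates ``state``.

    Returns the harvested :class:`LeadSignal`, or a :class:`StopRecord`
    when no SNP reaches ``state.stop_p``.
    """
    trait_names = list(state.tables)
    scores = _conditional_scores(state)
    already = set(state.lead_ids)

    # group candidate SNPs by trait-availability pattern
    by_pattern: dict[tuple[int, ...], list[str]] = {}
    all_snps: set[str] = set()
    for s in scores.values():
        all_snps.update(s)
    for snp in sorted(all_snps):
        if snp in already:
            continue
        pattern = tuple(
            k for k, name in enumerate(trait_names) if snp in scores[name]
        )
        if len(pattern) < 2:
            continue
        by_pattern.setdefault(pattern, []).append(snp)
    if not by_pattern:
        raise ValueError("no SNPs shared by at least two traits")

    best: dict | None = None
    for pattern, snps in sorted(by_pattern.items()):
        names = [trait_names[k] for k in pattern]
        w = np.array([np.sqrt(state.tables[n].n_eff) for n in names])
        C = state.overlap.submatrix(names)
        key = pattern
        if key not in state._calibrations:
            state._calibrations[key] = calibrate_null(
                K=len(names),
                C=C,
                w=w,
                n_draws=state.calib_draws,
                seed=state.seed + len(state._calibrations),
            )
        calib = state._calibrations[key]
        Z = np.array([[scores[n][s] for n in names] for s in snps])
        results = subset_meta_scan(snps, Z, names, w, C, calib)
        for r in results:
            cand = {"res": r}
            if (
                best is None
                or r.pval_adj < best["res"].pval_adj
                or (r.pval_adj == best["res"].pval_adj and r.T > best["res"].T)
            ):
                best = cand

    r = best["res"]
    iteration = len(state.leads)
    if r.pval_adj < state.stop_p:
        signal = LeadSignal(
            iteration=iteration,
            snp_id=r.snp_id,
            pval_adj=r.pval_adj,
            T=r.T,
            pos_subset=r.best_pos_subset,
            neg_subset=r.best_neg_subset,
            marginal_p={
                name: _marginal_p(state.tables[name], r.snp_id)
                for name in trait_names
            },
            conditional_z={
                name: scores[name].get(r.snp_id) for name in trait_names
            },
        )
        state.leads.append(signal)
        logger.info(
            "iteration %d: harvested %s (p_adj = %.3g)", iteration, r.snp_id, r.pval_adj
        )
        return signal
    stop = StopRecord(iteration=iteration, snp_id=r.snp_id, pval_adj=r.pval_adj)
    state.stop = stop
    logger.info(
        "iteration %d: best remaining p_adj = %.3g >= %.3g, stopping",
        iteration, r.pval_adj, state.stop_p,
    )
    return stop


def _marginal_p(table: SumStatTable, snp_id: str) -> float | None:
    hit = table.df.loc[table.df["snp_id"] == snp_id, "pval"]
    return float(hit.iloc[0]) if len(hit) else None


def run_pipeline(
    tables: list[SumStatTable],
    panel: GenotypePanel,
    region: LDBlock,
    overlap: OverlapMatrix | None = None,
    stop_p: float = 5e-8,
    max_iter: int = 25,
    calib_draws: int = 100_000,
    seed: int = 0,
) -> tuple[list[LeadSignal], StopRecord, PipelineState]:
    """Run the full iterative loop until no genome-wide-significant SNP remains."""
    state = build_state(
        tables, panel, region, overlap,
        stop_p=stop_p, max_iter=max_iter, calib_draws=calib_draws, seed=seed,
    )
    if stop_p <= 0:
        state.stop = StopRecord(iteration=0, snp_id=None, pval_adj=None)
        return [], state.stop, state
    for _ in range(max_iter):
        out = run_iteration(state)
        if isinstance(out, StopRecord):
            return state.leads, out, state
    raise RuntimeError(f"pipeline did not converge within max_iter={max_iter} iterations")


def traits_for_finemap(
    signal: LeadSignal,
    raw_tables: list[SumStatTable],
    gw_p: float = 5e-8,
) -> list[str]:
    """Traits to fine-map for one signal.

    Union of the meta-analysis positive/negative subsets with any trait whose
    unadjusted marginal p at the lead SNP is genome-wide significant (the
    manual-addition rule); sorted by trait name.
    """
    traits = set(signal.pos_subset) | set(signal.neg_subset)
    for t in raw_tables:
        p = _marginal_p(t, signal.snp_id)
        if p is not None and p < gw_p:
            traits.add(t.trait_name)
    return sorted(traits)


def leads_to_frame(
    leads: list[LeadSignal], stop: StopRecord | None, trait_names: list[str]
) -> pd.DataFrame:
    """Lead-signal table: iteration, SNP, adjusted p, subsets, per-trait marginal p."""
    rows = []
    for s in leads:
        row = {
            "iteration": "Initiation" if s.iteration == 0 else s.iteration,
            "snp_id": s.snp_id,
            "pval_adj": s.pval_adj,
            "set1": ",".join(s.pos_subset),
            "set2": ",".join(s.neg_subset),
        }
        for name in trait_names:
            p = s.marginal_p.get(name)
            row[f"p_{name}"] = "NA" if p is None else p
        rows.append(row)
    if stop is not None and stop.snp_id is not None:
        rows.append(
            {
                "iteration": stop.iteration,
                "snp_id": stop.snp_id,
                "pval_adj": stop.pval_adj,
                "set1": "not reached genome-wide significance, iteration stopped",
                "set2": "",
            }
        )
    return pd.DataFrame(rows)
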
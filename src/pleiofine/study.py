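"""End-to-end study drivers and repeatable simulation experiments.

This module wires the analysis stages together the way the regional
cross-trait workflow runs them in practice:

    harmonize -> overlap -> local correlation scan -> iterative
    conditional/subset-meta loop -> per-signal multi-trait fine-mapping
    (uniform and annotation priors) -> pairwise colocalization

and packages the Monte-Carlo experiments (parameter recovery, calibration,
credible-set coverage) used to validate the estimators under the synthetic
generative model.  Everything is deterministic given the seeds.
"""

from __future__ import annotations

import tempfile
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pleiofine import finemap as fm
from pleiofine import localrg
from pleiofine import overlap as ov
from pleiofine import pipeline as pl
from pleiofine import simulate as sim
from pleiofine.conditional import conditional_z
from pleiofine.ldref import compute_ld
from pleiofine.sumstats import SumStatTable, harmonize, qc_filter


@dataclass
class FlagshipResult:
    """Everything the flagship synthetic run produces."""

    config: sim.SimConfig
    truth: dict
    overlap_est: ov.OverlapMatrix
    localrg_results: list
    localrg_threshold: float
    leads: list[pl.LeadSignal]
    stop: pl.StopRecord
    state: pl.PipelineState
    credible_sets: dict[str, fm.CredibleSet]
    credible_sets_annotated: dict[str, fm.CredibleSet]
    annotation_model: fm.AnnotationModel
    coloc: dict[str, dict[str, float]]
    matched_causals: dict[str, str] = field(default_factory=dict)


def _match_leads_to_causals(panel, leads, truth, r2_min=0.8):
    """Greedy match of harvested leads to planted causals by panel r^2."""
    X = panel.dosage
    index = {s: i for i, s in enumerate(panel.snp_ids)}
    remaining = list(truth["causal_snp_ids"])
    matched = {}
    for lead in leads:
        li = index[lead.snp_id]
        best, best_r2 = None, 0.0
        for c in remaining:
            r = np.corrcoef(X[:, li], X[:, index[c]])[0, 1]
            if r**2 > best_r2:
                best, best_r2 = c, r**2
        if best is not None and best_r2 > r2_min:
            matched[lead.snp_id] = best
            remaining.remove(best)
    return matched


def finemap_signal(
    state: pl.PipelineState,
    leads: list[pl.LeadSignal],
    idx: int,
    raw_tables: list[SumStatTable],
    prior_by_snp: dict[str, float] | None = None,
    gw_p: float = 5e-8,
    w_prior: float = 0.04,
) -> fm.CredibleSet:
    """Fine-map one harvested signal with single-causal multi-trait ABFs.

    Traits follow the contributing-subsets-plus-marginal-significance rule;
    per-trait z-scores are conditioned on the *other* lead SNPs; only SNPs
    with data (and a defined conditional z) in all included traits enter.
    """
    sig = leads[idx]
    traits = pl.traits_for_finemap(sig, raw_tables)
    traits = [t for t in traits if t in state.tables]
    if not traits:
        raise ValueError(f"no traits available to fine-map signal {sig.snp_id}")
    other = [l.snp_id for i, l in enumerate(leads) if i != idx]

    per_trait: dict[str, dict[str, float]] = {}
    for name in traits:
        ld = state.lds[name]
        have = set(ld.snp_ids)
        z = state.z_marg[name].loc[list(ld.snp_ids)].to_numpy()
        res = conditional_z(
            z, ld, [l for l in other if l in have],
            collinearity_max=state.collinearity_max,
        )
        per_trait[name] = {
            s: float(v) for s, v in zip(res.snp_ids, res.z_cond) if np.isfinite(v)
        }

    common = set(per_trait[traits[0]])
    for name in traits[1:]:
        common &= set(per_trait[name])
    first_ld = state.lds[traits[0]]
    snp_ids = [s for s in first_ld.snp_ids if s in common]
    if not snp_ids:
        raise ValueError(f"empty SNP intersection for signal {sig.snp_id}")

    z_by_trait = {
        name: np.array([per_trait[name][s] for s in snp_ids]) for name in traits
    }
    n_eff = {name: state.tables[name].n_eff for name in traits}
    prior = None
    if prior_by_snp is not None:
        prior = np.array([prior_by_snp[s] for s in snp_ids])
        prior = prior / prior.sum()
    return fm.multitrait_pp(
        sig.snp_id, snp_ids, z_by_trait, n_eff, prior=prior, w_prior=w_prior
    )


def estimate_overlap_genomewide(
    cfg: sim.SimConfig, seed: int, n_chunks: int = 10, chunk_m: int = 1500,
    chunk_panel: int = 1500,
) -> ov.OverlapMatrix:
    """Estimate the study's overlap matrix from simulated genome-wide nulls.

    Overlap estimation needs many independent null SNPs, which one dense
    region cannot supply; this emulates the genome-wide null set under the
    same trait/overlap configuration.
    """
    base = sim.SimConfig(
        seed=seed, m_snps=chunk_m, n_panel=chunk_panel, ld_rho=0.0,
        traits=cfg.traits, shared_controls=cfg.shared_controls, rho_p=cfg.rho_p,
    )
    tables = sim.simulate_overlap_study(base, n_chunks=n_chunks)
    zs = [t.zscores().to_numpy() for t in tables]
    names = [t.trait_name for t in tables]
    K = len(names)
    C = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            C[i, j] = C[j, i] = ov.tetrachoric_pair(zs[i], zs[j])
    return ov.OverlapMatrix(names, C)


def finemap_all(
    state: pl.PipelineState,
    leads: list[pl.LeadSignal],
    tables: list[SumStatTable],
    panel,
    cfg: sim.SimConfig,
) -> tuple[dict, dict, fm.AnnotationModel | None]:
    """Fine-map every harvested signal, without and with annotation priors.

    The annotation model is fitted by EM across all signals on the shared
    SNP frame, from peaks generated by the study's annotation plan.
    """
    credible_sets = {}
    for i in range(len(leads)):
        credible_sets[leads[i].snp_id] = finemap_signal(state, leads, i, tables)
    if not leads:
        return {}, {}, None

    ann = sim.simulate_annotations(panel, cfg)
    with tempfile.TemporaryDirectory() as td:
        bed_paths = {}
        for name, ivs in ann.items():
            p = pathlib.Path(td) / f"{name}.bed"
            sim.write_bed(ivs, p)
            bed_paths[name] = p
        snp_frame = pd.DataFrame(
            {"snp_id": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos}
        )
        tracks = fm.annotate_snps(snp_frame, bed_paths)
    ind_by_snp = {
        s: np.array([t.indicator[i] for t in tracks])
        for i, s in enumerate(panel.snp_ids)
    }

    # per-signal summed log Bayes factors for the enrichment fit; signals
    # sharing one SNP frame are fitted jointly, else the first frame is used
    signal_logbfs, frames = [], []
    for snp_id, cs in credible_sets.items():
        lb = np.zeros(len(cs.snp_ids))
        idx = [l.snp_id for l in leads].index(snp_id)
        for name in cs.traits:
            z = _conditional_vector(state, leads, idx, name, cs.snp_ids)
            lb += fm.log_abf(z, state.tables[name].n_eff)
        signal_logbfs.append(lb)
        frames.append(cs.snp_ids)
    shared_frame = all(f == frames[0] for f in frames)
    A_tracks = [
        fm.AnnotationTrack(
            t.name, t.intervals,
            np.array([ind_by_snp[s][k] for s in frames[0]], dtype=np.int8),
        )
        for k, t in enumerate(tracks)
    ]
    model = fm.fit_annotation_prior(
        signal_logbfs if shared_frame else [signal_logbfs[0]], A_tracks
    )

    credible_sets_annotated = {}
    for i, lead in enumerate(leads):
        cs0 = credible_sets[lead.snp_id]
        A = np.array(
            [[ind_by_snp[s][k] for k in range(len(tracks))] for s in cs0.snp_ids]
        )
        prior = model.prior(A.astype(float))
        credible_sets_annotated[lead.snp_id] = finemap_signal(
            state, leads, i, tables,
            prior_by_snp=dict(zip(cs0.snp_ids, prior)),
        )
    return credible_sets, credible_sets_annotated, model


def colocalize_shared_signal(
    state: pl.PipelineState,
    leads: list[pl.LeadSignal],
    credible_sets: dict,
    panel,
    cfg: sim.SimConfig,
    truth: dict,
) -> dict[str, dict[str, float]]:
    """Colocalization for the trait pair sharing a planted causal variant,
    each trait conditioned on the region's other lead SNPs."""
    coloc = {}
    pair = _shared_pair(cfg, truth)
    if pair is not None and all(p in state.tables for p in pair):
        shared_idx = _signal_index_for_pair(cfg, leads, panel, truth, pair)
        if shared_idx is not None:
            ids = credible_sets[leads[shared_idx].snp_id].snp_ids
            z1 = _conditional_vector(state, leads, shared_idx, pair[0], ids)
            z2 = _conditional_vector(state, leads, shared_idx, pair[1], ids)
            coloc[f"{pair[0]}|{pair[1]}"] = fm.colocalize_pair(
                z1, z2,
                state.tables[pair[0]].n_eff, state.tables[pair[1]].n_eff,
            )
    return coloc


def run_flagship(seed: int = 0, calib_draws: int = 100_000) -> FlagshipResult:
    """The full synthetic study at the default (flagship) conditions."""
    cfg = sim.flagship_config(seed)
    panel = sim.simulate_panel(cfg)
    tables_raw, truth = sim.simulate_sumstats(panel, cfg)

    tables = harmonize([qc_filter(t) for t in tables_raw])

    overlap_est = estimate_overlap_genomewide(cfg, seed=cfg.seed + 7_001)

    region = sim.blocks_of(cfg)[0]
    lr_results, lr_threshold = localrg.scan_blocks(
        tables, panel, [region], overlap_est
    )

    leads, stop, state = pl.run_pipeline(
        tables, panel, region, overlap_est,
        calib_draws=calib_draws, seed=cfg.seed + 11,
    )

    credible_sets, credible_sets_annotated, model = finemap_all(
        state, leads, tables, panel, cfg
    )
    coloc = (
        colocalize_shared_signal(state, leads, credible_sets, panel, cfg, truth)
        if len(leads) >= 2
        else {}
    )

    result = FlagshipResult(
        config=cfg,
        truth=truth,
        overlap_est=overlap_est,
        localrg_results=lr_results,
        localrg_threshold=lr_threshold,
        leads=leads,
        stop=stop,
        state=state,
        credible_sets=credible_sets,
        credible_sets_annotated=credible_sets_annotated,
        annotation_model=model,
        coloc=coloc,
        matched_causals=_match_leads_to_causals(panel, leads, truth),
    )
    return result


def _conditional_vector(state, leads, idx, trait, snp_ids):
    ld = state.lds[trait]
    have = set(ld.snp_ids)
    other = [l.snp_id for i, l in enumerate(leads) if i != idx and l.snp_id in have]
    z = state.z_marg[trait].loc[list(ld.snp_ids)].to_numpy()
    res = conditional_z(z, ld, other, collinearity_max=state.collinearity_max)
    lookup = dict(zip(res.snp_ids, res.z_cond))
    return np.array([lookup[s] for s in snp_ids])


def _shared_pair(cfg, truth):
    for spec in cfg.causals:
        names = sorted(spec.effects)
        if len(names) >= 2:
            counts = {}
            for other in cfg.causals:
                for n in other.effects:
                    counts[n] = counts.get(n, 0) + 1
            # prefer a pair for which this is the only shared signal
            pair = tuple(sorted(spec.effects, key=lambda n: counts[n])[:2])
            return pair
    return None


def _signal_index_for_pair(cfg, leads, panel, truth, pair):
    index = {s: i for i, s in enumerate(panel.snp_ids)}
    X = panel.dosage
    for spec in cfg.causals:
        if set(pair) <= set(spec.effects):
            causal_id = panel.snp_ids[spec.index]
            for i, lead in enumerate(leads):
                r = np.corrcoef(X[:, index[lead.snp_id]], X[:, index[causal_id]])[0, 1]
                if r**2 > 0.8:
                    return i
    return None


# ---------------------------------------------------------------------------
# repeatable Monte-Carlo experiments


def signal_recovery_experiment(
    n_signals: int = 2,
    reps: int = 100,
    seed: int = 0,
    m: int = 300,
    n_panel: int = 2000,
    calib_draws: int = 20_000,
) -> dict:
    """Fraction of replicates in which the loop recovers exactly the planted
    independent cross-trait signals (as themselves or r^2 > 0.8 proxies)."""
    traits = [
        sim.TraitSpec("a", 20_000, 20_000),
        sim.TraitSpec("b", 30_000, 30_000),
        sim.TraitSpec("c", 15_000, 15_000),
    ]
    t = {x.name: x for x in traits}
    plans = {
        2: [
            sim.CausalSpec(60, {"a": 10 / np.sqrt(t["a"].n_eff), "b": 9.5 / np.sqrt(t["b"].n_eff)}),
            sim.CausalSpec(230, {"b": 9 / np.sqrt(t["b"].n_eff), "c": 9.5 / np.sqrt(t["c"].n_eff)}),
        ],
        3: [
            sim.CausalSpec(50, {"a": 10 / np.sqrt(t["a"].n_eff), "b": 9.5 / np.sqrt(t["b"].n_eff)}),
            sim.CausalSpec(150, {"a": 9 / np.sqrt(t["a"].n_eff), "c": -9.5 / np.sqrt(t["c"].n_eff)}),
            sim.CausalSpec(250, {"b": 9.5 / np.sqrt(t["b"].n_eff), "c": 9 / np.sqrt(t["c"].n_eff)}),
        ],
    }
    causals = plans[n_signals]
    cfg0 = sim.SimConfig(
        seed=seed, m_snps=m, n_panel=n_panel, ld_rho=0.8, traits=traits, causals=causals
    )
    panel = sim.simulate_panel(cfg0)
    region = sim.blocks_of(cfg0)[0]
    X = panel.dosage
    causal_ids = [panel.snp_ids[c.index] for c in causals]
    index = {s: i for i, s in enumerate(panel.snp_ids)}

    exact = 0
    opposite_ok = 0
    for rep in range(reps):
        cfg = sim.SimConfig(
            seed=seed + 1 + rep, m_snps=m, n_panel=n_panel, ld_rho=0.8,
            traits=traits, causals=causals,
        )
        tables, _ = sim.simulate_sumstats(panel, cfg)
        leads, stop, _ = pl.run_pipeline(
            tables, panel, region, calib_draws=calib_draws, seed=seed + 50_000 + rep
        )
        if len(leads) != n_signals:
            continue
        remaining = list(causal_ids)
        ok = True
        for lead in leads:
            li = index[lead.snp_id]
            r2 = [np.corrcoef(X[:, li], X[:, index[c]])[0, 1] ** 2 for c in remaining]
            if not r2 or max(r2) <= 0.8:
                ok = False
                break
            remaining.pop(int(np.argmax(r2)))
        if ok:
            exact += 1
            if n_signals == 3:
                # the opposite-direction trait ("c" on the second planted
                # signal) must sit opposite "a" in its harvested subsets
                for lead in leads:
                    li = index[lead.snp_id]
                    r = np.corrcoef(X[:, li], X[:, causals[1].index])[0, 1]
                    if r**2 > 0.8:
                        pos, neg = set(lead.pos_subset), set(lead.neg_subset)
                        if ("a" in pos and "c" in neg) or ("a" in neg and "c" in pos):
                            opposite_ok += 1
                        break
    out = {"rate": exact / reps, "reps": reps}
    if n_signals == 3:
        out["opposite_direction_rate"] = opposite_ok / max(exact, 1)
    return out


def h2_recovery_experiment(
    reps: int = 500, seed: int = 0, m: int = 100, n_panel: int = 2000,
    n: float = 50_000, h2_true: float = 0.001,
) -> dict:
    """Mean local-heritability estimate over replicates of a planted block."""
    cfg = sim.SimConfig(
        seed=seed, m_snps=m, n_panel=n_panel, ld_rho=0.7,
        traits=[sim.TraitSpec("t", 1000, 1000)],
    )
    panel = sim.simulate_panel(cfg)
    ld = compute_ld(panel)
    X = panel.dosage - panel.dosage.mean(axis=0, keepdims=True)
    Xs = X / X.std(axis=0)
    V = (Xs.T @ Xs) / panel.n_samples
    vals, vecs = np.linalg.eigh(V)
    Lv = vecs * np.sqrt(np.clip(vals, 0, None))[None, :]
    rng = np.random.default_rng(seed + 1)
    beta = np.zeros(m)
    beta[rng.choice(m, 3, replace=False)] = 1.0
    beta *= np.sqrt(h2_true / (beta @ V @ beta))
    mean_z = np.sqrt(n) * (V @ beta)
    ests = np.array(
        [
            localrg.local_h2(mean_z + Lv @ rng.standard_normal(m), n, ld)[0]
            for _ in range(reps)
        ]
    )
    return {
        "mean": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(reps)),
        "true": h2_true,
    }


def rho_recovery_experiment(
    reps: int = 500, seed: int = 0, m: int = 100, n_panel: int = 2000,
    n: float = 50_000, rho_true: float = 0.0005,
) -> dict:
    """Mean local genetic-covariance estimate for traits sharing all effects."""
    cfg = sim.SimConfig(
        seed=seed, m_snps=m, n_panel=n_panel, ld_rho=0.7,
        traits=[sim.TraitSpec("t", 1000, 1000)],
    )
    panel = sim.simulate_panel(cfg)
    ld = compute_ld(panel)
    X = panel.dosage - panel.dosage.mean(axis=0, keepdims=True)
    Xs = X / X.std(axis=0)
    V = (Xs.T @ Xs) / panel.n_samples
    vals, vecs = np.linalg.eigh(V)
    Lv = vecs * np.sqrt(np.clip(vals, 0, None))[None, :]
    rng = np.random.default_rng(seed + 1)
    beta = np.zeros(m)
    beta[rng.choice(m, 3, replace=False)] = 1.0
    beta *= np.sqrt(rho_true / (beta @ V @ beta))
    mean_z = np.sqrt(n) * (V @ beta)
    ests = np.empty(reps)
    for r in range(reps):
        z1 = mean_z + Lv @ rng.standard_normal(m)
        z2 = mean_z + Lv @ rng.standard_normal(m)
        ests[r] = localrg.local_rcov(z1, z2, n, n, ld)[0]
    return {
        "mean": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(reps)),
        "true": rho_true,
    }


def localrg_type1_experiment(
    reps: int = 1000, seed: int = 0, m: int = 100, n_panel: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the local-covariance test on independent null traits."""
    cfg = sim.SimConfig(
        seed=seed, m_snps=m, n_panel=n_panel, ld_rho=0.7,
        traits=[sim.TraitSpec("t", 1000, 1000)],
    )
    panel = sim.simulate_panel(cfg)
    ld = compute_ld(panel)
    X = panel.dosage - panel.dosage.mean(axis=0, keepdims=True)
    Xs = X / X.std(axis=0)
    V = (Xs.T @ Xs) / panel.n_samples
    vals, vecs = np.linalg.eigh(V)
    Lv = vecs * np.sqrt(np.clip(vals, 0, None))[None, :]
    rng = np.random.default_rng(seed + 1)
    n1, n2 = 40_000, 60_000
    rej = 0
    for _ in range(reps):
        z1 = Lv @ rng.standard_normal(m)
        z2 = Lv @ rng.standard_normal(m)
        rho, var = localrg.local_rcov(z1, z2, n1, n2, ld)
        rej += 2 * stats.norm.sf(abs(rho) / np.sqrt(var)) < alpha
    return {"rate": rej / reps, "reps": reps, "alpha": alpha}


def coverage_experiment(
    reps: int = 500, seed: int = 0, m: int = 100, n_panel: int = 2000
) -> dict:
    """Empirical coverage of nominal-95% credible sets for planted causals."""
    cfg = sim.SimConfig(
        seed=seed, m_snps=m, n_panel=n_panel, ld_rho=0.7,
        traits=[sim.TraitSpec("t", 1000, 1000)],
    )
    panel = sim.simulate_panel(cfg)
    X = panel.dosage - panel.dosage.mean(axis=0, keepdims=True)
    Xs = X / X.std(axis=0)
    V = (Xs.T @ Xs) / panel.n_samples
    vals, vecs = np.linalg.eigh(V)
    Lv = vecs * np.sqrt(np.clip(vals, 0, None))[None, :]
    rng = np.random.default_rng(seed + 1)
    ids = panel.snp_ids
    n_eff = {"a": 40_000, "b": 60_000}
    covered = 0
    for _ in range(reps):
        j = int(rng.integers(m))
        zt = {}
        for t, n in n_eff.items():
            target = rng.uniform(5, 9)
            beta = np.zeros(m)
            beta[j] = target / np.sqrt(n)
            zt[t] = np.sqrt(n) * (V @ beta) + Lv @ rng.standard_normal(m)
        cs = fm.multitrait_pp("sig", ids, zt, n_eff)
        covered += ids[j] in cs.set95
    return {"coverage": covered / reps, "reps": reps}


def tetrachoric_recovery_experiment(seed: int = 0, c_true: float = 0.08) -> dict:
    """Recovery of a planted shared-control score correlation."""
    traits = [sim.TraitSpec("a", 20_000, 30_000), sim.TraitSpec("b", 15_000, 25_000)]
    n_s = int(round(c_true * np.sqrt(traits[0].n_eff * traits[1].n_eff)))
    base = sim.SimConfig(
        seed=seed, m_snps=1500, n_panel=1500, ld_rho=0.0,
        traits=traits, shared_controls={("a", "b"): n_s},
    )
    tables = sim.simulate_overlap_study(base, n_chunks=20)
    z1 = tables[0].zscores().to_numpy()
    z2 = tables[1].zscores().to_numpy()
    planted = n_s / np.sqrt(traits[0].n_eff * traits[1].n_eff)
    return {
        "estimate": ov.tetrachoric_pair(z1, z2),
        "planted": float(planted),
    }
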
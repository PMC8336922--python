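"""Generate the flagship synthetic study: panel, summary statistics, tracks.

Writes to scratch/flagship/: the reference-panel VCF, one GCTA-.ma-style
summary-statistics table per trait (with a JSON sidecar naming the trait and
its sample sizes), the LD-block BED, the annotation-peak BED, and the
ground-truth manifest (causal variants, per-trait effects, planted overlap).
"""

import json

import common
from pleiofine import simulate as sim
from pleiofine.sumstats import write_sumstats


def main():
    common.ensure_dirs()
    cfg = common.config()
    panel = sim.simulate_panel(cfg)
    tables, truth = sim.simulate_sumstats(panel, cfg)

    sim.write_vcf(panel, common.SCRATCH / "panel.vcf")
    sim.write_blocks_bed(sim.blocks_of(cfg), common.SCRATCH / "blocks.bed")
    for name, ivs in sim.simulate_annotations(panel, cfg).items():
        sim.write_bed(ivs, common.SCRATCH / f"{name}.bed")
    for t in tables:
        write_sumstats(t, common.SCRATCH / f"{t.trait_name}.tsv")
        (common.SCRATCH / f"{t.trait_name}.json").write_text(
            json.dumps(
                {
                    "trait_name": t.trait_name,
                    "n_cases": t.n_cases,
                    "n_controls": t.n_controls,
                }
            )
        )
    sim.write_truth(truth, common.SCRATCH / "truth.json")

    print(f"panel: {panel.n_samples} samples x {panel.n_variants} variants")
    print(f"traits: {[t.trait_name for t in tables]}")
    print(f"planted causal variants: {truth['causal_snp_ids']}")
    print(f"wrote study inputs to {common.SCRATCH}")


if __name__ == "__main__":
    main()
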
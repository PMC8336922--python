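"""Quality-filter and harmonize the per-trait summary statistics.

Reads the raw tables written by 01_simulate.py, applies the standard QC
(imputation quality >= 0.3, MAF >= 1%, |log OR| <= 3), places all traits on
the shared strand-stable allele frame, and writes the harmonized tables
plus a per-trait drop tally.
"""

import json

import common
from pleiofine.sumstats import harmonize, qc_filter, read_sumstats, write_sumstats

MA_PLUS = {
    "snp_id": "SNP", "chrom": "chrom", "pos": "pos",
    "effect_allele": "A1", "other_allele": "A2",
    "eaf": "freq", "beta": "b", "se": "se", "pval": "p", "info": "info",
}


def main():
    common.ensure_dirs()
    tables = []
    for sidecar in sorted(common.SCRATCH.glob("*.json")):
        if sidecar.stem == "truth":
            continue
        meta = json.loads(sidecar.read_text())
        tables.append(
            read_sumstats(
                sidecar.with_suffix(".tsv"), dialect=MA_PLUS,
                trait_name=meta["trait_name"],
                n_cases=meta["n_cases"], n_controls=meta["n_controls"],
            )
        )
    tables = [qc_filter(t) for t in tables]
    tables = harmonize(tables)

    out = common.SCRATCH / "harmonized"
    out.mkdir(exist_ok=True)
    tally = {}
    for t in tables:
        write_sumstats(t, out / f"{t.trait_name}.tsv")
        tally[t.trait_name] = {"records": len(t), **t.log}
        print(f"{t.trait_name}: {len(t)} records after QC + harmonization")
    (common.RESULTS / "harmonization_tally.json").write_text(json.dumps(tally, indent=1))
    print(f"wrote harmonized tables to {out}")


if __name__ == "__main__":
    main()
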
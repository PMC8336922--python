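"""Estimate cross-trait score correlation induced by shared controls.

The tetrachoric estimator needs many independent null SNPs, so the estimate
comes from a genome-wide null emulation under the same trait and
shared-control configuration.  The flagship study plants shared controls
between the breast and ovarian studies (score correlation 0.05); every
other pair is independent.  Writes the symmetric overlap matrix TSV used by
the local-correlation scan and the meta-analysis loop.
"""

import common
from pleiofine import study


def main():
    common.ensure_dirs()
    C = study.estimate_overlap_genomewide(common.config(), seed=common.SEED + 7_001)
    C.to_tsv(common.RESULTS / "overlap.tsv")
    print("estimated cross-trait null-score correlations (|c| >= 0.03):")
    for i, a in enumerate(C.trait_names):
        for j in range(i + 1, len(C.trait_names)):
            if abs(C.C[i, j]) >= 0.03:
                print(f"  {a} - {C.trait_names[j]}: {C.C[i, j]:+.3f}")
    print(f"wrote {common.RESULTS / 'overlap.tsv'}")


if __name__ == "__main__":
    main()
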
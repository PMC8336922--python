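"""Shared paths and study conditions for the numbered analysis scripts.

The analysis runs one fully synthetic regional study at the flagship
conditions (eight case-control traits, a 3,000-SNP high-LD region, three
planted cross-trait causal variants, one shared-control pair).  Bulky
intermediate data (the panel VCF, per-trait summary-statistic tables) live
under scratch/; small result tables land in results/.
"""

import pathlib

from pleiofine import simulate as sim

ROOT = pathlib.Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "flagship"
RESULTS = ROOT / "results"

SEED = 0


def config() -> sim.SimConfig:
    return sim.flagship_config(seed=SEED)


def get_panel():
    """The flagship reference panel, regenerated deterministically.

    Identical to the VCF written by 01_simulate.py (same seed); regenerating
    is faster than re-parsing 15M genotypes.
    """
    return sim.simulate_panel(config())


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
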
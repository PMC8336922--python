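"""Reading, quality control and cross-trait harmonization of GWAS summary statistics.

A :class:`SumStatTable` holds one trait's marginal association records as a
pandas DataFrame with canonical columns.  Harmonization places several
traits on a shared allele frame with a deterministic, strand-stable marker
ID ``chr:pos:minAllele:maxAllele`` (alleles ordered lexicographically) so
that tables can be joined byte-identically downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical per-record columns, in output order
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "info",
]

#: built-in column-name mappings (canonical field -> source column)
DIALECTS: dict[str, dict[str, str]] = {
    "native": {c: c for c in CANONICAL_COLUMNS},
    # GCTA ".ma" layout: SNP A1 A2 freq b se p N.  Positions are parsed from
    # the SNP column when it carries a chr:pos:...:... marker.
    "ma": {
        "snp_id": "SNP",
        "effect_allele": "A1",
        "other_allele": "A2",
        "eaf": "freq",
        "beta": "b",
        "se": "se",
        "pval": "p",
    },
}

_MANDATORY = ["effect_allele", "other_allele", "eaf", "beta", "se", "pval"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_allele(a: str) -> str | None:
    """Reverse complement of an allele string, or None if not pure ACGT."""
    if not a or any(ch not in "ACGT" for ch in a):
        return None
    return a[::-1].translate(_COMPLEMENT)


def canonical_marker(chrom, pos, a1: str, a2: str) -> str:
    """Strand-stable canonical marker ID "chr:pos:minAllele:maxAllele".

    The allele pair and its reverse complement name the same variant on
    opposite strands; the lexicographically smaller of the two sorted pairs
    is used, so tables and reference panels agree byte-identically.
    """
    a1, a2 = a1.upper(), a2.upper()
    ra, rb = _revcomp_allele(a1), _revcomp_allele(a2)
    pair = tuple(sorted((a1, a2)))
    if ra is not None and rb is not None:
        pair = min(pair, tuple(sorted((ra, rb))))
    return f"{str(chrom).removeprefix('chr')}:{pos}:{pair[0]}:{pair[1]}"


def _chrom_sort_key(c: str):
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


@dataclass
class SumStatTable:
    """One trait's harmonized per-SNP marginal association records.

    Parameters
    ----------
    trait_name
        Label used in all downstream reports.
    n_cases, n_controls
        Trait-level participant counts; per-SNP sample-size heterogeneity
        is not modeled.
    df
        Records with the canonical columns, sorted by (chrom, pos).
    log
        Drop tallies accumulated by the I/O and filtering steps.
    """

    trait_name: str
    n_cases: int
    n_controls: int
    df: pd.DataFrame
    log: dict = field(default_factory=dict)

    @property
    def n_eff(self) -> float:
        """Effective case-control sample size 4 / (1/n_cases + 1/n_controls)."""
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)

    def __len__(self) -> int:
        return len(self.df)

    def zscores(self) -> pd.Series:
        """Marginal z-statistics beta / se, indexed by snp_id."""
        z = self.df["beta"] / self.df["se"]
        z.index = self.df["snp_id"]
        return z

    def validate(self) -> None:
        df = self.df
        if df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in table")
        if (df["se"] <= 0).any():
            raise ValueError("non-positive se")
        if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
            raise ValueError("eaf outside (0, 1)")
        if self.n_eff <= 0:
            raise ValueError("non-positive effective sample size")

    def _sorted(self) -> "SumStatTable":
        df = self.df.copy()
        df["_ck"] = df["chrom"].map(_chrom_sort_key)
        df = df.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")
        return SumStatTable(
            self.trait_name, self.n_cases, self.n_controls,
            df.reset_index(drop=True), dict(self.log),
        )


def read_sumstats(
    path,
    dialect: str | dict[str, str] = "native",
    *,
    trait_name: str = "trait",
    n_cases: int = 1,
    n_controls: int = 1,
) -> SumStatTable:
    """Read a delimited summary-statistics file into a :class:`SumStatTable`.

    ``dialect`` maps canonical field names to the source's column names
    (or names a built-in mapping, ``"native"`` or ``"ma"``).  Rows whose
    numeric fields fail coercion are dropped and counted in ``table.log``.
    Missing chrom/pos columns are parsed from a ``chr:pos:a:b`` marker ID.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    if raw.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    for canon in _MANDATORY:
        src = dialect.get(canon)
        if src is None or src not in raw.columns:
            raise ValueError(f"missing mandatory column for field '{canon}': {src!r}")

    df = pd.DataFrame(index=raw.index)
    for canon, src in dialect.items():
        if src in raw.columns:
            df[canon] = raw[src]
    if "chrom" not in df.columns or "pos" not in df.columns:
        if "snp_id" not in df.columns:
            raise ValueError("missing mandatory column: chrom/pos (or a parsable snp_id)")
        parts = df["snp_id"].str.split(":", expand=True)
        if parts.shape[1] < 2:
            raise ValueError("snp_id not in chr:pos:...:... form; chrom/pos unavailable")
        df["chrom"] = parts[0].str.removeprefix("chr")
        df["pos"] = parts[1]

    n_raw = len(df)
    for col in ("eaf", "beta", "se", "pval", "info"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    needed = ["pos", "eaf", "beta", "se", "pval"]
    ok = df[needed].notna().all(axis=1) & (df["se"] > 0)
    df = df[ok].copy()
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("%s: dropped %d malformed row(s) of %d", path, n_dropped, n_raw)

    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    if "info" not in df.columns:
        df["info"] = np.nan
    if "snp_id" not in df.columns:
        df["snp_id"] = ""
    df = df[CANONICAL_COLUMNS]

    table = SumStatTable(
        trait_name, n_cases, n_controls, df.reset_index(drop=True),
        log={"rows_read": n_raw, "rows_dropped_malformed": n_dropped},
    )
    return table._sorted()


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table in the GCTA-.ma-style layout plus snp_id, losslessly."""
    out = pd.DataFrame(
        {
            "SNP": table.df["snp_id"],
            "chrom": table.df["chrom"],
            "pos": table.df["pos"],
            "A1": table.df["effect_allele"],
            "A2": table.df["other_allele"],
            "freq": table.df["eaf"],
            "b": table.df["beta"],
            "se": table.df["se"],
            "p": table.df["pval"],
            "N": int(table.n_cases + table.n_controls),
            "info": table.df["info"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def qc_filter(
    table: SumStatTable,
    info_min: float = 0.3,
    maf_min: float = 0.01,
    abs_beta_max: float = 3.0,
) -> SumStatTable:
    """Quality-filter one trait's records.

    Retains records with imputation quality >= ``info_min`` (records with no
    info score are retained), minor allele frequency >= ``maf_min`` and
    |log odds ratio| <= ``abs_beta_max``.  Cutoffs are strict on the removal
    side: info exactly at the threshold is kept.
    """
    df = table.df
    keep_info = df["info"].isna() | (df["info"] >= info_min)
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep_maf = maf >= maf_min
    keep_beta = df["beta"].abs() <= abs_beta_max
    keep = keep_info & keep_maf & keep_beta
    log = dict(table.log)
    log.update(
        {
            "qc_dropped_info": int((~keep_info).sum()),
            "qc_dropped_maf": int((~keep_maf).sum()),
            "qc_dropped_beta": int((~keep_beta).sum()),
        }
    )
    return SumStatTable(
        table.trait_name, table.n_cases, table.n_controls,
        df[keep].reset_index(drop=True), log,
    )


def _canonicalize_one(df: pd.DataFrame) -> pd.DataFrame:
    """Strand-normalize alleles and attach the canonical marker ID.

    For pure-ACGT SNPs the allele pair and its reverse complement denote the
    same variant on opposite strands; the lexicographically smaller of the
    two sorted pairs is chosen so that all tables land on one strand frame.
    The canonical effect allele is the lexicographically smaller allele;
    beta is sign-flipped and eaf complemented where the source effect allele
    was the larger one.
    """
    df = df.copy()
    ea = df["effect_allele"].to_numpy(dtype=object)
    oa = df["other_allele"].to_numpy(dtype=object)
    beta = df["beta"].to_numpy(dtype=float).copy()
    eaf = df["eaf"].to_numpy(dtype=float).copy()

    for i in range(len(df)):
        a, b = ea[i], oa[i]
        ra, rb = _revcomp_allele(a), _revcomp_allele(b)
        if ra is not None and rb is not None:
            if tuple(sorted((ra, rb))) < tuple(sorted((a, b))):
                a, b = ra, rb
        if a > b:
            a, b = b, a
            beta[i] = -beta[i]
            eaf[i] = 1.0 - eaf[i]
        ea[i], oa[i] = a, b

    df["effect_allele"] = ea
    df["other_allele"] = oa
    df["beta"] = beta
    df["eaf"] = eaf
    df["snp_id"] = (
        df["chrom"].astype(str)
        + ":" + df["pos"].astype(str)
        + ":" + df["effect_allele"]
        + ":" + df["other_allele"]
    )
    return df


def harmonize(
    tables: list[SumStatTable],
    drop_ambiguous: bool = True,
    max_allele_len: int = 50,
) -> list[SumStatTable]:
    """Place several tables on a shared allele frame.

    Removes, from every table: within-table duplicate markers, multi-allelic
    positions (more than two distinct alleles observed at a chrom:pos across
    all tables), strand-ambiguous SNPs (A/T and C/G pairs, optional), and
    structural alleles longer than ``max_allele_len`` bases.  A variant whose
    alleles disagree across tables beyond a strand flip shows up as
    multi-allelic and is likewise removed everywhere.  Idempotent and
    order-independent.
    """
    if not tables:
        raise ValueError("harmonize requires at least one table")

    canon = [_canonicalize_one(t.df) for t in tables]

    # alleles observed per position across all tables (post strand-normalization)
    alleles_at: dict[tuple[str, int], set[str]] = {}
    for df in canon:
        for chrom, pos, a, b in zip(df["chrom"], df["pos"], df["effect_allele"], df["other_allele"]):
            alleles_at.setdefault((chrom, int(pos)), set()).update((a, b))
    multi = {k for k, v in alleles_at.items() if len(v) > 2}

    out = []
    for t, df in zip(tables, canon):
        log = dict(t.log)
        n0 = len(df)
        dup = df["snp_id"].duplicated(keep=False)
        df = df[~dup]
        log["harmonize_dropped_duplicate"] = int(dup.sum())

        is_multi = [
            (chrom, int(pos)) in multi for chrom, pos in zip(df["chrom"], df["pos"])
        ]
        is_multi = np.asarray(is_multi, dtype=bool)
        df = df[~is_multi]
        log["harmonize_dropped_multiallelic"] = int(is_multi.sum())

        pair = df["effect_allele"] + "/" + df["other_allele"]
        ambiguous = pair.isin(["A/T", "C/G"]).to_numpy()
        if drop_ambiguous:
            df = df[~ambiguous]
            log["harmonize_dropped_ambiguous"] = int(ambiguous.sum())

        structural = (
            (df["effect_allele"].str.len() > max_allele_len)
            | (df["other_allele"].str.len() > max_allele_len)
        ).to_numpy()
        df = df[~structural]
        log["harmonize_dropped_structural"] = int(structural.sum())
        logger.info(
            "%s: harmonize kept %d/%d records", t.trait_name, len(df), n0
        )
        out.append(
            SumStatTable(
                t.trait_name, t.n_cases, t.n_controls,
                df.reset_index(drop=True), log,
            )._sorted()
        )
    return out


def intersect_snps(tables: list[SumStatTable]) -> list[str]:
    """Marker IDs present in every table, in the first table's order."""
    common = set(tables[0].df["snp_id"])
    for t in tables[1:]:
        common &= set(t.df["snp_id"])
    return [s for s in tables[0].df["snp_id"] if s in common]
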
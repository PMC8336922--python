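"""Summary-statistics reading, QC filtering and cross-trait harmonization."""

import numpy as np
import pandas as pd
import pytest

from pleiofine import sumstats as ss


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


NATIVE_HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tinfo\n"


def _native_file(tmp_path, rows, name="t.tsv"):
    return _write(tmp_path, name, NATIVE_HEADER + "".join(rows))


class TestReadSumstats:
    def test_well_formed_file_sorted_by_position(self, tmp_path):
        p = _native_file(
            tmp_path,
            [
                "5:300:A:G\t5\t300\tA\tG\t0.3\t0.1\t0.05\t0.045\t0.9\n",
                "5:100:C:T\t5\t100\tC\tT\t0.2\t-0.2\t0.04\t1e-6\t0.8\n",
                "5:200:A:C\t5\t200\tA\tC\t0.5\t0.0\t0.05\t1.0\t1.0\n",
            ],
        )
        t = ss.read_sumstats(p, trait_name="demo", n_cases=100, n_controls=100)
        assert len(t) == 3
        assert list(t.df["pos"]) == [100, 200, 300]
        t.validate()

    def test_na_row_dropped_and_counted(self, tmp_path):
        p = _native_file(
            tmp_path,
            [
                "5:100:C:T\t5\t100\tC\tT\t0.2\t-0.2\tNA\t1e-6\t0.8\n",
                "5:200:A:C\t5\t200\tA\tC\t0.5\t0.0\t0.05\t1.0\t1.0\n",
                "5:300:A:G\t5\t300\tA\tG\t0.3\t0.1\t0.05\t0.045\t0.9\n",
            ],
        )
        t = ss.read_sumstats(p)
        assert len(t) == 2
        assert t.log["rows_dropped_malformed"] == 1

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "snp_id\tbeta\n5:1:A:C\t0.1\n")
        with pytest.raises(ValueError, match="mandatory"):
            ss.read_sumstats(p)

    def test_empty_file_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "empty.tsv", NATIVE_HEADER)
        with pytest.raises(ValueError):
            ss.read_sumstats(p)

    def test_ma_dialect_roundtrip_matches_native(self, tmp_path):
        """A random table read through the GCTA-.ma layout equals the native read."""
        rng = np.random.default_rng(5)
        n = 25
        pos = np.sort(rng.choice(10_000, n, replace=False)) + 1
        ea = rng.choice(["A", "C"], n)
        rows_native, rows_ma = [], []
        for i in range(n):
            a, b = ("A", "G") if ea[i] == "A" else ("C", "T")
            eaf, beta, se = rng.uniform(0.05, 0.95), rng.normal(0, 0.1), rng.uniform(0.01, 0.1)
            pval = rng.uniform(1e-8, 1)
            sid = f"5:{pos[i]}:{a}:{b}"
            rows_native.append(
                f"{sid}\t5\t{pos[i]}\t{a}\t{b}\t{eaf}\t{beta}\t{se}\t{pval}\t1.0\n"
            )
            rows_ma.append(f"{sid}\t{a}\t{b}\t{eaf}\t{beta}\t{se}\t{pval}\t20000\n")
        p1 = _native_file(tmp_path, rows_native)
        p2 = _write(tmp_path, "t.ma", "SNP\tA1\tA2\tfreq\tb\tse\tp\tN\n" + "".join(rows_ma))
        t1 = ss.read_sumstats(p1)
        t2 = ss.read_sumstats(p2, dialect="ma")
        for col in ("snp_id", "chrom", "pos", "effect_allele", "other_allele"):
            assert list(t1.df[col]) == list(t2.df[col])
        for col in ("eaf", "beta", "se", "pval"):
            np.testing.assert_allclose(t1.df[col], t2.df[col])

    def test_write_read_roundtrip_lossless(self, tmp_path):
        p = _native_file(
            tmp_path,
            ["5:100:C:T\t5\t100\tC\tT\t0.2\t-0.2\t0.04\t1e-6\t0.8\n"],
        )
        t = ss.read_sumstats(p, trait_name="x", n_cases=10, n_controls=30)
        out = tmp_path / "out.tsv"
        ss.write_sumstats(t, out)
        t2 = ss.read_sumstats(
            out,
            dialect={**ss.DIALECTS["ma"], "chrom": "chrom", "pos": "pos", "info": "info"},
            trait_name="x", n_cases=10, n_controls=30,
        )
        pd.testing.assert_frame_equal(t.df, t2.df)


def _table(records, name="t", n_cases=1000, n_controls=1000):
    df = pd.DataFrame(records, columns=[
        "snp_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "info",
    ])
    return ss.SumStatTable(name, n_cases, n_controls, df)


def _rec(pos, ea, oa, eaf=0.3, beta=0.1, se=0.05, pval=0.04, info=0.9, chrom="5"):
    return (f"{chrom}:{pos}:{min(ea,oa)}:{max(ea,oa)}", chrom, pos, ea, oa,
            eaf, beta, se, pval, info)


class TestQcFilter:
    @pytest.mark.parametrize(
        "field,value,kept",
        [
            ("info", 0.2, False),   # below the imputation-quality cutoff
            ("info", 0.3, True),    # boundary: strict "<" removal
            ("info", np.nan, True), # no info score: filter skipped
            ("eaf", 0.005, False),  # MAF below 1%
            ("eaf", 0.995, False),  # MAF symmetric in eaf
            ("beta", 3.5, False),   # |log odds ratio| above 3
            ("beta", -3.5, False),
            ("beta", 3.0, True),
        ],
    )
    def test_filter_rules(self, field, value, kept):
        rec = dict(zip(
            ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "eaf", "beta", "se", "pval", "info"],
            _rec(100, "A", "G"),
        ))
        rec[field] = value
        t = _table([tuple(rec.values())])
        out = ss.qc_filter(t)
        assert (len(out) == 1) == kept

    def test_idempotent_and_never_grows(self):
        t = _table([_rec(100, "A", "G", info=0.2), _rec(200, "C", "T"),
                    _rec(300, "A", "C", eaf=0.002)])
        once = ss.qc_filter(t)
        twice = ss.qc_filter(once)
        assert len(once) <= len(t)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestHarmonize:
    def test_ambiguous_snp_removed(self):
        t = _table([_rec(100, "A", "T"), _rec(200, "C", "G"), _rec(300, "A", "G")])
        (out,) = ss.harmonize([t])
        assert list(out.df["pos"]) == [300]

    def test_swapped_effect_allele_signs_align(self):
        t1 = _table([_rec(100, "A", "G", eaf=0.3, beta=0.5)], name="t1")
        t2 = _table([_rec(100, "G", "A", eaf=0.7, beta=-0.5)], name="t2")
        o1, o2 = ss.harmonize([t1, t2])
        assert o1.df.loc[0, "beta"] == o2.df.loc[0, "beta"] == 0.5
        np.testing.assert_allclose(o1.df.loc[0, "eaf"], 0.3)
        np.testing.assert_allclose(o2.df.loc[0, "eaf"], 0.3)
        assert o1.df.loc[0, "snp_id"] == o2.df.loc[0, "snp_id"]

    def test_strand_flip_reconciled(self):
        # same variant reported on opposite strands: A/G vs T/C
        t1 = _table([_rec(100, "A", "G", beta=0.4)], name="t1")
        t2 = _table([_rec(100, "T", "C", beta=0.4)], name="t2")
        o1, o2 = ss.harmonize([t1, t2])
        assert o1.df.loc[0, "snp_id"] == o2.df.loc[0, "snp_id"]
        assert o1.df.loc[0, "beta"] == o2.df.loc[0, "beta"]

    def test_allele_mismatch_removed_not_error(self):
        t1 = _table([_rec(100, "A", "G")], name="t1")
        t2 = _table([_rec(100, "A", "C")], name="t2")
        o1, o2 = ss.harmonize([t1, t2])
        assert len(o1) == 0 and len(o2) == 0

    def test_idempotent(self):
        t1 = _table([_rec(100, "G", "A", beta=-0.2), _rec(200, "C", "T")], name="t1")
        t2 = _table([_rec(100, "A", "G", beta=0.2), _rec(300, "T", "G")], name="t2")
        once = ss.harmonize([t1, t2])
        twice = ss.harmonize(once)
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a.df, b.df)

    def test_order_independent(self):
        t1 = _table([_rec(100, "G", "A"), _rec(200, "C", "T")], name="t1")
        t2 = _table([_rec(100, "A", "G"), _rec(300, "T", "G")], name="t2")
        t3 = _table([_rec(200, "T", "C"), _rec(300, "G", "T")], name="t3")
        fwd = {t.trait_name: t for t in ss.harmonize([t1, t2, t3])}
        rev = {t.trait_name: t for t in ss.harmonize([t3, t1, t2])}
        for name in fwd:
            pd.testing.assert_frame_equal(fwd[name].df, rev[name].df)

    def test_intersection_alleles_identical(self):
        t1 = _table([_rec(100, "G", "A"), _rec(200, "C", "T")], name="t1")
        t2 = _table([_rec(100, "A", "G"), _rec(200, "T", "C")], name="t2")
        o1, o2 = ss.harmonize([t1, t2])
        m = o1.df.merge(o2.df, on="snp_id")
        assert (m["effect_allele_x"] == m["effect_allele_y"]).all()
        assert (m["other_allele_x"] == m["other_allele_y"]).all()

    def test_long_indel_removed_short_indel_kept(self):
        t = _table([_rec(100, "A", "AC"), _rec(200, "A", "A" + "C" * 60)])
        (out,) = ss.harmonize([t])
        assert list(out.df["pos"]) == [100]
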
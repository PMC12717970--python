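from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutload.errors import ConfigError
from mutload.sv import (
    CALL_COLUMNS,
    collapse_across_accessions,
    consensus_per_accession,
    genic_feature_overlap,
    load_in_sv_vs_outside,
    longread_concordance,
    read_caller_vcfs,
    sv_filter_and_polarize,
)

from ._oracles import brute_force_clusters
from .conftest import make_assignment, make_categories, make_polarized

SV_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def sv_vcf(tmp_path, records, name="sv.vcf"):
    p = tmp_path / name
    p.write_text(SV_VCF_HEADER + "".join(records))
    return p


def calls_frame(rows):
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class TestReadCallerVcfs:
    def test_del_with_end(self, tmp_path):
        p = sv_vcf(tmp_path, ["chr1\t1000\tsv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500\n"])
        df = read_caller_vcfs({"a1": {"callerA": p}})
        assert df.iloc[0]["start"] == 1000
        assert df.iloc[0]["end"] == 1500
        assert df.iloc[0]["type"] == "DEL"

    def test_ins_dropped(self, tmp_path):
        p = sv_vcf(
            tmp_path,
            [
                "chr1\t1000\ti1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=1000\n",
                "chr1\t2000\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2500\n",
            ],
        )
        df = read_caller_vcfs({"a1": {"callerA": p}})
        assert len(df) == 1
        assert df.iloc[0]["type"] == "DEL"

    def test_svlen_substitutes_for_missing_end(self, tmp_path):
        p = sv_vcf(
            tmp_path, ["chr1\t1000\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-470\n"]
        )
        df = read_caller_vcfs({"a1": {"callerA": p}})
        assert df.iloc[0]["end"] == 1470

    def test_missing_svtype_skipped(self, tmp_path):
        p = sv_vcf(tmp_path, ["chr1\t1000\tx\tN\t<DEL>\t.\tPASS\tEND=1500\n"])
        df = read_caller_vcfs({"a1": {"callerA": p}})
        assert len(df) == 0

    def test_within_caller_duplicates_collapsed(self, tmp_path):
        rec = "chr1\t1000\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500\n"
        p = sv_vcf(tmp_path, [rec, rec.replace("d1", "d2")])
        df = read_caller_vcfs({"a1": {"callerA": p}})
        assert len(df) == 1


class TestConsensus:
    def test_two_caller_merge(self):
        calls = calls_frame(
            [
                ("a1", "callerA", "chr1", 1000, 1500, "DEL", "x1"),
                ("a1", "callerB", "chr1", 1050, 1540, "DEL", "x2"),
            ]
        )
        out = consensus_per_accession(calls)
        assert len(out) == 1
        assert out.iloc[0]["n_callers"] == 2
        assert out.iloc[0]["start"] == 1025
        assert out.iloc[0]["end"] == 1520

    def test_type_mismatch_no_merge(self):
        calls = calls_frame(
            [
                ("a1", "callerA", "chr1", 1000, 1500, "DEL", "x1"),
                ("a1", "callerB", "chr1", 1000, 1500, "DUP", "x2"),
            ]
        )
        out = consensus_per_accession(calls)
        assert len(out) == 0

    def test_min_size_dropped(self):
        calls = calls_frame(
            [
                ("a1", "callerA", "chr1", 1000, 1024, "DEL", "x1"),
                ("a1", "callerB", "chr1", 1000, 1024, "DEL", "x2"),
            ]
        )
        out = consensus_per_accession(calls)
        assert len(out) == 0

    def test_single_caller_not_emitted(self):
        calls = calls_frame([("a1", "callerA", "chr1", 1000, 2000, "DEL", "x1")])
        assert len(consensus_per_accession(calls)) == 0

    def test_length_ratio_criterion(self):
        # same start, lengths 1000 vs 800: ratio 0.8 < 0.9 -> no merge
        calls = calls_frame(
            [
                ("a1", "callerA", "chr1", 1000, 1999, "DEL", "x1"),
                ("a1", "callerB", "chr1", 1000, 1799, "DEL", "x2"),
            ]
        )
        assert len(consensus_per_accession(calls)) == 0

    def test_tra_uses_both_breakpoints(self):
        calls = calls_frame(
            [
                ("a1", "callerA", "chr1", 1000, 900_000, "TRA", "x1"),
                ("a1", "callerB", "chr1", 1050, 900_060, "TRA", "x2"),
                ("a1", "callerC", "chr1", 1050, 950_000, "TRA", "x3"),
            ]
        )
        out = consensus_per_accession(calls)
        assert len(out) == 1
        assert out.iloc[0]["n_callers"] == 2


class TestCollapse:
    def _consensus(self, rows):
        return pd.DataFrame(
            rows,
            columns=["accession", "chrom", "start", "end", "type", "n_callers",
                     "callers", "member_ids"],
        )

    def test_identical_three_accessions(self):
        rows = [
            (f"a{i}", "chr1", 1000, 2000, "DEL", 2, "callerA,callerB", f"m{i}")
            for i in range(3)
        ]
        out = collapse_across_accessions(self._consensus(rows))
        assert len(out) == 1
        assert out.iloc[0]["n_carriers"] == 3

    def test_150bp_apart_two_entries(self):
        rows = [
            ("a1", "chr1", 1000, 2000, "DEL", 2, "callerA,callerB", "m1"),
            ("a2", "chr1", 1150, 2150, "DEL", 2, "callerA,callerB", "m2"),
        ]
        out = collapse_across_accessions(self._consensus(rows))
        assert len(out) == 2

    def test_brute_force_oracle(self, rng):
        # scaled-down; the full 200-trial version is in the acceptance suite
        for trial in range(30):
            n = 50
            df = pd.DataFrame(
                {
                    "accession": rng.choice(["a1", "a2", "a3"], size=n),
                    "chrom": rng.choice(["chr1", "chr2"], size=n),
                    "start": rng.integers(1, 20_000, size=n),
                    "type": rng.choice(["DEL", "DUP", "INV", "TRA"], size=n),
                    "n_callers": 2,
                    "callers": "callerA,callerB",
                }
            )
            df["end"] = df["start"] + rng.integers(100, 3000, size=n)
            df["member_ids"] = [f"m{i}" for i in range(n)]
            out = collapse_across_accessions(df)
            got = {
                frozenset(ids.split(",")) for ids in out["member_ids"]
            }
            expected_idx = brute_force_clusters(df, 100, 0.9)
            expected = {
                frozenset(df.loc[list(c), "member_ids"]) for c in expected_idx
            }
            assert got == expected, f"trial {trial}"

    def test_order_invariance(self, rng):
        rows = [
            ("a1", "chr1", 1000, 2000, "DEL", 2, "callerA,callerB", "m1"),
            ("a2", "chr1", 1050, 2080, "DEL", 2, "callerA,callerB", "m2"),
            ("a3", "chr1", 5000, 6000, "DUP", 2, "callerA,callerC", "m3"),
            ("a1", "chr2", 1000, 2000, "DEL", 2, "callerB,callerC", "m4"),
        ]
        base = self._consensus(rows)
        out1 = collapse_across_accessions(base)
        out2 = collapse_across_accessions(
            base.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_idempotent(self):
        rows = [
            ("a1", "chr1", 1000, 2000, "DEL", 2, "callerA,callerB", "m1"),
            ("a2", "chr1", 1050, 2080, "DEL", 2, "callerA,callerB", "m2"),
        ]
        once = collapse_across_accessions(self._consensus(rows))
        again = collapse_across_accessions(
            once.assign(accession=once["carriers"].str.split(",").str[0],
                        n_callers=2, callers="callerA,callerB")[
                ["accession", "chrom", "start", "end", "type", "n_callers",
                 "callers", "member_ids"]
            ]
        )
        assert len(again) == len(once)
        assert again["start"].tolist() == once["start"].tolist()


class TestFilterPolarize:
    def _catalogue(self, carriers, chrom="chr1"):
        return pd.DataFrame(
            {
                "sv_id": ["sv1"],
                "chrom": [chrom],
                "start": [1000],
                "end": [2000],
                "type": ["DEL"],
                "carriers": [",".join(carriers)],
                "n_carriers": [len(carriers)],
                "member_ids": ["m"],
            }
        )

    def test_rare_sv_dropped(self):
        accs = [f"a{i}" for i in range(200)] + ["OG"]
        cat = self._catalogue(["a0"])
        out = sv_filter_and_polarize(cat, accs, "OG", 0.01)
        assert len(out) == 0

    def test_outgroup_carrier_absence_derived(self):
        accs = ["a0", "a1", "a2", "a3", "OG"]
        cat = self._catalogue(["a0", "a1", "OG"])
        out = sv_filter_and_polarize(cat, accs, "OG", 0.01)
        assert out.iloc[0]["derived_state"] == "absence"
        assert out.iloc[0]["presence_freq"] == 0.5

    def test_outgroup_noncarrier_presence_derived(self):
        accs = ["a0", "a1", "a2", "a3", "OG"]
        out = sv_filter_and_polarize(self._catalogue(["a0", "a1"]), accs, "OG")
        assert out.iloc[0]["derived_state"] == "presence"


GENES = pd.DataFrame(
    [
        ("chr1", 1000, 1999, "gene", "g1"),
        ("chr1", 1000, 1199, "five_prime_UTR", "g1"),
        ("chr1", 1200, 1399, "exon", "g1"),
        ("chr1", 1400, 1599, "intron", "g1"),
        ("chr1", 1600, 1799, "exon", "g1"),
        ("chr1", 1800, 1999, "three_prime_UTR", "g1"),
        ("chr1", 5000, 5999, "gene", "g2"),
        ("chr1", 5000, 5199, "five_prime_UTR", "g2"),
        ("chr1", 5200, 5799, "exon", "g2"),
        ("chr1", 5800, 5999, "three_prime_UTR", "g2"),
    ],
    columns=["chrom", "start", "end", "feature", "gene_id"],
)


def catalogue_of(rows):
    return pd.DataFrame(
        rows, columns=["sv_id", "chrom", "start", "end", "type"]
    ).assign(carriers="a0", n_carriers=1, member_ids="m")


class TestGenicOverlap:
    def test_intronic_del(self):
        cat = catalogue_of([("s1", "chr1", 1450, 1500, "DEL")])
        out = genic_feature_overlap(cat, GENES, genome_size=10_000).set_index("region")
        assert out.loc["genic", "raw_count"] == 1
        assert out.loc["intron", "raw_count"] == 1
        assert out.loc["exon", "raw_count"] == 0
        assert out.loc["non_genic", "raw_count"] == 0

    def test_intergenic_del(self):
        cat = catalogue_of([("s1", "chr1", 3000, 3100, "DEL")])
        out = genic_feature_overlap(cat, GENES, genome_size=10_000).set_index("region")
        assert out.loc["non_genic", "raw_count"] == 1
        assert out.loc["genic", "raw_count"] == 0

    def test_adjustment_arithmetic(self):
        # 10 SVs in 1 Mb genic vs 10 in 4 Mb non-genic -> 10 vs 2.5 per Mb
        gene = pd.DataFrame(
            [("chr1", 1, 1_000_000, "gene", "g1")],
            columns=["chrom", "start", "end", "feature", "gene_id"],
        )
        rows = [(f"g{i}", "chr1", 100 + 50 * i, 120 + 50 * i, "DEL") for i in range(10)]
        rows += [
            (f"n{i}", "chr1", 1_500_000 + 1000 * i, 1_500_100 + 1000 * i, "DEL")
            for i in range(10)
        ]
        out = genic_feature_overlap(
            catalogue_of(rows), gene, genome_size=5_000_000
        ).set_index("region")
        assert out.loc["genic", "adjusted_per_mb"] == pytest.approx(10.0)
        assert out.loc["non_genic", "adjusted_per_mb"] == pytest.approx(2.5)

    def test_overlapping_genes_rejected(self):
        bad = pd.DataFrame(
            [
                ("chr1", 100, 500, "gene", "g1"),
                ("chr1", 400, 900, "gene", "g2"),
            ],
            columns=["chrom", "start", "end", "feature", "gene_id"],
        )
        with pytest.raises(ConfigError, match="overlapping"):
            genic_feature_overlap(catalogue_of([]), bad)

    def test_tra_attributed_by_breakpoints(self):
        cat = catalogue_of([("t1", "chr1", 1450, 3000, "TRA")])
        out = genic_feature_overlap(cat, GENES, genome_size=10_000).set_index("region")
        # one breakpoint in the intron, the other intergenic
        assert out.loc["genic", "raw_count"] == 1
        assert out.loc["non_genic", "raw_count"] == 1
        assert out.loc["intron", "raw_count"] == 1


class TestLoadInSV:
    def _setup(self, site_positions, labels, dosage, sv_rows):
        t = make_polarized(
            np.asarray(dosage, dtype=np.int8), chrom="chr1", start_pos=0, step=0
        )
        t.sites["pos"] = site_positions
        cats = make_categories(t, labels)
        asg = make_assignment(
            {a: "p1" for a in t.accessions}
        )
        return t, cats, asg, catalogue_of(sv_rows)

    def test_no_svs_inside_undefined(self):
        t, cats, asg, cat_sv = self._setup(
            [1250, 1650], ["deleterious", "neutral_nonsynonymous"],
            [[2, 2], [2, 2]], [],
        )
        acc, tests = load_in_sv_vs_outside(cat_sv, cats, t, asg, GENES)
        assert acc["ratio_inside"].isna().all()
        assert acc["ratio_outside"].notna().all()

    def test_brute_force_fixture(self):
        # g1 overlapped by an SV, g2 not; accession carries different
        # dosages in each gene
        positions = [1250, 1450, 5300, 5400]
        labels = [
            "deleterious", "neutral_nonsynonymous",
            "deleterious", "neutral_nonsynonymous",
        ]
        dosage = [[2, 1], [2, 2], [1, 0], [2, 2]]
        t, cats, asg, cat_sv = self._setup(
            positions, labels, dosage, [("s1", "chr1", 1100, 1300, "DEL")]
        )
        acc, tests = load_in_sv_vs_outside(cat_sv, cats, t, asg, GENES)
        a0 = acc.set_index("accession").loc["acc0"]
        assert a0["ratio_inside"] == pytest.approx(1.0)   # 1 / 1
        assert a0["ratio_outside"] == pytest.approx(0.5)  # 0.5 / 1
        a1 = acc.set_index("accession").loc["acc1"]
        assert a1["ratio_inside"] == pytest.approx(0.5)   # 0.5 / 1
        assert a1["ratio_outside"] == pytest.approx(0.0)

    def test_planted_enrichment_detected(self, rng):
        # quick version of the planted 2x deleterious-density comparison
        hits = 0
        reps = 10
        for _ in range(reps):
            n_genes, n_acc = 40, 20
            genes = []
            for g in range(n_genes):
                s = 1000 + 5000 * g
                genes.append(("chr1", s, s + 999, "gene", f"g{g}"))
            genes_df = pd.DataFrame(
                genes, columns=["chrom", "start", "end", "feature", "gene_id"]
            )
            sv_rows = [
                (f"s{g}", "chr1", 1000 + 5000 * g, 1200 + 5000 * g, "DEL")
                for g in range(0, n_genes, 2)
            ]
            positions, labels = [], []
            for g in range(n_genes):
                base = 1000 + 5000 * g
                overlapped = g % 2 == 0
                n_del = 6 if overlapped else 3
                for k in range(n_del):
                    positions.append(base + 10 + k)
                    labels.append("deleterious")
                for k in range(6):
                    positions.append(base + 500 + k)
                    labels.append("neutral_nonsynonymous")
            dosage = rng.integers(0, 3, size=(len(positions), n_acc))
            t, cats, asg, _ = self._setup(
                positions, labels, dosage, sv_rows
            )
            acc, tests = load_in_sv_vs_outside(
                catalogue_of(sv_rows), cats, t, asg, genes_df
            )
            row = tests.iloc[0]
            if row["mean_inside"] > row["mean_outside"] and row["p"] < 0.05:
                hits += 1
        assert hits >= 9


class TestConcordance:
    def _svs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "type"])

    def test_identical_lists(self):
        svs = self._svs([("chr1", 100, 200, "DEL"), ("chr2", 5, 50, "DUP")])
        assert longread_concordance(svs, svs.copy()) == 1.0

    def test_disjoint_chromosomes(self):
        a = self._svs([("chr1", 100, 200, "DEL")])
        b = self._svs([("chr2", 100, 200, "DEL")])
        assert longread_concordance(a, b) == 0.0

    def test_empty_short_set_undefined(self):
        a = self._svs([])
        b = self._svs([("chr1", 100, 200, "DEL")])
        assert np.isnan(longread_concordance(a, b))

    def test_planted_seventy_percent(self):
        short = self._svs(
            [("chr1", 1000 * i, 1000 * i + 500, "DEL") for i in range(10)]
        )
        long_rows = [
            ("chr1", 1000 * i + 20, 1000 * i + 520, "DEL") for i in range(7)
        ]
        long_df = self._svs(long_rows)
        assert longread_concordance(short, long_df) == pytest.approx(0.70)

    def test_one_to_one_matching(self):
        # two short SVs near one long SV: only one can match
        short = self._svs(
            [("chr1", 100, 200, "DEL"), ("chr1", 150, 250, "DEL")]
        )
        long_df = self._svs([("chr1", 120, 220, "DEL")])
        assert longread_concordance(short, long_df) == 0.5
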
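"""Structural-variant consensus, collapsing, polarization and overlap.

Merging follows the SURVIVOR-style criterion: two same-type, same-chrom
calls merge when their start positions are within ``max_dist`` bp and
their length ratio (min/max) is at least ``min_overlap``; translocations
compare both breakpoints and skip the length criterion.  Clustering is
single linkage (chains are possible) and the cluster representative is
the member-wise median of coordinates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .errors import ConfigError
from .variant_io import PolarizedSiteTable, PopulationAssignment

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

CALL_COLUMNS = ["accession", "caller", "chrom", "start", "end", "type", "call_id"]


def read_caller_vcfs(
    paths: Mapping[str, Mapping[str, str | Path]],
) -> pd.DataFrame:
    """Read per-accession, per-caller SV VCFs into one call table.

    ``paths`` maps accession -> caller -> VCF path.  INS records are
    dropped (count logged); records without SVTYPE are skipped with a
    warning; a negative SVLEN substitutes for a missing END.  BND records
    are normalized to TRA breakpoint pairs when the mate is on the same
    chromosome.
    """
    rows = []
    n_ins = 0
    for acc, callers in paths.items():
        for caller, path in callers.items():
            for v in VCF(str(path)):
                svtype = v.INFO.get("SVTYPE")
                if svtype is None:
                    logger.warning("%s: record at %s:%d lacks SVTYPE; skipped",
                                   path, v.CHROM, v.POS)
                    continue
                if svtype == "INS":
                    n_ins += 1
                    continue
                if svtype == "BND":
                    svtype = "TRA"
                if svtype not in SV_TYPES:
                    logger.warning("%s: unknown SVTYPE %s skipped", path, svtype)
                    continue
                start = v.POS
                end = v.INFO.get("END")
                if end is None:
                    svlen = v.INFO.get("SVLEN")
                    if svlen is None:
                        logger.warning(
                            "%s: record at %s:%d lacks END and SVLEN; skipped",
                            path, v.CHROM, start,
                        )
                        continue
                    end = start + abs(int(svlen))
                rows.append(
                    (acc, caller, v.CHROM, int(start), int(end), svtype,
                     v.ID or f"{caller}:{v.CHROM}:{start}")
                )
    if n_ins:
        logger.info("dropped %d INS records", n_ins)
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    # within-caller duplicates (identical span and type) are collapsed
    df = df.drop_duplicates(
        subset=["accession", "caller", "chrom", "start", "end", "type"]
    ).reset_index(drop=True)
    return df


def _compatible(
    a_start: int, a_end: int, b_start: int, b_end: int,
    svtype: str, max_dist: int, min_overlap: float,
) -> bool:
    if svtype == "TRA":
        return abs(a_start - b_start) <= max_dist and abs(a_end - b_end) <= max_dist
    if abs(a_start - b_start) > max_dist:
        return False
    la = a_end - a_start + 1
    lb = b_end - b_start + 1
    return min(la, lb) / max(la, lb) >= min_overlap


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _cluster(
    df: pd.DataFrame, max_dist: int, min_overlap: float
) -> list[np.ndarray]:
    """Single-linkage clusters within one (chrom, type) group.

    Candidate pairs are pruned by sorted start position; single linkage
    is then the transitive closure of pairwise compatibility.
    """
    order = df.sort_values(["start", "end"], kind="mergesort").index.to_numpy()
    starts = df.loc[order, "start"].to_numpy()
    ends = df.loc[order, "end"].to_numpy()
    svtype = df["type"].iloc[0]
    uf = _UnionFind(len(order))
    for i in range(len(order)):
        for k in range(i + 1, len(order)):
            if starts[k] - starts[i] > max_dist:
                break
            if _compatible(
                starts[i], ends[i], starts[k], ends[k], svtype, max_dist, min_overlap
            ):
                uf.union(i, k)
    groups: dict[int, list[int]] = {}
    for i in range(len(order)):
        groups.setdefault(uf.find(i), []).append(i)
    return [order[np.array(g)] for g in groups.values()]


def _cluster_all(
    df: pd.DataFrame, max_dist: int, min_overlap: float
) -> list[np.ndarray]:
    clusters = []
    for _, grp in df.groupby(["chrom", "type"], sort=True):
        clusters.extend(_cluster(grp, max_dist, min_overlap))
    return clusters


def consensus_per_accession(
    calls: pd.DataFrame,
    max_dist: int = 100,
    min_overlap: float = 0.9,
    min_size: int = 30,
) -> pd.DataFrame:
    """Two-of-three caller consensus per accession.

    Same-type, same-chromosome calls of one accession are single-linkage
    clustered; clusters supported by at least two distinct callers are
    emitted with member-wise median coordinates.  Non-TRA consensus SVs
    shorter than ``min_size`` bp are dropped.
    """
    rows = []
    for acc, grp in calls.groupby("accession", sort=True):
        for cluster in _cluster_all(grp, max_dist, min_overlap):
            members = grp.loc[cluster]
            callers = sorted(members["caller"].unique())
            if len(callers) < 2:
                continue
            start = int(np.median(members["start"]))
            end = int(np.median(members["end"]))
            svtype = members["type"].iloc[0]
            if svtype != "TRA" and end - start + 1 < min_size:
                continue
            rows.append(
                {
                    "accession": acc,
                    "chrom": members["chrom"].iloc[0],
                    "start": start,
                    "end": end,
                    "type": svtype,
                    "n_callers": len(callers),
                    "callers": ",".join(callers),
                    "member_ids": ",".join(sorted(members["call_id"])),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "accession", "chrom", "start", "end", "type",
            "n_callers", "callers", "member_ids",
        ],
    )
    return out.sort_values(
        ["chrom", "start", "end", "type", "accession"], kind="mergesort"
    ).reset_index(drop=True)


def collapse_across_accessions(
    consensus: pd.DataFrame,
    max_dist: int = 100,
    min_overlap: float = 0.9,
) -> pd.DataFrame:
    """Collapse per-accession consensus SVs into one catalogue.

    The same clustering rule is applied across accessions; each entry
    carries a presence/absence carrier list and member-wise median
    coordinates.  Deterministic given any input row order.
    """
    rows = []
    for cluster in _cluster_all(consensus, max_dist, min_overlap):
        members = consensus.loc[cluster]
        carriers = sorted(members["accession"].unique())
        rows.append(
            {
                "chrom": members["chrom"].iloc[0],
                "start": int(np.median(members["start"])),
                "end": int(np.median(members["end"])),
                "type": members["type"].iloc[0],
                "carriers": ",".join(carriers),
                "n_carriers": len(carriers),
                "member_ids": ",".join(sorted({
                    i for ids in members["member_ids"] for i in ids.split(",")
                })),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "type", "carriers", "n_carriers",
                 "member_ids"],
    ).sort_values(["chrom", "start", "end", "type"], kind="mergesort").reset_index(
        drop=True
    )
    out.insert(0, "sv_id", [f"sv{i:05d}" for i in range(len(out))])
    return out


def sv_filter_and_polarize(
    catalogue: pd.DataFrame,
    accessions: Sequence[str],
    outgroup: str,
    min_maf: float = 0.01,
) -> pd.DataFrame:
    """MAF filter and outgroup polarization of the SV catalogue.

    Genotypes are presence/absence; the presence frequency is computed
    over all non-outgroup accessions and entries with
    ``min(f, 1 - f) < min_maf`` are dropped.  The derived state is the
    state absent from the outgroup.
    """
    non_og = [a for a in accessions if a != outgroup]
    if not non_og:
        raise ConfigError("no non-outgroup accessions")
    out = catalogue.copy()
    carrier_sets = [set(c.split(",")) if c else set() for c in out["carriers"]]
    freq = np.array(
        [len(cs & set(non_og)) / len(non_og) for cs in carrier_sets]
    )
    out["presence_freq"] = freq
    out["maf"] = np.minimum(freq, 1.0 - freq)
    out["derived_state"] = [
        "absence" if outgroup in cs else "presence" for cs in carrier_sets
    ]
    keep = out["maf"] >= min_maf
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d SVs with MAF < %s", dropped, min_maf)
    return out.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genic / feature overlap


def _overlaps(start: int, end: int, f_start: np.ndarray, f_end: np.ndarray) -> np.ndarray:
    return (start <= f_end) & (end >= f_start)


def _sv_intervals(row) -> list[tuple[str, int, int]]:
    """Overlap intervals for one SV; TRA contributes each breakpoint."""
    if row.type == "TRA":
        return [(row.chrom, row.start, row.start), (row.chrom, row.end, row.end)]
    return [(row.chrom, row.start, row.end)]


def genic_feature_overlap(
    catalogue: pd.DataFrame,
    gene_models: pd.DataFrame,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Genic/non-genic and per-feature SV counts, raw and size-adjusted.

    An SV is genic when its span overlaps any gene body by at least one
    bp; it is attributed to every feature class it overlaps.  Adjusted
    counts divide by the total Mb of the region class.  Gene models must
    be non-overlapping.
    """
    genes = gene_models[gene_models["feature"] == "gene"].reset_index(drop=True)
    for chrom, grp in genes.groupby("chrom"):
        srt = grp.sort_values("start")
        if (srt["start"].to_numpy()[1:] <= srt["end"].to_numpy()[:-1]).any():
            raise ConfigError(f"overlapping gene models on {chrom}")
    feature_classes = ["five_prime_UTR", "exon", "intron", "three_prime_UTR"]
    genic_bp = int((genes["end"] - genes["start"] + 1).sum())
    if genome_size is None:
        genome_size = int(gene_models["end"].max()) * len(
            gene_models["chrom"].unique()
        )
    non_genic_bp = max(genome_size - genic_bp, 0)

    counts = {c: 0 for c in ["genic", "non_genic"] + feature_classes}
    by_chrom = {c: g for c, g in gene_models.groupby("chrom")}
    for row in catalogue.itertuples(index=False):
        for chrom, s, e in _sv_intervals(row):
            grp = by_chrom.get(chrom)
            hit_gene = False
            if grp is not None:
                gmask = grp["feature"] == "gene"
                hit_gene = bool(
                    _overlaps(s, e, grp.loc[gmask, "start"].to_numpy(),
                              grp.loc[gmask, "end"].to_numpy()).any()
                )
                for feat in feature_classes:
                    fmask = grp["feature"] == feat
                    if fmask.any() and _overlaps(
                        s, e, grp.loc[fmask, "start"].to_numpy(),
                        grp.loc[fmask, "end"].to_numpy(),
                    ).any():
                        counts[feat] += 1
            counts["genic" if hit_gene else "non_genic"] += 1

    feat_bp = {
        feat: int(
            (gene_models.loc[gene_models["feature"] == feat, "end"]
             - gene_models.loc[gene_models["feature"] == feat, "start"] + 1).sum()
        )
        for feat in feature_classes
    }
    rows = []
    for region, bp in (
        [("genic", genic_bp), ("non_genic", non_genic_bp)]
        + [(f, feat_bp[f]) for f in feature_classes]
    ):
        mb = bp / 1e6
        rows.append(
            {
                "region": region,
                "raw_count": counts[region],
                "total_mb": mb,
                "adjusted_per_mb": counts[region] / mb if mb > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def load_in_sv_vs_outside(
    catalogue: pd.DataFrame,
    categories: pd.DataFrame,
    polarized: PolarizedSiteTable,
    assignment: PopulationAssignment,
    gene_models: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative load over SNPs in SV-overlapped vs SV-free genes.

    Genes are partitioned population-agnostically by any-overlap with the
    catalogue.  Per accession the del/neutr ratio is computed over SNPs
    inside each gene partition; a two-sample T-test compares the two
    per-accession distributions within each population.  Empty
    partitions yield NaN ratios and an undefined test.
    """
    genes = gene_models[gene_models["feature"] == "gene"].reset_index(drop=True)
    overlapped = np.zeros(len(genes), dtype=bool)
    for row in catalogue.itertuples(index=False):
        for chrom, s, e in _sv_intervals(row):
            sel = genes["chrom"] == chrom
            overlapped[sel.to_numpy()] |= _overlaps(
                s, e, genes.loc[sel, "start"].to_numpy(),
                genes.loc[sel, "end"].to_numpy(),
            )

    sites = polarized.sites
    in_gene = np.full(len(sites), -1, dtype=int)  # gene row index or -1
    for gi, g in genes.iterrows():
        sel = (
            (sites["chrom"] == g["chrom"])
            & (sites["pos"] >= g["start"])
            & (sites["pos"] <= g["end"])
        ).to_numpy()
        in_gene[sel] = gi
    ok = polarized.ok_mask
    cat = categories["category"].to_numpy()
    site_in_sv_gene = (in_gene >= 0) & overlapped[np.clip(in_gene, 0, None)]
    site_in_free_gene = (in_gene >= 0) & ~overlapped[np.clip(in_gene, 0, None)]

    acc_rows = []
    for j, acc in enumerate(polarized.accessions):
        dos = polarized.derived_dosage[:, j]
        vals = {}
        for label, region in (
            ("inside", site_in_sv_gene),
            ("outside", site_in_free_gene),
        ):
            d_mask = ok & region & (cat == "deleterious")
            n_mask = ok & region & (cat == "neutral_nonsynonymous")
            d = float((dos[d_mask] == 2).sum() + 0.5 * (dos[d_mask] == 1).sum())
            n = float((dos[n_mask] == 2).sum() + 0.5 * (dos[n_mask] == 1).sum())
            vals[label] = d / n if n > 0 else np.nan
        acc_rows.append(
            {
                "accession": acc,
                "population": assignment.mapping.get(acc),
                "ratio_inside": vals["inside"],
                "ratio_outside": vals["outside"],
            }
        )
    acc_df = pd.DataFrame(acc_rows)

    test_rows = []
    for pop in assignment.populations():
        sub = acc_df[acc_df["population"] == pop]
        inside = sub["ratio_inside"].dropna().to_numpy()
        outside = sub["ratio_outside"].dropna().to_numpy()
        if len(inside) >= 2 and len(outside) >= 2:
            t, p = stats.ttest_ind(inside, outside)
            t, p = float(t), float(p)
        else:
            t, p = np.nan, np.nan
        test_rows.append(
            {
                "population": pop,
                "mean_inside": float(inside.mean()) if len(inside) else np.nan,
                "mean_outside": float(outside.mean()) if len(outside) else np.nan,
                "t": t,
                "p": p,
            }
        )
    return acc_df, pd.DataFrame(test_rows)


def longread_concordance(
    short_svs: pd.DataFrame,
    long_svs: pd.DataFrame,
    max_dist: int = 100,
) -> float:
    """Fraction of short-read SVs matched one-to-one by long-read SVs.

    A match requires the same chromosome and type with both breakpoints
    within ``max_dist``; matching is greedy by total breakpoint distance.
    Returns NaN for an empty short-read set.
    """
    if len(short_svs) == 0:
        return float("nan")
    pairs = []
    for i, s in enumerate(short_svs.itertuples(index=False)):
        for j, l in enumerate(long_svs.itertuples(index=False)):
            if s.chrom != l.chrom or s.type != l.type:
                continue
            d0 = abs(s.start - l.start)
            d1 = abs(s.end - l.end)
            if d0 <= max_dist and d1 <= max_dist:
                pairs.append((d0 + d1, i, j))
    pairs.sort()
    used_s: set[int] = set()
    used_l: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_s or j in used_l:
            continue
        used_s.add(i)
        used_l.add(j)
        matched += 1
    return matched / len(short_svs)
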
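"""Windowed population statistics and the high/low partition analysis.

Windows are anchored at position 1 of each chromosome and converted
internally to half-open ``[start0, end)`` intervals; the final partial
window is retained and flagged.  Per-site diversity follows the
unbiased-heterozygosity convention ``2 j (n - j) / (n (n - 1))`` with
``j`` the derived/alt allele count over ``n`` non-missing allele calls,
and window pi divides the per-site sum by the window width in bp, i.e.
unobserved positions count as invariant (the documented downward bias
under missingness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .variant_io import (
    MISSING,
    GenotypeMatrix,
    PolarizedSiteTable,
    PopulationAssignment,
)

logger = logging.getLogger(__name__)


def _sites_and_dosage(obj) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    if isinstance(obj, PolarizedSiteTable):
        return obj.sites, obj.derived_dosage, obj.accessions
    if isinstance(obj, GenotypeMatrix):
        return obj.sites, obj.dosage, obj.accessions
    raise TypeError(f"expected PolarizedSiteTable or GenotypeMatrix, got {type(obj)}")


def make_windows(
    chrom_sizes: Mapping[str, int], width: int
) -> pd.DataFrame:
    """Tile each chromosome with fixed-width windows (last one partial)."""
    if width < 1:
        raise ConfigError("window width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        start = 0
        while start < size:
            end = min(start + width, size)
            rows.append((chrom, start, start + width, end - start < width))
            start += width
    return pd.DataFrame(rows, columns=["chrom", "start0", "end", "partial"])


def chrom_sizes_from_sites(sites: pd.DataFrame, width: int) -> dict[str, int]:
    """Infer chromosome extents from the largest observed position,
    rounded up to a whole number of windows."""
    out = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        top = int(grp["pos"].max())
        out[chrom] = ((top + width - 1) // width) * width
    return out


def _window_ids(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Index into ``windows`` for every site; -1 if outside all windows."""
    key = {
        (row.chrom, row.start0): i for i, row in enumerate(windows.itertuples(index=False))
    }
    width = int((windows["end"] - windows["start0"]).iloc[0])
    ids = np.full(len(sites), -1, dtype=int)
    pos0 = sites["pos"].to_numpy() - 1
    starts = (pos0 // width) * width
    for i, (chrom, s) in enumerate(zip(sites["chrom"].to_numpy(), starts)):
        ids[i] = key.get((chrom, int(s)), -1)
    return ids


def _per_site_pi(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site pi contribution, allele count j and call count n."""
    called = dos != MISSING
    n = 2 * called.sum(axis=1)
    j = np.where(called, dos, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n > 1, 2.0 * j * (n - j) / (n * (n - 1.0)), 0.0)
    return pi, j, n


def windowed_pi(
    data,
    assignment: PopulationAssignment,
    width: int = 10_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window, per-population nucleotide diversity.

    Returns columns chrom, start0, end, partial, population, pi,
    n_sites, missing_frac.  Windows with no called site get pi 0 and a
    missingness flag via ``missing_frac`` = 1.
    """
    sites, dosage, accessions = _sites_and_dosage(data)
    if chrom_sizes is None:
        chrom_sizes = chrom_sizes_from_sites(sites, width)
    windows = make_windows(chrom_sizes, width)
    wid = _window_ids(sites, windows)
    rows = []
    for pop in assignment.populations():
        cols = [accessions.index(a) for a in assignment.members(pop)]
        dos = dosage[:, cols]
        pi_site, _, _ = _per_site_pi(dos)
        miss_site = (dos == MISSING).mean(axis=1) if dos.size else np.array([])
        for w in range(len(windows)):
            in_w = wid == w
            n_sites = int(in_w.sum())
            pi_sum = float(pi_site[in_w].sum())
            wrow = windows.iloc[w]
            span = wrow["end"] - wrow["start0"]
            rows.append(
                {
                    "chrom": wrow["chrom"],
                    "start0": int(wrow["start0"]),
                    "end": int(wrow["end"]),
                    "partial": bool(wrow["partial"]),
                    "population": pop,
                    "pi": pi_sum / span,
                    "n_sites": n_sites,
                    "missing_frac": float(miss_site[in_w].mean()) if n_sites else 1.0,
                }
            )
    return pd.DataFrame(rows)


def tajimas_d_constants(n: int) -> dict[str, float]:
    """Standard constants for n sequences."""
    if n < 2:
        raise ConfigError("Tajima's D requires n >= 2 sequences")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(pi_sum: float, s: int, n: int) -> float:
    """D from the window pairwise-diversity sum, segregating sites and n."""
    if s == 0 or n < 2:
        return float("nan")
    k = tajimas_d_constants(n)
    denom = np.sqrt(k["e1"] * s + k["e2"] * s * (s - 1))
    if denom == 0:
        return float("nan")
    return float((pi_sum - s / k["a1"]) / denom)


def windowed_tajimas_d(
    data,
    assignment: PopulationAssignment,
    width: int = 10_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window, per-population Tajima's D.

    ``n`` is twice the minimum per-site non-missing diploid count within
    the window (conservative under missingness).  Windows with no
    segregating site are undefined (NaN), not zero.
    """
    sites, dosage, accessions = _sites_and_dosage(data)
    if chrom_sizes is None:
        chrom_sizes = chrom_sizes_from_sites(sites, width)
    windows = make_windows(chrom_sizes, width)
    wid = _window_ids(sites, windows)
    rows = []
    for pop in assignment.populations():
        cols = [accessions.index(a) for a in assignment.members(pop)]
        dos = dosage[:, cols]
        pi_site, j, n_calls = _per_site_pi(dos)
        seg = (j > 0) & (j < n_calls)
        for w in range(len(windows)):
            in_w = wid == w
            s = int((in_w & seg).sum())
            wrow = windows.iloc[w]
            if s == 0:
                d = float("nan")
            else:
                n_min = int(n_calls[in_w & seg].min())
                pi_sum = float(pi_site[in_w & seg].sum())
                d = tajimas_d(pi_sum, s, n_min)
            rows.append(
                {
                    "chrom": wrow["chrom"],
                    "start0": int(wrow["start0"]),
                    "end": int(wrow["end"]),
                    "population": pop,
                    "tajima_d": d,
                    "n_segregating": s,
                }
            )
    return pd.DataFrame(rows)


def window_relative_load(
    polarized: PolarizedSiteTable,
    categories: pd.DataFrame,
    assignment: PopulationAssignment,
    width: int = 100_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window del/neutr ratio per accession, plus population means.

    Windows with zero neutral-nonsynonymous derived sites for an
    accession are excluded for that accession (NaN); the population mean
    is over defined values only.
    """
    sites = polarized.sites
    if chrom_sizes is None:
        chrom_sizes = chrom_sizes_from_sites(sites, width)
    windows = make_windows(chrom_sizes, width)
    wid = _window_ids(sites, windows)
    ok = polarized.ok_mask
    cat = categories["category"].to_numpy()
    acc_rows = []
    for w in range(len(windows)):
        in_w = wid == w
        wrow = windows.iloc[w]
        del_mask = in_w & ok & (cat == "deleterious")
        neut_mask = in_w & ok & (cat == "neutral_nonsynonymous")
        for j, acc in enumerate(polarized.accessions):
            dos = polarized.derived_dosage[:, j]
            dcount = float(
                (dos[del_mask] == 2).sum() + 0.5 * (dos[del_mask] == 1).sum()
            )
            ncount = float(
                (dos[neut_mask] == 2).sum() + 0.5 * (dos[neut_mask] == 1).sum()
            )
            acc_rows.append(
                {
                    "chrom": wrow["chrom"],
                    "start0": int(wrow["start0"]),
                    "end": int(wrow["end"]),
                    "accession": acc,
                    "population": assignment.mapping.get(acc),
                    "ratio": dcount / ncount if ncount > 0 else np.nan,
                }
            )
    acc_df = pd.DataFrame(acc_rows)
    pop_df = (
        acc_df.groupby(["chrom", "start0", "end", "population"], sort=False)["ratio"]
        .mean()
        .reset_index()
        .rename(columns={"ratio": "mean_ratio"})
    )
    return acc_df, pop_df


# ---------------------------------------------------------------------------
# recombination and sweep attachment


def _validate_map(gmap: pd.DataFrame) -> None:
    for chrom, grp in gmap.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        cm = grp["cM"].to_numpy()
        bad = np.flatnonzero((np.diff(bp) <= 0) | (np.diff(cm) < 0))
        if len(bad):
            offenders = [
                f"{chrom}:{bp[i]}->{bp[i + 1]} ({cm[i]}->{cm[i + 1]} cM)" for i in bad
            ]
            raise ConfigError(f"non-monotone genetic map at {offenders}")
        if len(bp) < 2:
            raise ConfigError(f"chromosome {chrom} has < 2 map markers")


def _cm_at(bp: np.ndarray, mbp: np.ndarray, mcm: np.ndarray) -> np.ndarray:
    """Piecewise-linear cM(bp) with linear extrapolation beyond terminal
    markers using the nearest segment's slope."""
    cm = np.interp(bp, mbp, mcm)
    slope_lo = (mcm[1] - mcm[0]) / (mbp[1] - mbp[0])
    slope_hi = (mcm[-1] - mcm[-2]) / (mbp[-1] - mbp[-2])
    lo = bp < mbp[0]
    hi = bp > mbp[-1]
    cm[lo] = mcm[0] + (bp[lo] - mbp[0]) * slope_lo
    cm[hi] = mcm[-1] + (bp[hi] - mbp[-1]) * slope_hi
    return cm


def interpolate_recombination(
    gmap: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Attach a cM/Mb recombination rate to every window."""
    _validate_map(gmap)
    out = windows.copy()
    out["recomb_rate"] = np.nan
    for chrom, grp in gmap.groupby("chrom", sort=False):
        mbp = grp["bp"].to_numpy(dtype=float)
        mcm = grp["cM"].to_numpy(dtype=float)
        sel = out["chrom"] == chrom
        if not sel.any():
            continue
        start_bp = out.loc[sel, "start0"].to_numpy(dtype=float)
        end_bp = out.loc[sel, "end"].to_numpy(dtype=float)
        d_cm = _cm_at(end_bp, mbp, mcm) - _cm_at(start_bp, mbp, mcm)
        mb = (end_bp - start_bp) / 1e6
        out.loc[sel, "recomb_rate"] = d_cm / mb
    return out


def attach_sweep(
    sweep: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Mean sweep-grid likelihood of positions falling in each window."""
    out = windows.copy()
    vals = np.full(len(out), np.nan)
    for i, w in enumerate(out.itertuples(index=False)):
        sel = (
            (sweep["chrom"] == w.chrom)
            & (sweep["position"] > w.start0)
            & (sweep["position"] <= w.end)
        )
        if sel.any():
            vals[i] = float(sweep.loc[sel, "likelihood"].mean())
    out["sweep_stat"] = vals
    return out


# ---------------------------------------------------------------------------
# high/low partition


@dataclass
class HighLowResult:
    n_high: int
    n_low: int
    mean_load_high: float
    mean_load_low: float
    p_value: float
    verdict: str  # "s" or "n"


def partition_high_low(stat: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split windows on the statistic: top 50 % -> high.

    Ties at the cut value go to 'low'; with an odd count 'low' gets the
    extra window.  Deterministic regardless of input row order.
    """
    vals = stat.dropna()
    if len(vals) < 4:
        raise ConfigError("need >= 4 windows with a defined statistic")
    n_high = len(vals) // 2
    sorted_desc = np.sort(vals.to_numpy())[::-1]
    cutoff = sorted_desc[n_high]  # largest value that must stay low
    high = vals.index[vals > cutoff]
    low = vals.index[~vals.index.isin(high)]
    return high, low


def high_low_partition_test(
    stat: pd.Series,
    loads: pd.DataFrame,
    alpha: float = 0.05,
) -> HighLowResult:
    """Wilcoxon rank-sum between pooled per-accession loads of the two groups.

    ``stat`` is indexed by window id; ``loads`` has columns ``window``
    and ``value`` with one row per (window, accession).  Windows with an
    undefined statistic are dropped.  An all-tied statistic yields the
    verdict 'n' with a warning.
    """
    high, low = partition_high_low(stat)
    if len(high) == 0:
        logger.warning("statistic is constant; no high group")
        return HighLowResult(0, len(low), np.nan, np.nan, np.nan, "n")
    hi_vals = loads.loc[loads["window"].isin(high), "value"].dropna().to_numpy()
    lo_vals = loads.loc[loads["window"].isin(low), "value"].dropna().to_numpy()
    if len(hi_vals) == 0 or len(lo_vals) == 0:
        return HighLowResult(len(high), len(low), np.nan, np.nan, np.nan, "n")
    _, p = stats.mannwhitneyu(hi_vals, lo_vals, alternative="two-sided")
    return HighLowResult(
        n_high=len(high),
        n_low=len(low),
        mean_load_high=float(hi_vals.mean()),
        mean_load_low=float(lo_vals.mean()),
        p_value=float(p),
        verdict="s" if p < alpha else "n",
    )
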
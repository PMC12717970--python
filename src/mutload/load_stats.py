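"""Per-genome load statistics, population comparisons, SFS and private alleles.

The central counting rule: an accession's count for a category is the
number of homozygous-derived sites plus half the number of heterozygous
sites of that category ("heterozygous counts divided by two").  The
*relative mutational load* is the ratio of the deleterious count to the
neutral-nonsynonymous count; ratios with zero denominators are flagged
undefined (NaN) and dropped from comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .simulate import CATEGORIES
from .variant_io import (
    MISSING,
    PolarizedSiteTable,
    PopulationAssignment,
)

logger = logging.getLogger(__name__)

LOAD_CLASSES = ("deleterious", "neutral_nonsynonymous")


def _halved_counts(dosage: np.ndarray) -> np.ndarray:
    """hom-derived + 0.5 * het per accession (columns); missing ignored."""
    return (dosage == 2).sum(axis=0) + 0.5 * (dosage == 1).sum(axis=0)


def per_genome_counts(
    polarized: PolarizedSiteTable,
    categories: pd.DataFrame,
    assignment: PopulationAssignment,
) -> pd.DataFrame:
    """Per-accession derived-allele counts by category plus ratio statistics.

    Only sites with polarization status ``ok`` contribute.  Returns one
    row per (non-outgroup) accession with columns ``population``,
    ``count_<category>`` for each of the four categories,
    ``nonsyn_syn_ratio`` and ``del_neutr_ratio`` (NaN when the
    denominator is zero).
    """
    unassigned = [a for a in polarized.accessions if a not in assignment.mapping]
    if unassigned:
        raise ConfigError(f"accessions without population assignment: {unassigned}")
    ok = polarized.ok_mask
    cat = categories["category"].to_numpy()
    rows: dict[str, np.ndarray] = {}
    for c in CATEGORIES:
        mask = ok & (cat == c)
        rows[f"count_{c}"] = _halved_counts(polarized.derived_dosage[mask])
    out = pd.DataFrame(rows, index=pd.Index(polarized.accessions, name="accession"))
    out.insert(0, "population", [assignment.mapping[a] for a in out.index])
    nonsyn = out["count_neutral_nonsynonymous"] + out["count_deleterious"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nonsyn_syn_ratio"] = np.where(
            out["count_synonymous"] > 0, nonsyn / out["count_synonymous"], np.nan
        )
        out["del_neutr_ratio"] = np.where(
            out["count_neutral_nonsynonymous"] > 0,
            out["count_deleterious"] / out["count_neutral_nonsynonymous"],
            np.nan,
        )
    return out.reset_index()


# ---------------------------------------------------------------------------
# population comparisons


def dunn_test(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests with tie correction.

    Returns one row per population pair with the z statistic, raw
    two-sided p and Bonferroni-adjusted p (multiplied by the number of
    pairs, capped at 1).
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    offset = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[offset : offset + len(v)].mean()
        offset += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_factor * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "z": z,
                "p_raw": p,
                "p_adj": min(1.0, p * n_pairs) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compact_letter_display(
    order: Sequence[str], significant: Mapping[frozenset, bool]
) -> dict[str, str]:
    """Letters such that groups sharing a letter are not significantly different.

    ``order`` fixes letter precedence (typically populations sorted by
    mean value).  Implemented as a clique cover of the
    not-significantly-different graph.
    """
    g = nx.Graph()
    g.add_nodes_from(order)
    for a, b in combinations(order, 2):
        if not significant.get(frozenset((a, b)), False):
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    pos = {p: i for i, p in enumerate(order)}
    cliques.sort(key=lambda c: (min(pos[p] for p in c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {p: [] for p in order}
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)]
        for p in clique:
            letters[p].append(letter)
    return {p: "".join(sorted(ls)) for p, ls in letters.items()}


@dataclass
class PopulationComparison:
    statistic: float
    p_value: float
    dunn: pd.DataFrame
    letters: dict[str, str]
    excluded: list[str]


def compare_populations(
    values: Mapping[str, float] | pd.Series,
    assignment: PopulationAssignment,
    alpha: float = 0.05,
) -> PopulationComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise tests with Bonferroni.

    ``values`` maps accession to a statistic (NaN entries dropped).
    Populations with fewer than two usable values are excluded with a
    warning.  The compact-letter display assigns shared letters to
    populations whose Bonferroni-adjusted Dunn p is above ``alpha``.
    """
    series = pd.Series(values, dtype=float).dropna()
    groups: dict[str, np.ndarray] = {}
    excluded = []
    for pop in assignment.populations():
        members = [a for a in assignment.members(pop) if a in series.index]
        vals = series.loc[members].to_numpy()
        if len(vals) < 2:
            excluded.append(pop)
            logger.warning("population %r excluded from comparison (<2 values)", pop)
            continue
        groups[pop] = vals
    if len(groups) < 2:
        raise ConfigError("need at least two populations with >= 2 accessions")
    h, p = stats.kruskal(*groups.values())
    dunn = dunn_test(groups)
    sig = {
        frozenset((r.pop_a, r.pop_b)): bool(r.p_adj < alpha)
        for r in dunn.itertuples(index=False)
    }
    order = sorted(groups, key=lambda g: -np.mean(groups[g]))
    letters = compact_letter_display(order, sig)
    return PopulationComparison(
        statistic=float(h), p_value=float(p), dunn=dunn, letters=letters,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# site-frequency spectra


def population_daf(
    polarized: PolarizedSiteTable, assignment: PopulationAssignment
) -> pd.DataFrame:
    """Per-site derived-allele frequency per population (NaN if all missing)."""
    out = {}
    for pop in assignment.populations():
        idx = [polarized.accessions.index(a) for a in assignment.members(pop)]
        dos = polarized.derived_dosage[:, idx].astype(float)
        dos[dos == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            out[pop] = np.nanmean(dos, axis=1) / 2.0
    return pd.DataFrame(out)


def sfs_bin(daf: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Left-open right-closed frequency bins over (0, 1]; DAF 0 excluded."""
    daf = daf[np.isfinite(daf) & (daf > 0)]
    idx = np.minimum(np.ceil(daf * n_bins).astype(int), n_bins)
    return np.bincount(idx, minlength=n_bins + 1)[1:]


@dataclass
class SFSResult:
    #: long frame: population, cls, bin_low, bin_high, count
    spectra: pd.DataFrame
    #: per population: adaf per class, KS statistic/p, verdict
    comparisons: pd.DataFrame


def sfs_and_adaf(
    polarized: PolarizedSiteTable,
    categories: pd.DataFrame,
    assignment: PopulationAssignment,
    classes: Sequence[str] = LOAD_CLASSES,
    alpha: float = 0.05,
    n_bins: int = 10,
) -> SFSResult:
    """Binned derived-allele-frequency spectra and ADAF comparison per population.

    ADAF is the mean DAF over segregating sites (DAF > 0, fixed-derived
    included).  The verdict compares the deleterious and
    neutral-nonsynonymous DAF distributions: ``D<N``/``D>N`` when the
    two-sample KS test is significant at ``alpha``, ``D~N`` otherwise,
    ``undefined`` when either class has no segregating site.
    """
    ok = polarized.ok_mask
    cat = categories["category"].to_numpy()
    daf = population_daf(polarized, assignment)
    spec_rows = []
    comp_rows = []
    edges = np.linspace(0, 1, n_bins + 1)
    for pop in assignment.populations():
        freqs = daf[pop].to_numpy()
        lists = {}
        for cls in classes:
            vals = freqs[ok & (cat == cls)]
            vals = vals[np.isfinite(vals) & (vals > 0)]
            lists[cls] = vals
            counts = sfs_bin(freqs[ok & (cat == cls)], n_bins)
            for b in range(n_bins):
                spec_rows.append(
                    {
                        "population": pop,
                        "cls": cls,
                        "bin_low": edges[b],
                        "bin_high": edges[b + 1],
                        "count": int(counts[b]),
                    }
                )
        d = lists.get("deleterious", np.array([]))
        n = lists.get("neutral_nonsynonymous", np.array([]))
        if len(d) == 0 or len(n) == 0:
            comp_rows.append(
                {
                    "population": pop,
                    "adaf_deleterious": np.nan,
                    "adaf_neutral_nonsynonymous": np.nan,
                    "ks_stat": np.nan,
                    "ks_p": np.nan,
                    "verdict": "undefined",
                }
            )
            continue
        if np.array_equal(np.sort(d), np.sort(n)):
            ks_stat, ks_p = 0.0, 1.0
        else:
            ks_stat, ks_p = stats.ks_2samp(d, n, method="asymp")
        adaf_d, adaf_n = float(d.mean()), float(n.mean())
        if ks_p < alpha and adaf_d < adaf_n:
            verdict = "D<N"
        elif ks_p < alpha and adaf_d > adaf_n:
            verdict = "D>N"
        else:
            verdict = "D~N"
        comp_rows.append(
            {
                "population": pop,
                "adaf_deleterious": adaf_d,
                "adaf_neutral_nonsynonymous": adaf_n,
                "ks_stat": float(ks_stat),
                "ks_p": float(ks_p),
                "verdict": verdict,
            }
        )
    return SFSResult(
        spectra=pd.DataFrame(spec_rows), comparisons=pd.DataFrame(comp_rows)
    )


# ---------------------------------------------------------------------------
# private alleles


@dataclass
class PrivateAlleleReport:
    #: (population, cls) -> site row indices private to that population
    private_sites: dict[tuple[str, str], np.ndarray]
    #: per accession and class: private/all counts and proportions, both
    #: for sites the accession itself carries and for its population
    accession_table: pd.DataFrame
    #: per population and class: mean DAF of private vs shared sites
    population_table: pd.DataFrame
    #: per population: T-test of private vs shared del/neutr ratios
    ttests: pd.DataFrame


def private_alleles(
    polarized: PolarizedSiteTable,
    categories: pd.DataFrame,
    assignment: PopulationAssignment,
    classes: Sequence[str] = LOAD_CLASSES,
) -> PrivateAlleleReport:
    """Private-allele accounting per the one-population rule.

    A site is private to population P when its derived-allele frequency
    is > 0 in P and exactly 0 in every other population; it is therefore
    private to at most one population.
    """
    pops = assignment.populations()
    if len(pops) < 2:
        raise ConfigError("private alleles need >= 2 populations")
    ok = polarized.ok_mask
    cat = categories["category"].to_numpy()
    daf = population_daf(polarized, assignment)
    seg = {p: (daf[p].to_numpy() > 0) & ok for p in pops}

    private: dict[tuple[str, str], np.ndarray] = {}
    pop_rows = []
    for pop in pops:
        others = [q for q in pops if q != pop]
        priv_mask = seg[pop].copy()
        for q in others:
            priv_mask &= ~seg[q]
        for cls in classes:
            cls_mask = cat == cls
            private[(pop, cls)] = np.flatnonzero(priv_mask & cls_mask)
            shared_mask = seg[pop] & ~priv_mask & cls_mask
            freqs = daf[pop].to_numpy()
            priv_daf = freqs[priv_mask & cls_mask]
            shared_daf = freqs[shared_mask]
            pop_rows.append(
                {
                    "population": pop,
                    "cls": cls,
                    "n_private": int((priv_mask & cls_mask).sum()),
                    "n_segregating": int((seg[pop] & cls_mask).sum()),
                    "mean_daf_private": float(priv_daf.mean()) if len(priv_daf) else np.nan,
                    "mean_daf_shared": float(shared_daf.mean()) if len(shared_daf) else np.nan,
                }
            )

    acc_rows = []
    ratio_rows = {p: {"private": [], "shared": []} for p in pops}
    for pop in pops:
        others = [q for q in pops if q != pop]
        priv_mask_all = seg[pop].copy()
        for q in others:
            priv_mask_all &= ~seg[q]
        for acc in assignment.members(pop):
            j = polarized.accessions.index(acc)
            dos = polarized.derived_dosage[:, j]
            carried = _halved_site_vector(dos)
            per_class = {}
            for cls in classes:
                cls_mask = ok & (cat == cls)
                n_all = carried[cls_mask].sum()
                n_priv = carried[cls_mask & priv_mask_all].sum()
                n_all_pop = int((seg[pop] & cls_mask).sum())
                n_priv_pop = int((priv_mask_all & cls_mask).sum())
                per_class[cls] = (n_priv, n_all)
                acc_rows.append(
                    {
                        "accession": acc,
                        "population": pop,
                        "cls": cls,
                        "n_private_carried": float(n_priv),
                        "n_all_carried": float(n_all),
                        "priv_frac_carried": n_priv / n_all if n_all > 0 else np.nan,
                        "n_private_population": n_priv_pop,
                        "n_all_population": n_all_pop,
                        "priv_frac_population": (
                            n_priv_pop / n_all_pop if n_all_pop > 0 else np.nan
                        ),
                    }
                )
            # del/neutr ratio among private vs shared carried sites
            for which, mask_extra in (
                ("private", priv_mask_all),
                ("shared", seg[pop] & ~priv_mask_all),
            ):
                d = carried[ok & (cat == "deleterious") & mask_extra].sum()
                n = carried[ok & (cat == "neutral_nonsynonymous") & mask_extra].sum()
                ratio_rows[pop][which].append(d / n if n > 0 else np.nan)

    ttest_rows = []
    for pop in pops:
        priv = np.asarray(ratio_rows[pop]["private"], dtype=float)
        shar = np.asarray(ratio_rows[pop]["shared"], dtype=float)
        priv = priv[np.isfinite(priv)]
        shar = shar[np.isfinite(shar)]
        if len(priv) >= 2 and len(shar) >= 2:
            t, p = stats.ttest_ind(priv, shar)
        else:
            t, p = np.nan, np.nan
        ttest_rows.append(
            {
                "population": pop,
                "mean_private_ratio": float(priv.mean()) if len(priv) else np.nan,
                "mean_shared_ratio": float(shar.mean()) if len(shar) else np.nan,
                "t": float(t) if np.isfinite(t) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
            }
        )

    return PrivateAlleleReport(
        private_sites=private,
        accession_table=pd.DataFrame(acc_rows),
        population_table=pd.DataFrame(pop_rows),
        ttests=pd.DataFrame(ttest_rows),
    )


def _halved_site_vector(dosage_col: np.ndarray) -> np.ndarray:
    """Per-site contribution of one accession: 1 for hom, 0.5 for het."""
    out = np.zeros(len(dosage_col))
    out[dosage_col == 2] = 1.0
    out[dosage_col == 1] = 0.5
    return out


# ---------------------------------------------------------------------------
# genotype-frequency tables


def genotype_frequency_table(
    polarized: PolarizedSiteTable,
    assignment: PopulationAssignment,
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site, per-population frequencies of hom-derived / het / hom-ancestral.

    Frequencies are over non-missing accessions and sum to 1 per row.
    ``site_mask`` restricts the rows (default: all ok sites).
    """
    if site_mask is None:
        site_mask = polarized.ok_mask
    idx = np.flatnonzero(site_mask)
    rows = []
    for pop in assignment.populations():
        cols = [polarized.accessions.index(a) for a in assignment.members(pop)]
        dos = polarized.derived_dosage[np.ix_(idx, cols)]
        called = (dos != MISSING).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f2 = (dos == 2).sum(axis=1) / called
            f1 = (dos == 1).sum(axis=1) / called
            f0 = (dos == 0).sum(axis=1) / called
        sites = polarized.sites.iloc[idx]
        for k in range(len(idx)):
            rows.append(
                {
                    "chrom": sites.iloc[k]["chrom"],
                    "pos": sites.iloc[k]["pos"],
                    "population": pop,
                    "freq_hom_derived": f2[k],
                    "freq_het": f1[k],
                    "freq_hom_ancestral": f0[k],
                }
            )
    return pd.DataFrame(rows)
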
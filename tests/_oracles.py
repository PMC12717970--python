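"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written along a different code path from
the package (enumeration, haplotype expansion, transitive closure via
networkx, a per-site binomial Wright-Fisher sampler) so agreement is a
meaningful check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm


def halved_count(dosages) -> float:
    """Per-genome derived-site count by direct genotype enumeration."""
    total = 0.0
    for d in dosages:
        if d == 2:
            total += 1.0
        elif d == 1:
            total += 0.5
    return total


def pairwise_pi(dosage_matrix: np.ndarray) -> float:
    """Mean pairwise difference summed over sites via explicit haplotypes.

    Each diploid contributes two haplotypes; a heterozygote contributes
    one ancestral and one derived copy.  Missing dosages (-1) drop the
    individual at that site.
    """
    total = 0.0
    for row in dosage_matrix:
        haps = []
        for d in row:
            if d < 0:
                continue
            if d == 0:
                haps += [0, 0]
            elif d == 1:
                haps += [0, 1]
            else:
                haps += [1, 1]
        pairs = list(combinations(haps, 2))
        if not pairs:
            continue
        diffs = sum(1 for a, b in pairs if a != b)
        total += diffs / len(pairs)
    return total


def tajimas_d_textbook(allele_counts: list[int], n: int) -> float:
    """Textbook Tajima's D from per-site derived counts at n sequences."""
    s = sum(1 for j in allele_counts if 0 < j < n)
    if s == 0:
        return float("nan")
    pi = sum(
        j * (n - j) / (n * (n - 1) / 2.0) for j in allele_counts if 0 < j < n
    )
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def wf_single_site(
    q0: float, n_dip: int, s: float, h: float, generations: int,
    rng: np.random.Generator,
) -> float:
    """Independent one-locus Wright-Fisher sampler with viability selection."""
    q = q0
    for _ in range(generations):
        p = 1 - q
        w_bar = p * p + 2 * p * q * (1 + h * s) + q * q * (1 + s)
        if w_bar <= 0:
            return q
        q_sel = (p * q * (1 + h * s) + q * q * (1 + s)) / w_bar
        q = rng.binomial(2 * n_dip, q_sel) / (2 * n_dip)
        if q in (0.0, 1.0):
            # absorbing without mutation
            return q
    return q


def brute_force_clusters(
    df: pd.DataFrame, max_dist: int, min_overlap: float
) -> set[frozenset]:
    """Transitive closure of pairwise SV compatibility via a graph."""
    g = nx.Graph()
    g.add_nodes_from(df.index)
    for i, j in combinations(df.index, 2):
        a, b = df.loc[i], df.loc[j]
        if a["chrom"] != b["chrom"] or a["type"] != b["type"]:
            continue
        if a["type"] == "TRA":
            ok = (
                abs(a["start"] - b["start"]) <= max_dist
                and abs(a["end"] - b["end"]) <= max_dist
            )
        else:
            la = a["end"] - a["start"] + 1
            lb = b["end"] - b["start"] + 1
            ok = (
                abs(a["start"] - b["start"]) <= max_dist
                and min(la, lb) / max(la, lb) >= min_overlap
            )
        if ok:
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def dunn_reference(groups: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Independent Dunn z-test p-values (raw, two-sided) via pandas ranking."""
    frame = pd.DataFrame(
        [(g, v) for g, vals in groups.items() for v in vals],
        columns=["group", "value"],
    )
    frame["rank"] = frame["value"].rank(method="average")
    n = len(frame)
    tie_sizes = frame["value"].value_counts()
    correction = float(((tie_sizes**3 - tie_sizes).sum()) / (12 * (n - 1)))
    a = n * (n + 1) / 12.0 - correction
    out = {}
    for g1, g2 in combinations(groups, 2):
        r1 = frame.loc[frame["group"] == g1, "rank"].mean()
        r2 = frame.loc[frame["group"] == g2, "rank"].mean()
        n1 = len(groups[g1])
        n2 = len(groups[g2])
        z = (r1 - r2) / np.sqrt(a * (1 / n1 + 1 / n2))
        out[(g1, g2)] = float(2 * norm.sf(abs(z)))
    return out


def private_sets(
    daf_by_pop: dict[str, np.ndarray],
) -> dict[str, set[int]]:
    """Brute-force private-site set algebra."""
    pops = list(daf_by_pop)
    out: dict[str, set[int]] = {p: set() for p in pops}
    n_sites = len(next(iter(daf_by_pop.values())))
    for i in range(n_sites):
        present = [p for p in pops if daf_by_pop[p][i] > 0]
        if len(present) == 1:
            out[present[0]].add(i)
    return out
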
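"""Forward population simulator and synthetic-input generators.

The simulator is an individual-based diploid Wright--Fisher model with
four site categories (non-coding, synonymous, neutral-nonsynonymous,
deleterious), multiplicative fitness across deleterious sites with
per-site genotype factors ``{1, 1+h*s, 1+s}``, partial selfing, and a
demography of resizable populations connected by founder-sampling
splits.  It produces every input the analysis pipeline consumes:

* a multi-sample VCF (plus an outgroup fixed homozygous ancestral),
* SIFT-style and PROVEAN-style annotation tables with truth labels,
* GFF3-like gene models and a genetic map,
* a mock sweep-statistic grid,
* three jittered/incomplete mock SV-caller call sets over planted SVs.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the config, so identical configs give byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError

CATEGORIES = (
    "non_coding",
    "synonymous",
    "neutral_nonsynonymous",
    "deleterious",
)

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

_BASES = np.array(["A", "C", "G", "T"])

SIFT_DELETERIOUS = "DELETERIOUS"
SIFT_DELETERIOUS_LOWCONF = "DELETERIOUS (*WARNING! Low confidence)"
SIFT_TOLERATED = "TOLERATED"

# Score ranges used when emitting PROVEAN-style annotations.  Only the
# position of each range relative to the -2.5 decision threshold matters.
_PROVEAN_DELETERIOUS_RANGE = (-6.0, -2.6)
_PROVEAN_NEUTRAL_RANGE = (-2.4, 2.0)


@dataclass(frozen=True)
class DemographyEpoch:
    """One constant-size interval of a population's history.

    ``start_gen`` is the generation at which ``N`` takes effect.  A
    population's first epoch may name ``source_pop``, in which case the
    population is founded at ``start_gen`` by sampling ``N`` diploid
    founders with replacement from the source.
    """

    start_gen: int
    N: int
    source_pop: str | None = None


@dataclass
class SimConfig:
    """Full configuration of a forward simulation run."""

    seed: int
    epochs: Mapping[str, Sequence[DemographyEpoch]]
    n_generations: int = 200
    n_sites: int = 1000
    chrom_length: int = 1_000_000
    n_chromosomes: int = 10
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "non_coding": 0.55,
            "synonymous": 0.20,
            "neutral_nonsynonymous": 0.15,
            "deleterious": 0.10,
        }
    )
    sel_coeff: float = -0.02
    dominance: float = 0.5
    mut_rate: float = 1e-4
    init_freq: float = 0.05
    #: per-adjacent-site recombination probability within a chromosome;
    #: 0.5 means free recombination everywhere (the fast path).
    recomb_rate: float = 0.5
    selfing_rate: Mapping[str, float] = field(default_factory=dict)
    n_sampled: Mapping[str, int] = field(default_factory=dict)
    outgroup_name: str = "outgroup"

    def validate(self) -> None:
        props = dict(self.category_proportions)
        if set(props) != set(CATEGORIES):
            raise ConfigError(
                f"category_proportions must have keys {CATEGORIES}, got {sorted(props)}"
            )
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"category_proportions sum to {total}, expected 1")
        if any(p < 0 for p in props.values()):
            raise ConfigError("category proportions must be non-negative")
        for name, rate in [
            ("mut_rate", self.mut_rate),
            ("init_freq", self.init_freq),
            ("recomb_rate", self.recomb_rate),
            ("dominance", self.dominance),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}={rate} outside [0, 1]")
        if self.sel_coeff > 0:
            raise ConfigError("sel_coeff must be <= 0 for the deleterious class")
        if self.n_sites < 1 or self.n_generations < 0:
            raise ConfigError("n_sites and n_generations must be positive")
        if not self.epochs:
            raise ConfigError("at least one population required")
        n_roots = 0
        for pop, eps in self.epochs.items():
            if not eps:
                raise ConfigError(f"population {pop!r} has no epochs")
            starts = [e.start_gen for e in eps]
            if starts != sorted(set(starts)):
                raise ConfigError(f"epochs of {pop!r} must be ordered and non-overlapping")
            if any(e.N < 2 for e in eps):
                raise ConfigError(f"population {pop!r} has an epoch with N < 2")
            if any(e.source_pop is not None for e in eps[1:]):
                raise ConfigError(f"only the first epoch of {pop!r} may name a source")
            if eps[0].source_pop is None:
                if eps[0].start_gen != 0:
                    raise ConfigError(f"root population {pop!r} must start at generation 0")
                n_roots += 1
            else:
                if eps[0].source_pop not in self.epochs:
                    raise ConfigError(
                        f"{pop!r} splits from unknown population {eps[0].source_pop!r}"
                    )
                if eps[0].start_gen < 1:
                    raise ConfigError(f"split population {pop!r} must start at generation >= 1")
        if n_roots == 0:
            raise ConfigError("no root population (first epoch without source_pop)")
        for pop in self.epochs:
            rate = self.selfing_rate.get(pop, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"selfing_rate[{pop!r}]={rate} outside [0, 1]")
            n_s = self.n_sampled.get(pop, 0)
            final_n = self.epochs[pop][-1].N
            if n_s > final_n:
                raise ConfigError(
                    f"n_sampled[{pop!r}]={n_s} exceeds final population size {final_n}"
                )

    def pop_size_at(self, pop: str, gen: int) -> int:
        n = self.epochs[pop][0].N
        for e in self.epochs[pop]:
            if e.start_gen <= gen:
                n = e.N
        return n


@dataclass
class SimResult:
    """Output of :func:`simulate_populations`."""

    config: SimConfig
    #: population -> (n_sampled, n_sites) derived-allele dosage matrix
    populations: dict[str, np.ndarray]
    #: outgroup dosages, all zero by construction
    outgroup: np.ndarray
    #: per-site truth: site_id, chrom, pos, ref, alt, true_category,
    #: sift_label, provean_score
    truth: pd.DataFrame

    @property
    def accession_names(self) -> dict[str, list[str]]:
        return {
            pop: [f"{pop}_{i:03d}" for i in range(mat.shape[0])]
            for pop, mat in self.populations.items()
        }


def _site_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Scatter sites over equally sized chromosomes, sorted by position."""
    n_chrom = config.n_chromosomes
    base, extra = divmod(config.n_sites, n_chrom)
    frames = []
    for c in range(n_chrom):
        k = base + (1 if c < extra else 0)
        if k == 0:
            continue
        if k > config.chrom_length:
            raise ConfigError("more sites than positions on a chromosome")
        pos = np.sort(rng.choice(config.chrom_length, size=k, replace=False)) + 1
        frames.append(pd.DataFrame({"chrom": f"chr{c + 1:02d}", "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    ref_idx = rng.integers(0, 4, size=len(sites))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(sites))) % 4
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[alt_idx]
    return sites


def _assign_categories(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic per-category counts, shuffled over site indices."""
    props = config.category_proportions
    counts = {c: int(math.floor(props[c] * config.n_sites)) for c in CATEGORIES}
    short = config.n_sites - sum(counts.values())
    # distribute rounding remainder by descending fractional part
    fracs = sorted(
        CATEGORIES,
        key=lambda c: props[c] * config.n_sites - counts[c],
        reverse=True,
    )
    for c in fracs[:short]:
        counts[c] += 1
    labels = np.repeat(
        np.arange(len(CATEGORIES)), [counts[c] for c in CATEGORIES]
    )
    rng.shuffle(labels)
    return labels


def _annotation_truth(
    categories: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw SIFT-style labels and PROVEAN-style scores consistent with truth.

    A fraction of neutral-nonsynonymous sites receive a deleterious SIFT
    label but a PROVEAN score above the threshold, exercising the
    intersection rule downstream.
    """
    n = len(categories)
    labels = np.full(n, "NA", dtype=object)
    scores = np.full(n, np.nan)
    del_mask = categories == CATEGORIES.index("deleterious")
    neut_mask = categories == CATEGORIES.index("neutral_nonsynonymous")
    n_del = int(del_mask.sum())
    n_neut = int(neut_mask.sum())
    if n_del:
        lowconf = rng.random(n_del) < 0.3
        labels[del_mask] = np.where(lowconf, SIFT_DELETERIOUS_LOWCONF, SIFT_DELETERIOUS)
        scores[del_mask] = rng.uniform(*_PROVEAN_DELETERIOUS_RANGE, size=n_del)
    if n_neut:
        sift_disagrees = rng.random(n_neut) < 0.15
        labels[neut_mask] = np.where(sift_disagrees, SIFT_DELETERIOUS, SIFT_TOLERATED)
        scores[neut_mask] = rng.uniform(*_PROVEAN_NEUTRAL_RANGE, size=n_neut)
    return labels, scores


def _switch_probabilities(config: SimConfig, sites: pd.DataFrame) -> np.ndarray | None:
    """Per-site haplotype-switch probability for gamete formation.

    ``None`` signals free recombination everywhere (fast path).  The
    first site overall and the first site of each chromosome switch with
    probability 0.5; adjacent within-chromosome sites switch at
    ``recomb_rate``.
    """
    if config.recomb_rate == 0.5:
        return None
    p = np.full(len(sites), config.recomb_rate)
    chrom = sites["chrom"].to_numpy()
    new_chrom = np.ones(len(sites), dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    p[new_chrom] = 0.5
    return p


def _gametes(
    haps: np.ndarray,
    parents: np.ndarray,
    switch_p: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    a = haps[2 * parents]
    b = haps[2 * parents + 1]
    if switch_p is None:
        mask = rng.integers(0, 2, size=a.shape, dtype=np.uint8).astype(bool)
    else:
        mask = np.bitwise_xor.accumulate(rng.random(a.shape) < switch_p, axis=1)
    return np.where(mask, a, b)


def _next_generation(
    haps: np.ndarray,
    n_children: int,
    del_cols: np.ndarray,
    s: float,
    h: float,
    selfing: float,
    switch_p: np.ndarray | None,
    mut_rate: float,
    rng: np.random.Generator,
    gen: int,
    pop: str,
) -> np.ndarray:
    n_par = haps.shape[0] // 2
    if del_cols.size and s != 0.0:
        g = haps[0::2][:, del_cols].astype(np.int8) + haps[1::2][:, del_cols]
        n_het = (g == 1).sum(axis=1)
        n_hom = (g == 2).sum(axis=1)
        lw_het = np.log1p(h * s) if 1 + h * s > 0 else -np.inf
        lw_hom = np.log1p(s) if 1 + s > 0 else -np.inf
        logw = n_het * lw_het + n_hom * lw_hom
        top = logw.max()
        if not np.isfinite(top):
            raise SimulationError(
                f"population {pop!r} went extinct (all fitness 0) at generation {gen}",
                generation=gen,
            )
        w = np.exp(logw - top)
        cw = np.cumsum(w)
    else:
        cw = np.arange(1, n_par + 1, dtype=float)
    total = cw[-1]
    dads = np.searchsorted(cw, rng.random(n_children) * total, side="right")
    moms = np.searchsorted(cw, rng.random(n_children) * total, side="right")
    if selfing > 0:
        selfed = rng.random(n_children) < selfing
        moms[selfed] = dads[selfed]
    children = np.empty((2 * n_children, haps.shape[1]), dtype=np.uint8)
    children[0::2] = _gametes(haps, dads, switch_p, rng)
    children[1::2] = _gametes(haps, moms, switch_p, rng)
    if mut_rate > 0:
        n_mut = rng.binomial(children.size, mut_rate)
        if n_mut:
            flat = children.reshape(-1)
            idx = rng.integers(0, flat.size, size=n_mut)
            flat[idx] = 1  # derived-only mutation, no back mutation
    return children


def simulate_populations(config: SimConfig) -> SimResult:
    """Run the forward simulation and sample genotypes per population.

    Returns dosage matrices for ``n_sampled`` diploid accessions per
    population, an all-ancestral outgroup, and the truth annotation
    table.  Raises :class:`SimulationError` naming the generation if a
    population's fitness collapses to zero everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = _site_positions(config, rng)
    categories = _assign_categories(config, rng)
    labels, scores = _annotation_truth(categories, rng)
    del_cols = np.flatnonzero(categories == CATEGORIES.index("deleterious"))
    switch_p = _switch_probabilities(config, sites)

    active: dict[str, np.ndarray] = {}
    for pop, eps in config.epochs.items():
        if eps[0].source_pop is None:
            n0 = eps[0].N
            active[pop] = (
                rng.random((2 * n0, config.n_sites)) < config.init_freq
            ).astype(np.uint8)

    for gen in range(1, config.n_generations + 1):
        for pop in config.epochs:
            if pop not in active:
                continue
            active[pop] = _next_generation(
                active[pop],
                config.pop_size_at(pop, gen),
                del_cols,
                config.sel_coeff,
                config.dominance,
                config.selfing_rate.get(pop, 0.0),
                switch_p,
                config.mut_rate,
                rng,
                gen,
                pop,
            )
        for pop, eps in config.epochs.items():
            if pop in active or eps[0].start_gen != gen:
                continue
            src = active[eps[0].source_pop]
            founders = rng.integers(0, src.shape[0] // 2, size=eps[0].N)
            haps = np.empty((2 * eps[0].N, config.n_sites), dtype=np.uint8)
            haps[0::2] = src[2 * founders]
            haps[1::2] = src[2 * founders + 1]
            active[pop] = haps

    missing = [p for p in config.epochs if p not in active]
    if missing:
        raise ConfigError(
            f"populations never founded within n_generations: {missing} "
            "(split start_gen exceeds n_generations?)"
        )

    sampled: dict[str, np.ndarray] = {}
    for pop in config.epochs:
        n_s = config.n_sampled.get(pop, 0)
        if n_s == 0:
            continue
        n_ind = active[pop].shape[0] // 2
        pick = rng.choice(n_ind, size=n_s, replace=False)
        sampled[pop] = (
            active[pop][2 * pick].astype(np.int16) + active[pop][2 * pick + 1]
        )

    truth = sites.copy()
    truth.insert(0, "site_id", [f"s{i:06d}" for i in range(len(sites))])
    truth["true_category"] = [CATEGORIES[c] for c in categories]
    truth["sift_label"] = labels
    truth["provean_score"] = scores
    return SimResult(
        config=config,
        populations=sampled,
        outgroup=np.zeros(config.n_sites, dtype=np.int16),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# annotation-table emission


def emit_annotation_tables(
    truth: pd.DataFrame,
    miscls_rate: float,
    seed: int,
    sift_path: str | Path,
    provean_path: str | Path,
) -> pd.DataFrame:
    """Write SIFT-style and PROVEAN-style TSVs from a truth table.

    With ``miscls_rate`` m, exactly ``floor(m * n_nonsynonymous)`` sites
    (seeded choice) have their emitted annotation swapped to the other
    nonsynonymous class, flipping both the SIFT label and the PROVEAN
    score range so the decoded class differs from truth at exactly those
    sites.  Returns the emitted (possibly swapped) annotation frame.
    """
    if not 0.0 <= miscls_rate < 1.0:
        raise ConfigError(f"miscls_rate={miscls_rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    emitted = truth.copy()
    nonsyn = emitted["true_category"].isin(
        ["neutral_nonsynonymous", "deleterious"]
    )
    nonsyn_idx = np.flatnonzero(nonsyn.to_numpy())
    n_swap = int(math.floor(miscls_rate * len(nonsyn_idx)))
    if n_swap:
        chosen = rng.choice(nonsyn_idx, size=n_swap, replace=False)
        for i in chosen:
            if emitted.at[i, "true_category"] == "deleterious":
                emitted.at[i, "sift_label"] = SIFT_TOLERATED
                emitted.at[i, "provean_score"] = rng.uniform(*_PROVEAN_NEUTRAL_RANGE)
            else:
                emitted.at[i, "sift_label"] = SIFT_DELETERIOUS
                emitted.at[i, "provean_score"] = rng.uniform(*_PROVEAN_DELETERIOUS_RANGE)

    coding = emitted[
        emitted["true_category"].isin(
            ["synonymous", "neutral_nonsynonymous", "deleterious"]
        )
    ]
    sift = pd.DataFrame(
        {
            "chrom": coding["chrom"],
            "pos": coding["pos"],
            "ref": coding["ref"],
            "alt": coding["alt"],
            "region": "CDS",
            "substitution": np.where(
                coding["true_category"] == "synonymous",
                "SYNONYMOUS",
                "NONSYNONYMOUS",
            ),
            "label": coding["sift_label"],
        }
    )
    sift.to_csv(sift_path, sep="\t", index=False)
    nonsyn_emitted = coding[coding["true_category"] != "synonymous"]
    provean = pd.DataFrame(
        {
            "chrom": nonsyn_emitted["chrom"],
            "pos": nonsyn_emitted["pos"],
            "score": nonsyn_emitted["provean_score"].round(6),
        }
    )
    provean.to_csv(provean_path, sep="\t", index=False)
    return emitted


# ---------------------------------------------------------------------------
# gene models, genetic map, sweep grid


def generate_gene_models(
    n_genes: int,
    seed: int,
    *,
    chrom_names: Sequence[str] = ("chr01",),
    chrom_length: int = 1_000_000,
    n_exons: tuple[int, int] = (1, 4),
    exon_len: tuple[int, int] = (100, 400),
    intron_len: tuple[int, int] = (80, 300),
    utr_len: tuple[int, int] = (100, 250),
    gap: tuple[int, int] = (200, 800),
) -> pd.DataFrame:
    """Lay out non-overlapping genes with contiguous UTR/exon/intron parts.

    Each gene is 5'UTR, exon, (intron, exon)*, 3'UTR with no internal
    gaps.  Raises :class:`ConfigError` if the geometry does not fit on
    the given chromosomes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cursors = {c: 1 for c in chrom_names}
    chroms = list(chrom_names)
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        start = cursors[chrom] + int(rng.integers(*gap))
        gene_id = f"gene{g + 1:04d}"
        parts: list[tuple[str, int]] = [("five_prime_UTR", int(rng.integers(*utr_len)))]
        k_ex = int(rng.integers(n_exons[0], n_exons[1] + 1))
        for e in range(k_ex):
            if e:
                parts.append(("intron", int(rng.integers(*intron_len))))
            parts.append(("exon", int(rng.integers(*exon_len))))
        parts.append(("three_prime_UTR", int(rng.integers(*utr_len))))
        cur = start
        feat_rows = []
        for feat, length in parts:
            feat_rows.append((chrom, cur, cur + length - 1, feat, gene_id))
            cur += length
        end = cur - 1
        if end > chrom_length:
            raise ConfigError(
                f"gene layout exceeds chromosome length at {gene_id} on {chrom}"
            )
        rows.append((chrom, start, end, "gene", gene_id))
        rows.extend(feat_rows)
        cursors[chrom] = end + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "gene_id"])


def write_gff(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            if row.feature == "gene":
                attrs = f"ID={row.gene_id}"
            else:
                attrs = f"Parent={row.gene_id}"
            fh.write(
                f"{row.chrom}\tmutload\t{row.feature}\t{row.start}\t{row.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def read_gff(path: str | Path) -> pd.DataFrame:
    """Read the GFF3-like gene-model dialect written by :func:`write_gff`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Parent") or ""
            rows.append((f[0], int(f[3]), int(f[4]), f[2], gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "gene_id"])


def generate_genetic_map(
    n_markers: int,
    cm_per_mb: float,
    seed: int,
    *,
    chrom_names: Sequence[str] = ("chr01",),
    chrom_length: int = 1_000_000,
    noise: float = 0.0,
) -> pd.DataFrame:
    """Monotone genetic map; ``noise`` perturbs per-interval cM increments
    multiplicatively while preserving strict monotonicity."""
    if n_markers < 2 * len(chrom_names):
        raise ConfigError("need at least two markers per chromosome")
    rng = np.random.default_rng(seed)
    per_chrom = max(2, n_markers // len(chrom_names))
    frames = []
    for chrom in chrom_names:
        bp = np.unique(
            np.round(np.linspace(1, chrom_length, per_chrom)).astype(int)
        )
        inc = np.diff(bp) / 1e6 * cm_per_mb
        if noise > 0:
            inc = inc * rng.uniform(1 - noise, 1 + noise, size=inc.size)
        cm = np.concatenate([[0.0], np.cumsum(inc)])
        frames.append(pd.DataFrame({"chrom": chrom, "bp": bp, "cM": cm}))
    return pd.concat(frames, ignore_index=True)


def generate_sweep_table(
    seed: int,
    *,
    chrom_names: Sequence[str] = ("chr01",),
    chrom_length: int = 1_000_000,
    grid_points: int = 50,
) -> pd.DataFrame:
    """Mock per-position sweep-statistic grid (exponential likelihoods)."""
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in chrom_names:
        pos = np.round(np.linspace(1, chrom_length, grid_points)).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": pos,
                    "likelihood": rng.exponential(1.0, size=grid_points),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# SV fixtures


@dataclass
class SVFixtureConfig:
    """Configuration for planted-SV mock caller outputs."""

    accessions: Sequence[str]
    outgroup: str
    n_truth: int = 20
    chrom_names: Sequence[str] = ("chr01", "chr02")
    chrom_length: int = 2_000_000
    #: minimum truth length; must be large enough that jittered replicate
    #: calls still satisfy the 90 % length-ratio merge criterion.
    min_len: int = 1500
    max_len: int = 5000
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"DEL": 0.5, "DUP": 0.25, "INV": 0.2, "TRA": 0.05}
    )
    carrier_prob: float = 0.5
    outgroup_carrier_prob: float = 0.0
    callers: Sequence[str] = ("callerA", "callerB", "callerC")
    jitter: Mapping[str, int] = field(
        default_factory=lambda: {"callerA": 10, "callerB": 20, "callerC": 33}
    )
    dropout: Mapping[str, float] = field(default_factory=dict)
    false_positives: Mapping[str, int] = field(default_factory=dict)
    #: minimum separation (bp) between planted intervals so that jitter
    #: can never merge distinct events or false positives into truth.
    min_separation: int = 300

    def validate(self) -> None:
        if len(self.callers) != 3:
            raise ConfigError("exactly three callers expected")
        for c in self.callers:
            if self.jitter.get(c, 0) > 33:
                raise ConfigError(
                    f"jitter for {c!r} exceeds 33 bp; planted replicate calls "
                    "would no longer be mergeable by design"
                )
        if abs(sum(self.type_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("type_weights must sum to 1")
        if set(self.type_weights) - set(SV_TYPES):
            raise ConfigError(f"type_weights keys must be drawn from {SV_TYPES}")


def _place_interval(
    rng: np.random.Generator,
    cfg: SVFixtureConfig,
    existing: list[tuple[str, int, int]],
    length: int,
) -> tuple[str, int, int]:
    for _ in range(1000):
        chrom = cfg.chrom_names[rng.integers(0, len(cfg.chrom_names))]
        start = int(rng.integers(1, cfg.chrom_length - length))
        end = start + length - 1
        ok = all(
            not (c == chrom and start - cfg.min_separation <= e and s <= end + cfg.min_separation)
            for c, s, e in existing
        )
        if ok:
            existing.append((chrom, start, end))
            return chrom, start, end
    raise ConfigError("could not place SV fixtures; chromosomes too crowded")


def generate_sv_fixtures(
    cfg: SVFixtureConfig, seed: int, outdir: str | Path
) -> tuple[pd.DataFrame, dict[str, dict[str, Path]]]:
    """Plant truth SVs and write three jittered mock caller VCFs per accession.

    Every caller call carries the truth id in its VCF ID column so oracle
    tests can verify recovery.  False positives (ids ``fp_*``) appear in
    exactly one caller's output for one accession.  Returns the truth
    table and a mapping accession -> caller -> VCF path.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    types = list(cfg.type_weights)
    weights = np.array([cfg.type_weights[t] for t in types])
    occupied: list[tuple[str, int, int]] = []
    truth_rows = []
    for i in range(cfg.n_truth):
        svtype = types[rng.choice(len(types), p=weights)]
        if svtype == "TRA":
            # two distant breakpoints on one chromosome
            length = int(rng.integers(50_000, 200_000))
        else:
            length = int(rng.integers(cfg.min_len, cfg.max_len))
        chrom, start, end = _place_interval(rng, cfg, occupied, length)
        carriers = [
            a
            for a in cfg.accessions
            if a != cfg.outgroup and rng.random() < cfg.carrier_prob
        ]
        if not carriers:
            non_og = [a for a in cfg.accessions if a != cfg.outgroup]
            carriers = [non_og[rng.integers(0, len(non_og))]]
        if cfg.outgroup in cfg.accessions and rng.random() < cfg.outgroup_carrier_prob:
            carriers.append(cfg.outgroup)
        truth_rows.append(
            {
                "sv_id": f"t{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "type": svtype,
                "carriers": ",".join(carriers),
            }
        )
    truth = pd.DataFrame(truth_rows)

    calls: dict[str, dict[str, list]] = {
        a: {c: [] for c in cfg.callers} for a in cfg.accessions
    }
    for row in truth.itertuples(index=False):
        for acc in row.carriers.split(","):
            for caller in cfg.callers:
                if rng.random() < cfg.dropout.get(caller, 0.0):
                    continue
                sigma = cfg.jitter.get(caller, 0)
                j0 = int(rng.integers(-sigma, sigma + 1)) if sigma else 0
                j1 = int(rng.integers(-sigma, sigma + 1)) if sigma else 0
                s = max(1, row.start + j0)
                e = max(s + 1, row.end + j1)
                calls[acc][caller].append((row.chrom, s, e, row.type, row.sv_id))
    non_og = [a for a in cfg.accessions if a != cfg.outgroup]
    for caller in cfg.callers:
        for k in range(cfg.false_positives.get(caller, 0)):
            length = int(rng.integers(cfg.min_len, cfg.max_len))
            chrom, s, e = _place_interval(rng, cfg, occupied, length)
            svtype = types[rng.choice(len(types), p=weights)]
            acc = non_og[rng.integers(0, len(non_og))]
            calls[acc][caller].append((chrom, s, e, svtype, f"fp_{caller}_{k:03d}"))

    paths: dict[str, dict[str, Path]] = {}
    for acc in cfg.accessions:
        paths[acc] = {}
        for caller in cfg.callers:
            path = outdir / f"{acc}.{caller}.vcf"
            _write_sv_vcf(calls[acc][caller], cfg, path)
            paths[acc][caller] = path
    truth.to_csv(outdir / "sv_truth.tsv", sep="\t", index=False)
    return truth, paths


def _write_sv_vcf(
    records: list[tuple], cfg: SVFixtureConfig, path: Path
) -> None:
    records = sorted(records, key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in cfg.chrom_names:
            fh.write(f"##contig=<ID={chrom},length={cfg.chrom_length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, s, e, svtype, svid in records:
            svlen = e - s + 1
            if svtype == "TRA":
                info = f"SVTYPE=TRA;END={e}"
            else:
                sign = "-" if svtype == "DEL" else ""
                info = f"SVTYPE={svtype};END={e};SVLEN={sign}{svlen}"
            fh.write(
                f"{chrom}\t{s}\t{svid}\tN\t<{svtype}>\t.\tPASS\t{info}\n"
            )
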
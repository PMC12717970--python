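"""Functional classification of polarized SNPs from annotation tables.

The two tabular dialects are deliberately minimal:

* SIFT-style TSV: columns ``chrom  pos  ref  alt  region  substitution
  label`` where ``substitution`` is SYNONYMOUS or NONSYNONYMOUS and
  ``label`` is the effect prediction for nonsynonymous sites.
* PROVEAN-style TSV: columns ``chrom  pos  score``.

A site is *deleterious* only when it is nonsynonymous, its SIFT label is
in the deleterious class (plain or low-confidence) **and** its PROVEAN
score is strictly below -2.5.  Any other nonsynonymous site is
neutral-nonsynonymous; SIFT-synonymous sites are synonymous; sites
absent from the SIFT table are non-coding.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ClassificationError
from .variant_io import PolarizedSiteTable

logger = logging.getLogger(__name__)

PROVEAN_THRESHOLD = -2.5

_SIFT_COLUMNS = ["chrom", "pos", "ref", "alt", "region", "substitution", "label"]
_PROVEAN_COLUMNS = ["chrom", "pos", "score"]


def is_sift_deleterious_label(label: str) -> bool:
    """True for 'DELETERIOUS' and any low-confidence variant of it."""
    if not isinstance(label, str):
        return False
    upper = label.upper()
    return upper.startswith("DELETERIOUS") or "LOW CONFIDENCE" in upper


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != columns:
            raise ClassificationError(
                f"{path}: expected header {columns}, got {header}"
            )
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ClassificationError(
                    f"{path}: line {ln}: expected {len(columns)} columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=columns)
    try:
        df["pos"] = df["pos"].astype(int)
    except ValueError as exc:
        raise ClassificationError(f"{path}: non-integer position: {exc}") from exc
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = df.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ClassificationError(
            f"{path}: duplicate site key {first['chrom']}:{first['pos']}"
        )
    return df


def read_sift_table(path: str | Path) -> pd.DataFrame:
    """Read a SIFT-style TSV keyed by (chrom, pos)."""
    return _read_tsv(path, _SIFT_COLUMNS)


def read_provean_table(path: str | Path) -> pd.DataFrame:
    """Read a PROVEAN-style TSV keyed by (chrom, pos)."""
    df = _read_tsv(path, _PROVEAN_COLUMNS)
    try:
        df["score"] = df["score"].astype(float)
    except ValueError as exc:
        raise ClassificationError(f"{path}: non-numeric score: {exc}") from exc
    return df


def classify_sites(
    sift: pd.DataFrame,
    provean: pd.DataFrame,
    polarized: PolarizedSiteTable,
) -> pd.DataFrame:
    """Assign each polarized site one of the four categories.

    Returns a frame aligned row-for-row with ``polarized.sites`` carrying
    ``category``, ``sift_label`` and ``provean_score`` columns.  Every
    site receives exactly one category; counts per category are logged.
    """
    sites = polarized.sites[["chrom", "pos", "ancestral", "derived", "status"]].copy()
    merged = sites.merge(
        sift[["chrom", "pos", "substitution", "label"]], on=["chrom", "pos"], how="left"
    ).merge(provean[["chrom", "pos", "score"]], on=["chrom", "pos"], how="left")
    if len(merged) != len(sites):
        raise ClassificationError("annotation join changed row count; duplicate keys?")

    subst = merged["substitution"].fillna("")
    score = merged["score"]
    label = merged["label"].fillna("")
    nonsyn = subst == "NONSYNONYMOUS"
    syn = subst == "SYNONYMOUS"

    stray = score.notna() & ~nonsyn
    if stray.any():
        logger.warning(
            "%d PROVEAN scores on non-nonsynonymous sites ignored", int(stray.sum())
        )
    no_score = nonsyn & score.isna()
    if no_score.any():
        logger.info(
            "%d nonsynonymous sites lack a PROVEAN score; treated as "
            "neutral-nonsynonymous",
            int(no_score.sum()),
        )

    sift_del = label.map(is_sift_deleterious_label)
    deleterious = nonsyn & sift_del & (score < PROVEAN_THRESHOLD)
    category = np.full(len(merged), "non_coding", dtype=object)
    category[syn] = "synonymous"
    category[nonsyn] = "neutral_nonsynonymous"
    category[deleterious] = "deleterious"

    absent = ~(syn | nonsyn)
    if absent.any():
        logger.info(
            "%d sites absent from the SIFT table treated as non-coding",
            int(absent.sum()),
        )

    out = polarized.sites[["chrom", "pos", "ancestral", "derived"]].copy()
    out["category"] = category
    out["sift_label"] = label.where(label != "", other=pd.NA)
    out["provean_score"] = score
    counts = out["category"].value_counts().to_dict()
    logger.info("category counts: %s", counts)
    return out


def write_category_table(categories: pd.DataFrame, path: str | Path) -> None:
    categories.to_csv(path, sep="\t", index=False)
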
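"""Ingest of miRNA->target prediction tables from four databases.

Each database assigns a putative miRNA->gene pair a numerical score:

* MicroCosm and PicTar scores are used as-is;
* microRNA.org scores are negative and are squared into positive values;
* TargetScan provides no score, only a list of seed-match site types
  (8mer, 7mer-m8, 7mer-1A) with a conservation class; a score is built
  from a fixed per-site point scheme.

Transcript-level records are collapsed to gene level (CG number keyed);
zero-score records are dropped on ingest (a database "predicts" a gene
only with a nonzero score).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

DATABASES = ("microcosm", "pictar", "mirnaorg", "targetscan")

#: Points per seed-match site, privileging 8mer over 7mer and conservation.
SITE_POINTS = {
    ("8mer", "conserved"): 10,
    ("7mer-m8", "conserved"): 6,
    ("7mer-1A", "conserved"): 4,
    ("8mer", "poorly_conserved"): 8,
    ("7mer-m8", "poorly_conserved"): 4,
    ("7mer-1A", "poorly_conserved"): 2,
}


class SiteAnnotation(NamedTuple):
    site_type: str  # 8mer | 7mer-m8 | 7mer-1A
    conservation: str  # conserved | poorly_conserved


def targetscan_site_points(site: SiteAnnotation) -> int:
    try:
        return SITE_POINTS[(site.site_type, site.conservation)]
    except KeyError:
        raise ValueError(
            f"unknown site annotation {site!r}; site_type must be one of "
            "8mer/7mer-m8/7mer-1A and conservation conserved/poorly_conserved"
        ) from None


def targetscan_score(sites: Iterable[SiteAnnotation]) -> float:
    """Sum of per-site points; an empty site list scores 0."""
    return float(sum(targetscan_site_points(s) for s in sites))


def transform_score(database: str, raw_score: float) -> float:
    """Database-specific score transform (microRNA.org squares its scores)."""
    if database not in DATABASES:
        raise ValueError(f"unknown database {database!r}")
    if database == "mirnaorg":
        if raw_score > 0:
            warnings.warn(
                f"mirnaorg raw score {raw_score} is positive (expected "
                "negative polarity); squaring anyway",
                stacklevel=2,
            )
        return raw_score**2
    return raw_score


def collapse_transcripts(records: pd.DataFrame, rule: str = "sum") -> pd.DataFrame:
    """Collapse transcript-level records to one record per (mirna, gene_id).

    ``rule`` is "sum" (default; preserves total score mass) or "max"
    (sensitivity alternative).  A gene_id carrying conflicting gene_name
    values is refused.
    """
    if rule not in ("sum", "max"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    if records["database"].nunique() > 1:
        raise ValueError("collapse_transcripts expects records from one database")
    names = records[records["gene_name"].notna()].groupby("gene_id")["gene_name"].nunique()
    conflicts = names[names > 1]
    if len(conflicts) > 0:
        raise ValueError(
            "conflicting gene_name for gene_id(s): " + ", ".join(conflicts.index)
        )
    agg = (
        records.groupby(["database", "mirna", "gene_id"], as_index=False)
        .agg(gene_name=("gene_name", "first"), score=("score", rule))
    )
    return agg


# ---------------------------------------------------------------------------
# Canonical TSV dialects (the original web services are defunct; all inputs
# arrive as tab-separated text)


def read_predictions(path, database: str) -> pd.DataFrame:
    """Read the generic dialect `mirna gene_id gene_name transcript_id raw_score`.

    Returns transcript-level records with the database transform applied
    (column ``score``); zero-score rows are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["raw_score"] = df["raw_score"].astype(float)
    df["database"] = database
    df["score"] = [transform_score(database, x) for x in df["raw_score"]]
    return df[df["score"] != 0].reset_index(drop=True)


def read_targetscan(path) -> pd.DataFrame:
    """Read the TargetScan dialect
    `mirna_or_family gene_id gene_name site_type conservation count`.

    Each row contributes count * site points; rows for the same
    (mirna_or_family, gene_id) are summed into one raw score.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["count"] = df["count"].astype(int)
    df["points"] = [
        targetscan_site_points(SiteAnnotation(st, cons)) * n
        for st, cons, n in zip(df["site_type"], df["conservation"], df["count"])
    ]
    agg = (
        df.groupby(["mirna_or_family", "gene_id"], as_index=False)
        .agg(gene_name=("gene_name", "first"), raw_score=("points", "sum"))
        .rename(columns={"mirna_or_family": "mirna"})
    )
    agg["raw_score"] = agg["raw_score"].astype(float)
    agg["database"] = "targetscan"
    agg["score"] = agg["raw_score"]
    agg["transcript_id"] = agg["gene_id"]
    return agg[agg["score"] != 0].reset_index(drop=True)


def load_manifest(manifest_path, collapse_rule: str = "sum") -> dict[str, pd.DataFrame]:
    """Load all databases named in a manifest JSON.

    The manifest maps database name -> {"path": ..., "dialect":
    "generic"|"targetscan"}; paths are resolved relative to the manifest.
    Returns gene-level (collapsed), transformed records per database.
    """
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    out: dict[str, pd.DataFrame] = {}
    for db, entry in entries.items():
        if db not in DATABASES:
            raise ValueError(f"unknown database {db!r} in manifest")
        path = manifest_path.parent / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"prediction file for {db} not found: {path}")
        if entry.get("dialect", "generic") == "targetscan":
            df = read_targetscan(path)
        else:
            df = read_predictions(path, db)
        out[db] = collapse_transcripts(df, rule=collapse_rule)
    return out
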
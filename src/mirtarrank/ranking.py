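"""Two-step gene ranking, per-database normalisation, and pooling.

Within each database the ranking value of a gene is

    Sigma = sum over targeting miRNAs of (score x Av(chi2)),

i.e. prediction strength weighted by the miRNA's screen strength.  Each
database's Sigma column is scaled so its maximum equals 100 and then
weighted by the fraction of screened miRNAs the database covers; the
pooled gene score is the sum of these normalised values over databases.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatabaseCoverage:
    """How many of the screened miRNAs a database knows about."""

    database: str
    n_mirnas_present: int
    n_screened: int = 44

    def __post_init__(self) -> None:
        if not 0 < self.n_mirnas_present <= self.n_screened:
            raise ValueError(
                f"coverage {self.n_mirnas_present}/{self.n_screened} out of range"
            )

    @property
    def fraction(self) -> float:
        return self.n_mirnas_present / self.n_screened


def step1_weighted(
    predictions: pd.DataFrame, strengths: Mapping[str, float]
) -> pd.DataFrame:
    """Weight each gene-level prediction score by its miRNA's Av(chi2).

    ``strengths`` maps miRNA (or TargetScan family) label -> Av(chi2).
    Predictions for miRNAs absent from ``strengths`` (not screened) are
    skipped with a logged warning.
    """
    known = predictions["mirna"].isin(strengths.keys())
    skipped = predictions.loc[~known, "mirna"].unique()
    for m in skipped:
        logger.warning("miRNA %s has no screen strength; predictions skipped", m)
    out = predictions[known].copy()
    out["weighted"] = out["score"] * out["mirna"].map(strengths)
    return out


def step2_gene_sum(step1: pd.DataFrame) -> pd.Series:
    """Sum weighted values over all miRNAs targeting each gene.

    Returns a Series indexed by gene_id, descending (the within-database
    ranking order), gene_id-ascending on ties.
    """
    sigma = step1.groupby("gene_id")["weighted"].sum()
    return sigma.sort_index().sort_values(ascending=False, kind="stable")


def normalise_ranking(sigma: pd.Series, coverage: DatabaseCoverage) -> pd.Series:
    """Scale to max=100, then weight by the database's miRNA coverage fraction.

    Negative Sigma values (possible through negative family strengths) are
    scaled by the same positive maximum, preserving order.
    """
    max_sigma = sigma.max()
    if not max_sigma > 0:
        raise ValueError("degenerate ranking: maximum Sigma is not positive")
    return sigma / max_sigma * 100.0 * coverage.fraction


def pool_databases(normalised: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Sum each gene's normalised values over databases into a pooled score.

    A database not predicting a gene contributes 0.  Returns a DataFrame
    indexed by gene_id with one ``norm_<db>`` column per database, a
    ``pooled`` column, and a dense descending ``rank`` (ties broken by
    gene_id lexicographically).
    """
    if not normalised:
        raise ValueError("no database rankings to pool")
    wide = pd.DataFrame({f"norm_{db}": s for db, s in sorted(normalised.items())})
    pooled = wide.fillna(0.0).sum(axis=1)
    out = wide.assign(pooled=pooled)
    out = out.sort_index().sort_values("pooled", ascending=False, kind="stable")
    out["rank"] = out["pooled"].rank(method="dense", ascending=False).astype(int)
    out.index.name = "gene_id"
    return out


def common_targets(
    gene_sets: Mapping[str, Iterable[str]]
) -> tuple[set[str], dict[str, int]]:
    """Intersection of per-database gene sets plus the full Venn census.

    Returns (genes present in every set, region counts).  Region keys are
    "&"-joined sorted database names; each gene is counted in exactly the
    region of the databases containing it, so counts are exclusive and sum
    to the union size.
    """
    sets = {db: set(genes) for db, genes in gene_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    names = sorted(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions["&".join(combo)] = 0
    union = set().union(*sets.values())
    for gene in union:
        members = tuple(db for db in names if gene in sets[db])
        regions["&".join(members)] += 1
    intersection = set.intersection(*sets.values())
    return intersection, regions


def ranking_table(
    sigmas: Mapping[str, pd.Series],
    coverages: Mapping[str, DatabaseCoverage],
    gene_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full ranked output: per-database Sigma and normalised columns, pooled
    score, dense rank, and an ``in_all_four`` flag."""
    normalised = {
        db: normalise_ranking(sigma, coverages[db]) for db, sigma in sigmas.items()
    }
    pooled = pool_databases(normalised)
    for db, sigma in sorted(sigmas.items()):
        pooled[f"sigma_{db}"] = sigma
    in_all = pooled[[f"norm_{db}" for db in sigmas]].notna().all(axis=1)
    pooled["in_all_four"] = in_all if len(sigmas) == 4 else False
    if gene_names:
        pooled.insert(0, "gene_name", pooled.index.map(lambda g: gene_names.get(g, g)))
    return pooled
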
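"""RNAi validation scoring: Av(chi2)IR, categories, predicting power.

Candidate target genes are knocked down with (ideally two) independent
RNAi lines and their lifespan effect is scored with the same signed
chi-square averaging used for miRNA strengths — Av(chi2)IR.  Multiplying
a gene's Av(chi2)IR by its prediction score (pooled or per-database)
gives a combined score; summing combined scores over all tested genes
gives each database's predicting power, with lifespan-extending outcomes
(false positives of the "shortening" prediction) contributing negatively.
Efficiency divides power by the number of targets the database predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from mirtarrank.strength import MiRNAStrength, SignedLine, average_strength

CATEGORIES = (
    "confirmed_2x",
    "contradicted_2x",
    "partial_confirmed",
    "partial_contradicted",
    "no_effect",
)


@dataclass(frozen=True)
class ValidationRecord:
    gene_id: str
    lines: tuple[SignedLine, ...]
    av_chi2_ir: float
    category: str
    combined: dict[str, float]  # key: "pooled" or database name


@dataclass(frozen=True)
class PredictingPower:
    database_or_pooled: str
    group: str
    power: float
    n_genes: int


def categorize(lines: Sequence[SignedLine]) -> str:
    """Apply the 2-RNAi-lines criterion to a gene's line outcomes.

    confirmed_2x: at least two significant lines, all shortening.
    contradicted_2x: at least two significant lines, all extending.
    partial_(confirmed|contradicted): exactly one significant line.
    no_effect: no significant line.
    Genuinely mixed significant directions fall back to partial by the
    dominant absolute signed chi-square, with a warning.
    """
    if not lines:
        raise ValueError("categorize requires at least one line")
    shorten = [ln for ln in lines if ln.direction == "shorten"]
    extend = [ln for ln in lines if ln.direction == "extend"]
    if shorten and extend:
        warnings.warn(
            "mixed significant directions; categorising by dominant |chi2|",
            stacklevel=2,
        )
        dominant_shorten = max(ln.chi2 for ln in shorten) >= max(
            ln.chi2 for ln in extend
        )
        return "partial_confirmed" if dominant_shorten else "partial_contradicted"
    if len(shorten) >= 2:
        return "confirmed_2x"
    if len(extend) >= 2:
        return "contradicted_2x"
    if len(shorten) == 1:
        return "partial_confirmed"
    if len(extend) == 1:
        return "partial_contradicted"
    return "no_effect"


def validate_gene(
    gene_id: str,
    lines: Sequence[SignedLine],
    scores: Mapping[str, float],
) -> ValidationRecord:
    """Score one tested gene against its prediction scores.

    ``scores`` maps "pooled" and/or database names to the gene's
    normalised prediction scores; a gene with no score in any ranking is
    not a predicted target and is refused.
    """
    present = {k: v for k, v in scores.items() if pd.notna(v)}
    if not present:
        raise ValueError(f"{gene_id!r} is not a predicted target in any ranking")
    strength: MiRNAStrength = average_strength(list(lines), label=gene_id)
    combined = {k: float(v) * strength.av_chi2 for k, v in present.items()}
    return ValidationRecord(
        gene_id=gene_id,
        lines=tuple(lines),
        av_chi2_ir=strength.av_chi2,
        category=categorize(lines),
        combined=combined,
    )


def predicting_power(
    records: Sequence[ValidationRecord], key: str, group: str = ""
) -> PredictingPower:
    """Sum the combined scores for ``key`` over all records carrying it.

    Negative contributions (extending outcomes) are included as-is: the
    sign penalty already lives inside Av(chi2)IR.
    """
    carrying = [r for r in records if key in r.combined]
    if not carrying:
        raise ValueError(f"no validation record carries key {key!r}")
    power = sum(r.combined[key] for r in carrying)
    return PredictingPower(
        database_or_pooled=key, group=group, power=power, n_genes=len(carrying)
    )


def predicting_efficiency(power: PredictingPower, n_predicted: int) -> float:
    """Power normalised by the database's total number of predicted targets."""
    if n_predicted <= 0:
        raise ValueError("n_predicted must be positive")
    return power.power / n_predicted


# ---------------------------------------------------------------------------
# Table-level driver


def lines_from_table(lines_df: pd.DataFrame) -> dict[str, list[SignedLine]]:
    """Group a `gene_id line_id chi2 p direction` table into SignedLines."""
    out: dict[str, list[SignedLine]] = {}
    for r in lines_df.itertuples(index=False):
        out.setdefault(r.gene_id, []).append(
            SignedLine(line_id=str(r.line_id), chi2=float(r.chi2), direction=r.direction)
        )
    return out


def validate_table(
    lines_df: pd.DataFrame, scores_df: pd.DataFrame, score_cols: Sequence[str]
) -> list[ValidationRecord]:
    """Validate every gene in ``lines_df`` against a wide score table.

    ``scores_df`` is indexed by gene_id with one column per entry of
    ``score_cols``; missing cells mean the database does not predict the
    gene.
    """
    by_gene = lines_from_table(lines_df)
    records = []
    for gene_id, lines in by_gene.items():
        scores = {c: scores_df.at[gene_id, c] for c in score_cols}
        records.append(validate_gene(gene_id, lines, scores))
    return records


def power_summary(
    records: Sequence[ValidationRecord], keys: Sequence[str], group: str = ""
) -> dict[str, float]:
    """Predicting power per key over one validation group."""
    return {k: float(predicting_power(records, k, group=group).power) for k in keys}
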
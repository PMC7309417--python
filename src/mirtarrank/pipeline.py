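"""End-to-end orchestration: rank targets, validate RNAi outcomes.

Thin drivers over the library modules, reading the canonical TSV dialects
and writing ranked/validated tables plus a provenance block per run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel

from mirtarrank import ranking, strength, targetdb, validation

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    manifest: Path
    strengths: Path  # TSV `label av_chi2 n_lines` (miRNA/family strengths)
    out_dir: Path
    alpha: float = 0.05
    n_screened_mirnas: int = 44
    transcript_collapse_rule: str = "sum"
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.transcript_collapse_rule not in ("sum", "max"):
            raise ValueError("collapse rule must be sum or max")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(config: PipelineConfig, inputs: list[Path]) -> dict:
    return {
        "config": json.loads(config.model_dump_json()),
        "config_hash": hashlib.sha256(config.model_dump_json().encode()).hexdigest(),
        "seed": config.seed,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }


def read_strengths_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    return dict(zip(df["label"], df["av_chi2"].astype(float)))


def run_rank(config: PipelineConfig) -> pd.DataFrame:
    """Rank all predicted targets: per-database Sigma, normalised, pooled.

    Writes the ranked TSV and the Venn region-count JSON to the output
    directory and returns the ranked table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strengths = read_strengths_tsv(config.strengths)
    dbs = targetdb.load_manifest(
        config.manifest, collapse_rule=config.transcript_collapse_rule
    )
    if all(df.empty for df in dbs.values()):
        raise ValueError("empty prediction set: no database contains records")

    sigmas, coverages, gene_names = {}, {}, {}
    for db, df in dbs.items():
        weighted = ranking.step1_weighted(df, strengths)
        sigmas[db] = ranking.step2_gene_sum(weighted)
        n_present = df.loc[df["mirna"].isin(strengths), "mirna"].nunique()
        coverages[db] = ranking.DatabaseCoverage(
            db, n_mirnas_present=n_present, n_screened=config.n_screened_mirnas
        )
        logger.info(
            "database %s: %d/%d screened miRNAs present",
            db, n_present, config.n_screened_mirnas,
        )
        gene_names.update(dict(zip(df["gene_id"], df["gene_name"])))

    ranked = ranking.ranking_table(sigmas, coverages, gene_names)
    ranked.to_csv(out / "ranked_targets.tsv", sep="\t")

    _, venn = ranking.common_targets({db: set(s.index) for db, s in sigmas.items()})
    (out / "venn_regions.json").write_text(json.dumps(venn, indent=1))
    (out / "provenance_rank.json").write_text(
        json.dumps(_provenance(config, [Path(config.manifest), Path(config.strengths)]),
                   indent=1)
    )
    return ranked


def run_validate(
    config: PipelineConfig,
    rnai_path,
    ranked: pd.DataFrame | None = None,
    n_predicted: Mapping[str, int] | None = None,
) -> list[validation.ValidationRecord]:
    """Score an RNAi table `gene_id line_id chi2 p direction` against rankings.

    Genes absent from every ranking are reported in a skipped-genes file
    rather than failing the run.  Writes the validation TSV and the
    predicting-power JSON (with efficiencies if ``n_predicted`` supplies
    per-database predicted-target totals).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ranked is None:
        ranked = pd.read_csv(out / "ranked_targets.tsv", sep="\t", index_col="gene_id")
    rnai = pd.read_csv(rnai_path, sep="\t", dtype={"gene_id": str, "line_id": str})
    if rnai.empty:
        logger.warning("empty RNAi table %s; nothing to validate", rnai_path)
        (out / "validation.tsv").write_text("gene_id\tav_chi2_ir\tcategory\n")
        return []

    norm_cols = [c for c in ranked.columns if c.startswith("norm_")]
    keys = ["pooled"] + [c.removeprefix("norm_") for c in norm_cols]
    by_gene = validation.lines_from_table(rnai)
    records, skipped = [], []
    for gene_id, lines in by_gene.items():
        if gene_id not in ranked.index:
            skipped.append(gene_id)
            continue
        scores = {"pooled": ranked.at[gene_id, "pooled"]}
        for c in norm_cols:
            scores[c.removeprefix("norm_")] = ranked.at[gene_id, c]
        records.append(validation.validate_gene(gene_id, lines, scores))
    if skipped:
        (out / "skipped_genes.txt").write_text("\n".join(skipped) + "\n")
        logger.warning("%d RNAi genes not in any ranking; see skipped_genes.txt",
                       len(skipped))

    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "n_lines": len(r.lines),
            "av_chi2_ir": strength.round_half_up(r.av_chi2_ir),
            "category": r.category,
        }
        for k in keys:
            row[f"combined_{k}"] = (
                strength.round_half_up(r.combined[k]) if k in r.combined else None
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "validation.tsv", sep="\t", index=False)

    power = validation.power_summary(records, keys, group="all")
    summary: dict = {"predicting_power": power}
    if n_predicted:
        summary["efficiency"] = {
            k: power[k] / n_predicted[k] for k in power if k in n_predicted
        }
    (out / "predicting_power.json").write_text(json.dumps(summary, indent=1))
    (out / "provenance_validate.json").write_text(
        json.dumps(_provenance(config, [Path(rnai_path)]), indent=1)
    )
    return records
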
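"""Synthetic lifespan screens with planted ground truth.

Generates every input the pipeline consumes — per-fly survival records for
a miRNA overexpression screen, four miRNA->target prediction databases
with partial miRNA coverage and partial target overlap, a TargetScan
family table, and RNAi validation lines — so the whole analysis is
testable end to end without any external download.

The generative model:

* survival is Weibull (exponential by default, shape 1) with a per-day
  baseline hazard and a per-genotype hazard ratio; flies alive at the end
  of the study are right-censored;
* each screened miRNA carries a hazard ratio drawn log-uniformly from a
  configured range (all > 1: the screen retained lifespan-shortening
  miRNAs) and is tested with one or two transgenic lines;
* a configured number of "essential" genes is planted: each is targeted
  by several miRNAs with top-percentile prediction scores in every
  database covering that miRNA, and is predicted by all four databases;
* background genes receive log-normal scores from a few random miRNAs in
  a random proper subset of databases, so that only roughly the
  configured fraction of genes is predicted by all four;
* microRNA.org raw scores are emitted negative (the square recovers the
  working score) and TargetScan predictions are emitted as seed-match
  site lists rather than numerical scores.

One global seed drives hierarchical per-stream seeds (survival,
databases, RNAi), so each stage regenerates independently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from mirtarrank import strength, survival, targetdb
from mirtarrank.ranking import DatabaseCoverage

#: Per-database fractions of screened miRNAs covered (31, 28, 43, 40 of 44).
DEFAULT_DB_COVERAGE = {
    "microcosm": 31 / 44,
    "pictar": 28 / 44,
    "mirnaorg": 43 / 44,
    "targetscan": 40 / 44,
}


class ScreenSimConfig(BaseModel):
    """Study-condition parameters for a synthetic screen."""

    n_mirnas: int = 44
    n_genes: int = 10_000
    n_essential_genes: int = 20
    db_coverage: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DB_COVERAGE)
    )
    overlap_target: float = 0.056  # fraction of genes predicted by all four
    baseline_hazard: float = 0.0231  # per day; control median ~30 days
    hazard_ratio_range: tuple[float, float] = (2.0, 6.0)
    n_flies_per_group: int = 60
    study_days: int = 60
    weibull_shape: float = 1.0
    mirnas_per_planted_gene: int = 4
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScreenSimConfig":
        for db, f in self.db_coverage.items():
            if not 0 < f <= 1:
                raise ValueError(f"coverage fraction for {db} out of (0,1]: {f}")
        if not 0 < self.overlap_target <= 1:
            raise ValueError("overlap_target must be in (0,1]")
        lo, hi = self.hazard_ratio_range
        if not (lo > 0 and hi >= lo):
            raise ValueError("hazard ratios must be positive and ordered")
        return self

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            name: np.random.default_rng(ss)
            for name, ss in zip(("survival", "databases", "rnai"), children)
        }


def simulate_survival(
    config: ScreenSimConfig,
    genotype_hazard_ratios: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-fly survival records for the given genotypes.

    Event times follow a Weibull proportional-hazards model with cumulative
    hazard H(t) = baseline * ratio * t^shape; flies alive at
    ``study_days`` are censored there.  Columns: subject_id, genotype,
    time, event.
    """
    rows = []
    k = config.weibull_shape
    for genotype, ratio in genotype_hazard_ratios.items():
        e = rng.exponential(size=config.n_flies_per_group)
        t = (e / (config.baseline_hazard * ratio)) ** (1.0 / k)
        observed = t <= config.study_days
        t = np.where(observed, t, float(config.study_days))
        for i, (ti, ev) in enumerate(zip(t, observed)):
            rows.append((f"{genotype}#{i}", genotype, float(ti), bool(ev)))
    return pd.DataFrame(rows, columns=["subject_id", "genotype", "time", "event"])


def _records(df: pd.DataFrame, genotype: str) -> list[survival.SurvivalRecord]:
    sub = df[df["genotype"] == genotype]
    return [
        survival.SurvivalRecord(r.subject_id, r.genotype, r.time, r.event)
        for r in sub.itertuples(index=False)
    ]


def simulate_mirna_screen(
    config: ScreenSimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, float], dict[str, list[str]]]:
    """Survival data for the miRNA screen plus its ground truth.

    Each miRNA gets a log-uniform hazard ratio and one or two transgenic
    lines sharing it.  Returns (survival records incl. a ``control``
    genotype, miRNA -> hazard ratio, miRNA -> its line genotypes).
    """
    rng = rng or config.streams()["survival"]
    lo, hi = config.hazard_ratio_range
    mirnas = [f"miR-s{i + 1:02d}" for i in range(config.n_mirnas)]
    ratios = {m: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for m in mirnas}
    genotype_ratios: dict[str, float] = {"control": 1.0}
    lines: dict[str, list[str]] = {}
    for m in mirnas:
        n_lines = int(rng.integers(1, 3))  # one or two lines per miRNA
        lines[m] = [f"{m}/L{j + 1}" for j in range(n_lines)]
        for g in lines[m]:
            genotype_ratios[g] = ratios[m]
    df = simulate_survival(config, genotype_ratios, rng)
    return df, ratios, lines


def screen_strengths(
    screen_df: pd.DataFrame,
    mirna_lines: Mapping[str, Sequence[str]],
    alpha: float = survival.DEFAULT_ALPHA,
) -> dict[str, strength.MiRNAStrength]:
    """Run the survival comparisons and average into per-miRNA strengths."""
    control = _records(screen_df, "control")
    out: dict[str, strength.MiRNAStrength] = {}
    for mirna, genotypes in mirna_lines.items():
        signed = []
        for g in genotypes:
            res = survival.classify_direction(
                _records(screen_df, g), control, alpha=alpha,
                line_id=g, gene_or_mirna=mirna,
            )
            signed.append(strength.signed_chi2(res))
        out[mirna] = strength.average_strength(signed, label=mirna)
    return out


def _targetscan_sites(score: float) -> list[tuple[str, str, int]]:
    """Decompose a working score into site rows (type, conservation, count).

    Greedy in units of the point scheme, so the emitted sites re-score to
    approximately the requested value.
    """
    sites = []
    n8 = int(score // 10)
    if n8:
        sites.append(("8mer", "conserved", n8))
    rem = score - 10 * n8
    for stype, cons, pts in (
        ("8mer", "poorly_conserved", 8),
        ("7mer-m8", "conserved", 6),
        ("7mer-1A", "conserved", 4),
        ("7mer-1A", "poorly_conserved", 2),
    ):
        if rem >= pts:
            sites.append((stype, cons, 1))
            rem -= pts
    if not sites:
        sites.append(("7mer-1A", "poorly_conserved", 1))
    return sites


def simulate_prediction_databases(
    config: ScreenSimConfig,
    planted: Mapping[str, Sequence[str]],
    rng: np.random.Generator | None = None,
) -> dict:
    """Four prediction tables (canonical dialects) plus a family table.

    ``planted`` maps essential gene ids to the miRNA labels targeting
    them; those pairs get 99th-percentile scores in every database whose
    miRNA subset contains the miRNA, and the genes are predicted by all
    four databases.  Returns a dict with keys ``tables`` (db ->
    transcript-level DataFrame in the db's dialect), ``families`` (family
    -> members), ``db_mirnas`` (db -> covered miRNA labels).
    """
    rng = rng or config.streams()["databases"]
    mirnas = [f"miR-s{i + 1:02d}" for i in range(config.n_mirnas)]
    genes = [f"CGS{i + 1:05d}" for i in range(config.n_genes)]
    for g in planted:
        if g not in set(genes):
            raise ValueError(f"planted gene {g} outside the gene universe")
    dbs = sorted(config.db_coverage)

    # per-database miRNA subsets at the configured coverage
    db_mirnas = {
        db: sorted(
            rng.choice(mirnas, size=round(config.db_coverage[db] * config.n_mirnas),
                       replace=False)
        )
        for db in dbs
    }

    # TargetScan seed families: group ~30% of its miRNAs into triplets
    ts_pool = [m for m in db_mirnas.get("targetscan", [])]
    rng.shuffle(ts_pool)
    n_fam = max(1, len(ts_pool) // 10)
    families = {}
    for i in range(n_fam):
        members = ts_pool[3 * i : 3 * i + 3]
        if len(members) == 3:
            families["+".join(sorted(members))] = sorted(members)
    member_to_family = {m: f for f, mem in families.items() for m in mem}

    # which databases predict which genes: planted genes in all four,
    # background genes in a random proper subset sized to hit the overlap
    p_all4 = config.overlap_target
    gene_dbs: dict[str, list[str]] = {}
    for g in genes:
        if g in planted:
            gene_dbs[g] = dbs
        elif rng.random() < p_all4:
            gene_dbs[g] = dbs
        else:
            k = int(rng.integers(1, len(dbs)))  # 1..3 databases
            gene_dbs[g] = sorted(rng.choice(dbs, size=k, replace=False))

    # background score distribution and the planted (99th pct) level
    mu, sigma = 1.0, 1.0
    planted_score = float(np.exp(mu + 2.326 * sigma))

    tables: dict[str, pd.DataFrame] = {}
    for db in dbs:
        cov = set(db_mirnas[db])
        rows = []  # (mirna, gene, working_score)
        for g in genes:
            if db not in gene_dbs[g]:
                continue
            n_bg = 1 + rng.poisson(1.0)
            chosen = rng.choice(db_mirnas[db], size=min(n_bg, len(cov)), replace=False)
            for m in chosen:
                rows.append((m, g, float(rng.lognormal(mu, sigma))))
            if g in planted:
                for m in planted[g]:
                    if m in cov:
                        rows.append((m, g, planted_score))
        df = pd.DataFrame(rows, columns=["mirna", "gene_id", "score"])
        df = df.groupby(["mirna", "gene_id"], as_index=False)["score"].max()
        if db == "targetscan":
            out_rows = []
            for r in df.itertuples(index=False):
                label = member_to_family.get(r.mirna, r.mirna)
                for stype, cons, n in _targetscan_sites(r.score):
                    out_rows.append((label, r.gene_id, r.gene_id, stype, cons, n))
            tdf = pd.DataFrame(
                out_rows,
                columns=["mirna_or_family", "gene_id", "gene_name",
                         "site_type", "conservation", "count"],
            )
            # family rows from several members collapse onto one label
            tables[db] = (
                tdf.groupby(
                    ["mirna_or_family", "gene_id", "gene_name",
                     "site_type", "conservation"], as_index=False
                )["count"].max()
            )
        else:
            df["gene_name"] = df["gene_id"]
            df["transcript_id"] = df["gene_id"] + "-RA"
            if db == "mirnaorg":
                df["raw_score"] = -np.sqrt(df["score"])  # squaring recovers
            else:
                df["raw_score"] = df["score"]
            tables[db] = df[
                ["mirna", "gene_id", "gene_name", "transcript_id", "raw_score"]
            ]
    return {"tables": tables, "families": families, "db_mirnas": db_mirnas}


def collapsed_databases(sim: dict) -> dict[str, pd.DataFrame]:
    """Transform + collapse the emitted dialect tables to gene level."""
    out = {}
    for db, df in sim["tables"].items():
        if db == "targetscan":
            rows = df.copy()
            rows["points"] = [
                targetdb.targetscan_site_points(targetdb.SiteAnnotation(s, c)) * n
                for s, c, n in zip(rows["site_type"], rows["conservation"], rows["count"])
            ]
            agg = (
                rows.groupby(["mirna_or_family", "gene_id"], as_index=False)
                .agg(gene_name=("gene_name", "first"), score=("points", "sum"))
                .rename(columns={"mirna_or_family": "mirna"})
            )
            agg["score"] = agg["score"].astype(float)
            agg["database"] = db
            out[db] = agg[agg["score"] != 0]
        else:
            t = df.copy()
            t["database"] = db
            t["score"] = [targetdb.transform_score(db, x) for x in t["raw_score"]]
            out[db] = targetdb.collapse_transcripts(t[t["score"] != 0])
    return out


def simulate_rnai_lines(
    config: ScreenSimConfig,
    gene_hazard_ratios: Mapping[str, tuple[float, ...]],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Survival data for RNAi validation lines plus a ``control`` genotype.

    ``gene_hazard_ratios`` maps gene -> per-line hazard ratios (one entry
    per RNAi line; ratios < 1 model lifespan extension).
    """
    rng = rng or config.streams()["rnai"]
    genotype_ratios: dict[str, float] = {"control": 1.0}
    for gene, ratios in gene_hazard_ratios.items():
        for j, hr in enumerate(ratios):
            genotype_ratios[f"{gene}/IR{j + 1}"] = float(hr)
    return simulate_survival(config, genotype_ratios, rng)


def rnai_line_results(
    rnai_df: pd.DataFrame,
    gene_lines: Mapping[str, Sequence[str]],
    alpha: float = survival.DEFAULT_ALPHA,
) -> dict[str, list[strength.SignedLine]]:
    """Classify every RNAi line against control into signed lines per gene."""
    control = _records(rnai_df, "control")
    out: dict[str, list[strength.SignedLine]] = {}
    for gene, genotypes in gene_lines.items():
        out[gene] = [
            strength.signed_chi2(
                survival.classify_direction(
                    _records(rnai_df, g), control, alpha=alpha,
                    line_id=g, gene_or_mirna=gene,
                )
            )
            for g in genotypes
        ]
    return out


def default_coverages(sim: dict, n_screened: int) -> dict[str, DatabaseCoverage]:
    """DatabaseCoverage objects from the simulated per-database miRNA sets."""
    return {
        db: DatabaseCoverage(db, n_mirnas_present=len(ms), n_screened=n_screened)
        for db, ms in sim["db_mirnas"].items()
    }


def plant_essential_genes(
    config: ScreenSimConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Pick the essential genes and the miRNAs targeting each."""
    genes = [f"CGS{i + 1:05d}" for i in range(config.n_genes)]
    mirnas = [f"miR-s{i + 1:02d}" for i in range(config.n_mirnas)]
    chosen = rng.choice(genes, size=config.n_essential_genes, replace=False)
    return {
        g: sorted(
            rng.choice(mirnas, size=config.mirnas_per_planted_gene, replace=False)
        )
        for g in sorted(chosen)
    }


def run_synthetic_ranking(config: ScreenSimConfig) -> tuple[pd.DataFrame, dict]:
    """Full in-memory pipeline on one synthetic screen.

    Simulates the miRNA screen, derives per-miRNA strengths from the
    survival comparisons, simulates the four prediction databases with the
    configured planted essential genes, ranks and pools.  Returns (pooled
    ranking table, planted gene -> targeting miRNAs).
    """
    from mirtarrank import ranking

    streams = config.streams()
    screen_df, _, mirna_lines = simulate_mirna_screen(config, streams["survival"])
    strengths = screen_strengths(screen_df, mirna_lines)
    db_rng = streams["databases"]
    planted = plant_essential_genes(config, db_rng)
    sim = simulate_prediction_databases(config, planted, db_rng)
    dbs = collapsed_databases(sim)
    base = {m: s.av_chi2 for m, s in strengths.items()}
    with_families = dict(base)
    with_families.update(
        {f: s.av_chi2
         for f, s in strength.apply_families(strengths, sim["families"]).items()}
    )
    sigmas = {}
    coverages = default_coverages(sim, config.n_mirnas)
    for db, df in dbs.items():
        smap = with_families if db == "targetscan" else base
        sigmas[db] = ranking.step2_gene_sum(ranking.step1_weighted(df, smap))
    normalised = {
        db: ranking.normalise_ranking(s, coverages[db]) for db, s in sigmas.items()
    }
    return ranking.pool_databases(normalised), planted


def write_screen(config: ScreenSimConfig, outdir: str | Path) -> dict:
    """Emit a complete synthetic screen as the pipeline's TSV dialects.

    Writes the miRNA-screen survival TSV, the four prediction tables, the
    family table, a manifest JSON, RNAi survival data for the planted
    genes, and a ground-truth JSON.  Returns the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = config.streams()

    screen_df, ratios, mirna_lines = simulate_mirna_screen(config, streams["survival"])
    screen_out = screen_df.copy()
    screen_out["event"] = screen_out["event"].astype(int)
    screen_out.to_csv(outdir / "mirna_screen_survival.tsv", sep="\t", index=False)

    db_rng = streams["databases"]
    planted = plant_essential_genes(config, db_rng)
    sim = simulate_prediction_databases(config, planted, db_rng)
    manifest = {}
    for db, df in sim["tables"].items():
        fname = f"predictions_{db}.tsv"
        df.to_csv(outdir / fname, sep="\t", index=False)
        manifest[db] = {
            "path": fname,
            "dialect": "targetscan" if db == "targetscan" else "generic",
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    fam_rows = [(f, m) for f, mem in sim["families"].items() for m in mem]
    pd.DataFrame(fam_rows, columns=["family", "member"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False
    )

    rnai_rng = streams["rnai"]
    lo, hi = config.hazard_ratio_range
    gene_hrs = {
        g: tuple(np.exp(rnai_rng.uniform(np.log(max(lo, 3.0)), np.log(max(hi, 3.0)), 2)))
        for g in planted
    }
    rnai_df = simulate_rnai_lines(config, gene_hrs, rnai_rng)
    rnai_out = rnai_df.copy()
    rnai_out["event"] = rnai_out["event"].astype(int)
    rnai_out.to_csv(outdir / "rnai_survival.tsv", sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "mirna_hazard_ratios": ratios,
        "mirna_lines": mirna_lines,
        "planted_genes": {g: list(m) for g, m in planted.items()},
        "rnai_hazard_ratios": {g: list(v) for g, v in gene_hrs.items()},
        "db_mirnas": {db: list(m) for db, m in sim["db_mirnas"].items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return truth
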
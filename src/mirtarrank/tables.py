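"""Loaders for the published screen tables bundled with the package.

Three small TSV fixtures transcribed from the published study travel with
the package:

* ``mirna_strengths.tsv`` — the 44 screened miRNAs' Av(chi2) values and,
  where TargetScan groups miRNAs into seed families, the published family
  label, members and family-level value;
* ``rnai_common_lines.tsv`` / ``rnai_common_scores.tsv`` — the 51 RNAi
  validation genes drawn from the four-database common target set: per
  RNAi line median survival, chi-square, p and direction, plus the
  published per-gene prediction scores (pooled and per database);
* ``rnai_differential_lines.tsv`` / ``rnai_differential_scores.tsv`` —
  the 14 genes predicted by only some databases.

Direction labels for significant lines follow the published signed
averages (lifespan-extending lines carry negative sign).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Screened-miRNA coverage per database, out of 44 screened.
DB_COVERAGE = {"microcosm": 31, "pictar": 28, "mirnaorg": 43, "targetscan": 40}
N_SCREENED = 44


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("mirtarrank").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def load_mirna_strengths() -> pd.DataFrame:
    """Per-miRNA Av(chi2) with optional TargetScan family annotation.

    Columns: mirna, av_chi2, targetscan_family_av, targetscan_family_members
    (semicolon-joined member labels; NaN when the miRNA is not grouped).
    """
    return _read("mirna_strengths.tsv", dtype={"mirna": str})


def mirna_families() -> dict[str, list[str]]:
    """TargetScan family label -> member miRNA labels."""
    df = load_mirna_strengths()
    fams: dict[str, list[str]] = {}
    for r in df[df["targetscan_family_members"].notna()].itertuples(index=False):
        members = r.targetscan_family_members.split(";")
        fams["+".join(members)] = members
    return fams


def load_rnai_lines(group: str) -> pd.DataFrame:
    """Per-line RNAi outcomes; group is "common" or "differential".

    Columns: gene_id, line_id, median_survival, chi2, p_value, direction.
    """
    return _read(f"rnai_{group}_lines.tsv", dtype={"gene_id": str, "line_id": str})


def load_rnai_scores(group: str) -> pd.DataFrame:
    """Published per-gene prediction and combined scores, indexed by gene_id.

    The common group carries pooled and per-database columns; the
    differential group per-database columns only (missing cells = gene not
    predicted by that database).
    """
    return _read(f"rnai_{group}_scores.tsv", index_col="gene_id")
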
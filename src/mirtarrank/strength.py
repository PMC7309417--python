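"""Signed chi-square strengths: Av(chi2) per miRNA, family, or RNAi target.

The screen's effect size for a label (a miRNA in the overexpression screen,
a gene in the RNAi validation screen) is the average of its lines' log-rank
chi-squares, signed by direction:

* lifespan-extending lines (significant, opposite to the screened effect)
  contribute their chi-square negatively;
* lines without a significant effect contribute positively;
* a label tested with a single line is averaged with an assumed neutral
  second line of 0, i.e. its signed chi-square is halved.

TargetScan groups some miRNAs into seed families; a family's strength is
the plain mean of its members' Av(chi2) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mirtarrank.survival import ScreenLineResult


@dataclass(frozen=True)
class SignedLine:
    line_id: str
    chi2: float
    direction: str  # shorten | extend | none

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError(f"chi2 must be >= 0, got {self.chi2}")
        if self.direction not in ("shorten", "extend", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def signed_chi2(self) -> float:
        return -self.chi2 if self.direction == "extend" else self.chi2


@dataclass(frozen=True)
class MiRNAStrength:
    mirna_or_family: str
    av_chi2: float
    n_lines_used: int
    members: tuple[str, ...] = field(default_factory=tuple)


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding as used for all displayed chi-square values.

    The float is first formatted at 8 decimals so that sums/means of
    table-precision (4-dp) inputs round on their exact decimal value rather
    than on binary representation noise.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.8f}").quantize(q, rounding=ROUND_HALF_UP))


def signed_chi2(line: ScreenLineResult) -> SignedLine:
    """Carry a screen-line result over to a signed line (extend -> negative)."""
    return SignedLine(line_id=line.line_id, chi2=line.chi2, direction=line.direction)


def average_strength(
    lines: Sequence[SignedLine], label: str = ""
) -> MiRNAStrength:
    """Average the signed chi-squares of a label's lines.

    Two or more lines: arithmetic mean.  Exactly one line: half the signed
    value (a neutral 0 is assumed for a second, untested line).
    """
    if not lines:
        raise ValueError("average_strength requires at least one line")
    signed = [ln.signed_chi2 for ln in lines]
    if len(signed) == 1:
        av = signed[0] / 2.0
    else:
        av = sum(signed) / len(signed)
    return MiRNAStrength(
        mirna_or_family=label, av_chi2=av, n_lines_used=len(signed)
    )


def family_strength(
    member_strengths: Sequence[MiRNAStrength], family_label: str = ""
) -> MiRNAStrength:
    """Plain mean of member Av(chi2) values (members may be negative)."""
    if not member_strengths:
        raise ValueError("family_strength requires at least one member")
    av = sum(m.av_chi2 for m in member_strengths) / len(member_strengths)
    return MiRNAStrength(
        mirna_or_family=family_label,
        av_chi2=av,
        n_lines_used=sum(m.n_lines_used for m in member_strengths),
        members=tuple(m.mirna_or_family for m in member_strengths),
    )


def strengths_from_lines(
    lines_df: pd.DataFrame, label_col: str = "gene_id"
) -> dict[str, MiRNAStrength]:
    """Per-label strengths from a long table of signed lines.

    ``lines_df`` needs columns ``label_col``, ``line_id``, ``chi2``,
    ``direction``.
    """
    out: dict[str, MiRNAStrength] = {}
    for label, grp in lines_df.groupby(label_col, sort=True):
        lines = [
            SignedLine(line_id=str(r.line_id), chi2=float(r.chi2), direction=r.direction)
            for r in grp.itertuples(index=False)
        ]
        out[label] = average_strength(lines, label=str(label))
    return out


def apply_families(
    strengths: Mapping[str, MiRNAStrength], families: Mapping[str, Iterable[str]]
) -> dict[str, MiRNAStrength]:
    """Build family-level strengths from per-miRNA strengths.

    ``families`` maps a family label to its member miRNA labels; members
    missing from ``strengths`` are skipped (they were not screened).
    """
    out: dict[str, MiRNAStrength] = {}
    for fam, members in families.items():
        present = [strengths[m] for m in members if m in strengths]
        if present:
            out[fam] = family_strength(present, family_label=fam)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_lines_tsv(path, label_col: str = "mirna_or_gene") -> pd.DataFrame:
    """Read `<label> line_id chi2 p direction` TSV (p column optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["chi2"] = df["chi2"].astype(float)
    return df.rename(columns={label_col: "gene_id"} if label_col != "gene_id" else {})


def read_family_tsv(path) -> dict[str, list[str]]:
    """Read `family member` TSV into family -> members."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.family, []).append(r.member)
    return out


def write_strengths_tsv(strengths: Mapping[str, MiRNAStrength], path) -> None:
    df = pd.DataFrame(
        {
            "label": list(strengths),
            "av_chi2": [round_half_up(s.av_chi2) for s in strengths.values()],
            "n_lines": [s.n_lines_used for s in strengths.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)
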
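"""Kaplan-Meier estimation and log-rank screening statistics.

One screen line (a genotype) is compared against its control by the
Mantel-Cox log-rank test; the resulting 1-df chi-square, p-value and the
median-survival comparison classify the line as lifespan-shortening,
lifespan-extending, or without significant effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

DEFAULT_ALPHA = 0.05

#: Marker for a median that is never reached (survival stays above 0.5).
UNDEFINED_MEDIAN = math.inf


@dataclass(frozen=True)
class SurvivalRecord:
    """One fly: death day (event=True) or right-censoring day (event=False)."""

    subject_id: str
    genotype: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be positive, got {self.time}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: step function values at ordered event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first observed event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class ScreenLineResult:
    """A screen line's survival comparison against its control."""

    line_id: str
    gene_or_mirna: str
    chi2: float
    p_value: float
    median_survival: float
    direction: str  # shorten | extend | none


def _to_arrays(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    if not recs:
        raise ValueError("no records")
    times = np.array([r.time for r in recs], dtype=float)
    events = np.array([r.event for r in recs], dtype=bool)
    return times, events


def km_estimate(records: Iterable[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one genotype.

    Censored records reduce the at-risk count without stepping the survival
    function down.  Raises ``ValueError("no records")`` on empty input.
    """
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    # keep rows with at least one observed death: those are the step times
    steps = tab[tab["observed"] > 0]
    step_times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(step_times).to_numpy(dtype=float)
    at_risk = steps["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(times=step_times, survival=surv, at_risk=at_risk)


def logrank_chi2(
    group_a: Iterable[SurvivalRecord], group_b: Iterable[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two groups.

    Returns the 1-df chi-square statistic and its p-value.  Raises
    ``ValueError("no events")`` if neither group has an observed death.
    """
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if not (ea.any() or eb.any()):
        raise ValueError("no events")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest time with S(t) <= 0.5, or UNDEFINED_MEDIAN if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return UNDEFINED_MEDIAN
    return float(curve.times[below[0]])


def classify_direction(
    test: Iterable[SurvivalRecord],
    control: Iterable[SurvivalRecord],
    alpha: float = DEFAULT_ALPHA,
    line_id: str = "",
    gene_or_mirna: str = "",
) -> ScreenLineResult:
    """Compare a screen line to its control and label the direction.

    direction = shorten if p < alpha and the line's median survival is below
    the control's; extend if above; none if p >= alpha.  A significant
    result with exactly equal medians is refused as ambiguous.
    """
    test = list(test)
    control = list(control)
    chi2, p = logrank_chi2(test, control)
    med_t = median_survival(km_estimate(test))
    med_c = median_survival(km_estimate(control))
    if p < alpha:
        if med_t < med_c:
            direction = "shorten"
        elif med_t > med_c:
            direction = "extend"
        else:
            raise ValueError(
                f"ambiguous direction for line {line_id!r}: "
                f"p={p:.4g} < alpha but medians are equal ({med_t})"
            )
    else:
        direction = "none"
    return ScreenLineResult(
        line_id=line_id,
        gene_or_mirna=gene_or_mirna,
        chi2=chi2,
        p_value=p,
        median_survival=med_t,
        direction=direction,
    )


def format_p(p: float) -> str:
    """Display convention: 4 decimals, values below 1e-4 shown as <0.0001."""
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4f}"


# ---------------------------------------------------------------------------
# I/O: long-format survival TSV and per-line results TSV


def read_survival_tsv(path) -> dict[str, list[SurvivalRecord]]:
    """Read `subject_id genotype time event` TSV, grouped by genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "genotype": str})
    out: dict[str, list[SurvivalRecord]] = {}
    for row in df.itertuples(index=False):
        rec = SurvivalRecord(
            subject_id=row.subject_id,
            genotype=row.genotype,
            time=float(row.time),
            event=bool(int(row.event)),
        )
        out.setdefault(rec.genotype, []).append(rec)
    return out


def write_results_tsv(results: Sequence[ScreenLineResult], path) -> None:
    df = pd.DataFrame(
        {
            "line_id": [r.line_id for r in results],
            "chi2": [round(r.chi2, 4) for r in results],
            "p": [format_p(r.p_value) for r in results],
            "median": [r.median_survival for r in results],
            "direction": [r.direction for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
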
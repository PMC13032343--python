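"""Disproportionality statistics and the composite signal criterion.

For each (drug, PT) target the pair universe is partitioned into a 2×2
contingency table

===============  ==========  ==========
\\               target PT   other PTs
target drug      a           b
other drugs      c           d
===============  ==========  ==========

over which three frequentist pharmacovigilance indexes are computed:

* **ROR** (reporting odds ratio) ``= ad / bc`` with a 95% Wald
  confidence interval on the log-odds scale,
  ``exp(ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d))``.  The critical
  value is fixed at exactly 1.96 so results are bit-stable across
  platforms.
* **PRR** (proportional reporting ratio) ``= [a/(a+b)] / [c/(c+d)]``.
* **χ²**: the Pearson 2×2 independence statistic,
  ``N(|ad − bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)]`` with the Yates
  continuity term (default; the PRR/χ²/n≥3 triple originates in
  criteria defined on the corrected statistic) or ``N(ad − bc)²/[...]``
  without it.  The Yates subtraction is floored at zero.

A drug–event pair is flagged as a *signal* only when both composite
criteria hold:

a. the lower bound of the ROR 95% CI exceeds 1, and
b. PRR ≥ 2, χ² ≥ 4 and the number of target reports n = a ≥ 3.

Statistics are *undefined* (NaN) rather than raised on degenerate
tables — a zero cell for ROR, an empty margin for PRR or χ² — and an
undefined metric fails its criterion.  An optional Haldane–Anscombe
+0.5 adjustment is available for exploratory output only; the signal
verdict always uses the unadjusted cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .io import PairUniverse
from .pt import PTQuery, _match_mask

Z_95 = 1.96  # fixed critical value, not recomputed from a quantile routine


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 cell counts over the pair universe; ``n = a+b+c+d``."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def adjusted(self, delta: float = 0.5) -> tuple[float, float, float, float]:
        """Haldane–Anscombe continuity adjustment (exploratory only)."""
        return (self.a + delta, self.b + delta, self.c + delta, self.d + delta)


@dataclass(frozen=True)
class SignalMetrics:
    """ROR with 95% CI, PRR, χ² and the target report count n (= a)."""

    ror: float
    ci_low: float
    ci_high: float
    prr: float
    chi2: float
    n: int


@dataclass(frozen=True)
class SignalCriteria:
    """Composite signal-detection thresholds.

    Defaults follow the standard frequentist convention: CI lower
    bound > 1 (criterion a); PRR ≥ 2, χ² ≥ 4 and n ≥ 3 (criterion b).
    """

    ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    n_min: int = 3


@dataclass(frozen=True)
class SignalResult:
    drug_name: str
    pt_name: str
    table: ContingencyTable
    metrics: SignalMetrics
    criterion_a: bool
    criterion_b: bool

    @property
    def signal(self) -> bool:
        return self.criterion_a and self.criterion_b


def build_contingency(
    universe: PairUniverse,
    drug_name: str,
    pt_query: PTQuery,
    match_on: Literal["code", "name", "either"] = "either",
) -> ContingencyTable:
    """Partition the pair universe into the 2×2 table for one target.

    A drug absent from the universe yields a=b=0 (not an error); the
    four cells always sum to the universe's n_total.
    """
    pairs = universe.pairs
    is_drug = pairs["drug_name"].eq(drug_name)
    is_pt = _match_mask(pairs, pt_query, match_on)
    a = int((is_drug & is_pt).sum())
    b = int((is_drug & ~is_pt).sum())
    c = int((~is_drug & is_pt).sum())
    d = int((~is_drug & ~is_pt).sum())
    return ContingencyTable(a, b, c, d)


def compute_ror(
    table: ContingencyTable,
    zero_cell_policy: Literal["undefined", "haldane"] = "undefined",
) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% Wald CI on the log scale.

    Under the default policy any zero cell makes all three values NaN;
    the ``haldane`` policy adds 0.5 to every cell first (exploratory
    use only — the signal verdict never sees adjusted cells).
    """
    cells = (table.a, table.b, table.c, table.d)
    if min(cells) == 0:
        if zero_cell_policy == "undefined":
            return (math.nan, math.nan, math.nan)
        cells = table.adjusted()
    a, b, c, d = (float(x) for x in cells)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return (ror, math.exp(log_ror - Z_95 * se), math.exp(log_ror + Z_95 * se))


def compute_prr(table: ContingencyTable) -> float:
    """Proportional reporting ratio; NaN when a margin makes it undefined."""
    if table.a + table.b == 0 or table.c == 0:
        return math.nan
    return (table.a / (table.a + table.b)) / (table.c / (table.c + table.d))


def compute_chi_squared(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson 2×2 χ², optionally Yates-corrected (default).

    NaN when any margin is zero (the statistic is undefined under
    independence with a degenerate margin).  The Yates subtraction
    ``|ad − bc| − N/2`` is floored at zero.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])


def compute_metrics(
    table: ContingencyTable,
    yates: bool = True,
    zero_cell_policy: Literal["undefined", "haldane"] = "undefined",
) -> SignalMetrics:
    ror, lo, hi = compute_ror(table, zero_cell_policy)
    return SignalMetrics(
        ror=ror,
        ci_low=lo,
        ci_high=hi,
        prr=compute_prr(table),
        chi2=compute_chi_squared(table, yates=yates),
        n=table.a,
    )


def evaluate_criteria(
    metrics: SignalMetrics, criteria: SignalCriteria = SignalCriteria()
) -> tuple[bool, bool, bool]:
    """Apply the composite thresholds; NaN metrics fail their criterion.

    Returns ``(criterion_a, criterion_b, signal)`` with
    ``signal = criterion_a and criterion_b``.
    """
    crit_a = not math.isnan(metrics.ci_low) and metrics.ci_low > criteria.ci_low_gt
    crit_b = (
        not math.isnan(metrics.prr)
        and not math.isnan(metrics.chi2)
        and metrics.prr >= criteria.prr_min
        and metrics.chi2 >= criteria.chi2_min
        and metrics.n >= criteria.n_min
    )
    return crit_a, crit_b, crit_a and crit_b


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs for :func:`detect_signals`; defaults match the standard run."""

    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    yates: bool = True
    zero_cell_policy: Literal["undefined", "haldane"] = "undefined"
    match_on: Literal["code", "name", "either"] = "either"
    min_report_floor: int = 1


def detect_signals(
    universe: PairUniverse,
    queries: Sequence[PTQuery],
    config: DetectionConfig = DetectionConfig(),
) -> list[SignalResult]:
    """Score every drug co-reported with each queried PT.

    Emits one :class:`SignalResult` per (drug, PT) with
    a ≥ ``min_report_floor``; drugs never co-reported with the PT are
    omitted rather than emitted as non-signals.  Order is deterministic:
    query order, then descending a, then drug name.
    """
    pairs = universe.pairs
    results: list[SignalResult] = []
    for q in queries:
        is_pt = _match_mask(pairs, q, config.match_on)
        n_pt = int(is_pt.sum())
        counts = (
            pairs.loc[is_pt, "drug_name"].value_counts()
            if n_pt
            else pd.Series(dtype=int)
        )
        drug_totals = pairs["drug_name"].value_counts()
        for drug in sorted(counts.index, key=lambda x: (-counts[x], x)):
            a = int(counts[drug])
            if a < config.min_report_floor:
                continue
            b = int(drug_totals[drug]) - a
            c = n_pt - a
            d = universe.n_total - a - b - c
            table = ContingencyTable(a, b, c, d)
            metrics = compute_metrics(
                table, yates=config.yates, zero_cell_policy=config.zero_cell_policy
            )
            crit_a, crit_b, _ = evaluate_criteria(metrics, config.criteria)
            results.append(
                SignalResult(
                    drug_name=drug,
                    pt_name=q.pt_name,
                    table=table,
                    metrics=metrics,
                    criterion_a=crit_a,
                    criterion_b=crit_b,
                )
            )
    return results


def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten signal results into the report-table schema."""
    rows = []
    for r in results:
        rows.append(
            {
                "drug_name": r.drug_name,
                "pt_name": r.pt_name,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.metrics.ror,
                "ci_low": r.metrics.ci_low,
                "ci_high": r.metrics.ci_high,
                "prr": r.metrics.prr,
                "chi2": r.metrics.chi2,
                "n": r.metrics.n,
                "criterion_a": r.criterion_a,
                "criterion_b": r.criterion_b,
                "signal": r.signal,
            }
        )
    cols = [
        "drug_name", "pt_name", "a", "b", "c", "d", "ror", "ci_low",
        "ci_high", "prr", "chi2", "n", "criterion_a", "criterion_b", "signal",
    ]
    return pd.DataFrame(rows, columns=cols)
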
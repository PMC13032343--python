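"""Independent brute-force oracles used by the test suite.

These re-derive every quantity along a different route from the
implementation: exact rational arithmetic (``fractions.Fraction``) for
the proportional reporting ratio, the chi-squared statistic and the
composite verdict; the expected-count formulation Σ(|O−E|−corr)²/E for
chi-squared; and a cell-array log-space evaluation for the reporting
odds ratio.  A separate naive dictionary join rebuilds the pair
universe from raw records.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

NAN = float("nan")


def oracle_ror_ci(a: int, b: int, c: int, d: int):
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        return NAN, NAN, NAN
    log_ror = np.log(cells[0]) - np.log(cells[1]) - np.log(cells[2]) + np.log(cells[3])
    half = 1.96 * math.sqrt(float((1.0 / cells).sum()))
    return (
        float(np.exp(log_ror)),
        float(np.exp(log_ror - half)),
        float(np.exp(log_ror + half)),
    )


def oracle_prr(a: int, b: int, c: int, d: int):
    if a + b == 0 or c == 0:
        return NAN
    return float(Fraction(a, a + b) / Fraction(c, c + d))


def oracle_prr_exact(a: int, b: int, c: int, d: int) -> Fraction | None:
    if a + b == 0 or c == 0:
        return None
    return Fraction(a, a + b) / Fraction(c, c + d)


def oracle_chi2_exact(a: int, b: int, c: int, d: int, yates: bool) -> Fraction | None:
    """Exact rational chi-squared via the Σ(|O−E|−corr)²/E formulation."""
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if 0 in rows or 0 in cols:
        return None
    obs = ((a, b), (c, d))
    total = Fraction(0)
    for i in range(2):
        for j in range(2):
            e = Fraction(rows[i] * cols[j], n)
            dev = abs(Fraction(obs[i][j]) - e)
            if yates:
                dev = max(dev - Fraction(1, 2), Fraction(0))
            total += dev * dev / e
    return total


def oracle_chi2(a: int, b: int, c: int, d: int, yates: bool):
    exact = oracle_chi2_exact(a, b, c, d, yates)
    return NAN if exact is None else float(exact)


def oracle_verdict(
    a: int,
    b: int,
    c: int,
    d: int,
    yates: bool = True,
) -> tuple[bool, bool, bool]:
    """Composite criterion evaluated with exact arithmetic wherever the
    statistic is rational."""
    _, ci_low, _ = oracle_ror_ci(a, b, c, d)
    crit_a = not math.isnan(ci_low) and ci_low > 1.0
    prr = oracle_prr_exact(a, b, c, d)
    chi2 = oracle_chi2_exact(a, b, c, d, yates)
    crit_b = (
        prr is not None
        and chi2 is not None
        and prr >= 2
        and chi2 >= 4
        and a >= 3
    )
    return crit_a, crit_b, crit_a and crit_b


def brute_force_pairs(drug_rows, reac_rows) -> set[tuple[str, str, str]]:
    """Naive single-pass join: dict of case → suspected drug set and
    case → PT set, then the cross product, as a set of triples.

    ``drug_rows`` / ``reac_rows`` are iterables of dicts carrying the
    canonical field names, already deduplicated to one version.
    """
    drugs_by_case: dict[str, set[str]] = {}
    pts_by_case: dict[str, set[str]] = {}
    for r in drug_rows:
        if r["role"] == "suspected":
            drugs_by_case.setdefault(r["case_id"], set()).add(r["drug_name"])
    for r in reac_rows:
        pts_by_case.setdefault(r["case_id"], set()).add(r["pt_name"])
    out = set()
    for case, ds in drugs_by_case.items():
        for drug in ds:
            for pt in pts_by_case.get(case, ()):
                out.add((case, drug, pt))
    return out
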
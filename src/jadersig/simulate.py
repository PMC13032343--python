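"""Synthetic spontaneous-report generator with planted associations.

Emits JADER-format drug and reaction tables with known statistical
structure so every pipeline stage can be verified without the real
database:

* each case carries a zero-truncated-Poisson number of drug records,
  drawn from a popularity-weighted catalog *with replacement* (repeat
  draws become distinct ``drug_seq`` rows of the same drug, which the
  pair-uniqueness rule downstream must collapse);
* each drug record carries a role (suspected / concomitant /
  interacting) drawn from a configurable mix;
* each Preferred Term occurs independently per case at its background
  rate, except *planted* drug–event associations, where the event
  probability is ``p1`` when the case carries the drug as suspected
  and ``p0`` otherwise — the implied reporting odds ratio is
  ``[p1/(1−p1)] / [p0/(1−p0)]``;
* a case that would otherwise have no event receives one fallback
  event drawn from the non-planted PTs (every reported case has at
  least one reaction row), so planted odds ratios are never diluted;
* a configurable fraction of cases is emitted twice with an
  incremented version number and otherwise identical content,
  exercising deduplication.

The with-replacement draw is what makes the truth registry exact: the
probability that a case carries drug D as suspected has the closed
form ``1 − (1 − w_D·r_s)^k`` given ``k`` draws (``w_D`` the
normalized popularity weight, ``r_s`` the suspected-role
probability), so expected cell counts are pure functions of the
configuration, with no sampling.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import poisson

from . import io as jio
from .dialects import ROLES
from .io import PairUniverse, link_drug_event, normalize_name
from .pt import PTQuery
from .stats import (
    DetectionConfig,
    build_contingency,
    compute_metrics,
    evaluate_criteria,
)


class DrugSpec(BaseModel):
    name: str
    category_code: str = "119"
    weight: float = Field(gt=0)


class PTSpec(BaseModel):
    name: str
    code: str = Field(pattern=r"^[0-9]{8}$")
    background_rate: float = Field(gt=0, lt=1)


class PlantedAssociation(BaseModel):
    """One true drug–event association with per-case event probabilities."""

    drug_name: str
    pt_name: str
    p1: float = Field(gt=0, lt=1)  # P(event | case carries drug as suspected)
    p0: float = Field(gt=0, lt=1)  # P(event | otherwise)

    @property
    def implied_or(self) -> float:
        return (self.p1 / (1 - self.p1)) / (self.p0 / (1 - self.p0))


class SimulationConfig(BaseModel):
    """Full description of one synthetic reporting population."""

    n_cases: int = Field(gt=0)
    drug_catalog: list[DrugSpec]
    pt_catalog: list[PTSpec]
    planted: list[PlantedAssociation] = []
    drugs_per_case_lambda: float = Field(default=1.0, gt=0)
    role_mix: tuple[float, float, float] = (0.55, 0.40, 0.05)
    duplicate_rate: float = Field(default=0.0, ge=0, lt=1)
    seed: int = 0
    dialect: Literal["ascii", "japanese"] = "ascii"

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.drug_catalog:
            raise ValueError("drug_catalog must be non-empty")
        if not self.pt_catalog:
            raise ValueError("pt_catalog must be non-empty")
        names = [d.name for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("drug_catalog names must be unique")
        pt_names = [p.name for p in self.pt_catalog]
        if len(set(pt_names)) != len(pt_names):
            raise ValueError("pt_catalog names must be unique")
        if abs(sum(self.role_mix) - 1.0) > 1e-9:
            raise ValueError("role_mix must sum to 1")
        planted_pts = [pl.pt_name for pl in self.planted]
        if len(set(planted_pts)) != len(planted_pts):
            raise ValueError("each pt_name may appear in at most one planted association")
        for pl in self.planted:
            if pl.drug_name not in names:
                raise ValueError(f"planted drug_name {pl.drug_name!r} not in drug_catalog")
            if pl.pt_name not in pt_names:
                raise ValueError(f"planted pt_name {pl.pt_name!r} not in pt_catalog")
        if len(set(planted_pts)) >= len(pt_names):
            raise ValueError("pt_catalog needs at least one non-planted PT (fallback pool)")
        return self

    # -- pure expectation helpers -------------------------------------

    def _k_pmf(self, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
        """Support and pmf of the zero-truncated Poisson drug count."""
        lam = self.drugs_per_case_lambda
        kmax = int(poisson.ppf(1 - tol, lam)) + 1
        ks = np.arange(1, max(kmax, 2) + 1)
        pmf = poisson.pmf(ks, lam) / (1 - math.exp(-lam))
        return ks, pmf

    def p_case_has_suspected(self, drug_name: str) -> float:
        """P(a case carries ``drug_name`` with the suspected role)."""
        weights = np.array([d.weight for d in self.drug_catalog], float)
        w = weights / weights.sum()
        i = [d.name for d in self.drug_catalog].index(drug_name)
        per_draw = w[i] * self.role_mix[0]
        ks, pmf = self._k_pmf()
        return float(np.sum(pmf * (1 - (1 - per_draw) ** ks)))

    def expected_unique_suspected(self) -> float:
        """E[# distinct suspected drug names per case]."""
        weights = np.array([d.weight for d in self.drug_catalog], float)
        w = weights / weights.sum()
        ks, pmf = self._k_pmf()
        per_draw = w * self.role_mix[0]
        # sum over drugs of P(drug suspected | k), weighted by pmf of k
        return float(np.sum(pmf[:, None] * (1 - (1 - per_draw[None, :]) ** ks[:, None])))


@dataclass(frozen=True)
class PlantedPairTruth:
    drug_name: str
    pt_name: str
    p1: float
    p0: float
    implied_or: float
    expected_a: float


@dataclass(frozen=True)
class PlantedTruth:
    """Exact expectations implied by a configuration (no sampling)."""

    n_cases: int
    expected_role_counts: dict[str, float]
    expected_pt_pairs_no_fallback: dict[str, float]
    planted: tuple[PlantedPairTruth, ...]


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    """Closed-form expectations for a configuration.

    ``expected_a`` for a planted pair is
    ``n_cases · P(case carries the drug as suspected) · p1`` — exact
    because the fallback event never selects a planted PT.  Per-PT pair
    expectations ignore the fallback top-up (they are exact for
    configurations whose event rates make empty cases rare) and, for a
    planted PT, condition only on the background arm, so they are
    reported for non-planted PTs only.
    """
    lam = config.drugs_per_case_lambda
    e_k = lam / (1 - math.exp(-lam))
    expected_roles = {
        role: config.n_cases * e_k * p for role, p in zip(ROLES, config.role_mix)
    }
    e_s = config.expected_unique_suspected()
    planted_pts = {pl.pt_name for pl in config.planted}
    expected_pt = {
        normalize_name(p.name): config.n_cases * e_s * p.background_rate
        for p in config.pt_catalog
        if p.name not in planted_pts
    }
    rows = tuple(
        PlantedPairTruth(
            drug_name=normalize_name(pl.drug_name),
            pt_name=normalize_name(pl.pt_name),
            p1=pl.p1,
            p0=pl.p0,
            implied_or=pl.implied_or,
            expected_a=config.n_cases * config.p_case_has_suspected(pl.drug_name) * pl.p1,
        )
        for pl in config.planted
    )
    return PlantedTruth(
        n_cases=config.n_cases,
        expected_role_counts=expected_roles,
        expected_pt_pairs_no_fallback=expected_pt,
        planted=rows,
    )


# ---------------------------------------------------------------------
# sampling


def _truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    u = rng.uniform(size=n)
    q = math.exp(-lam) + u * (1 - math.exp(-lam))
    return np.maximum(poisson.ppf(q, lam).astype(int), 1)


def simulate_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one dataset; returns canonical drug/reac frames plus the
    realized truth registry (the generator's own independent
    bookkeeping of what it emitted, used as the oracle for pipeline
    stage counts)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = np.array([normalize_name(d.name) for d in config.drug_catalog])
    weights = np.array([d.weight for d in config.drug_catalog], float)
    w = weights / weights.sum()
    pt_names = np.array([normalize_name(p.name) for p in config.pt_catalog])
    pt_codes = np.array([p.code for p in config.pt_catalog])
    rates = np.array([p.background_rate for p in config.pt_catalog], float)
    n_pts = len(pt_names)

    k = _truncated_poisson(rng, config.drugs_per_case_lambda, n)
    kmax = int(k.max())
    draws = rng.choice(len(drug_names), size=(n, kmax), p=w)
    roles = rng.choice(3, size=(n, kmax), p=np.array(config.role_mix))
    active = np.arange(kmax)[None, :] < k[:, None]

    # event probabilities, with planted overrides keyed on suspected carriage
    prob = np.tile(rates, (n, 1))
    name_to_di = {normalize_name(d.name): i for i, d in enumerate(config.drug_catalog)}
    name_to_pj = {normalize_name(p.name): j for j, p in enumerate(config.pt_catalog)}
    planted_pjs = set()
    has_suspected: dict[int, np.ndarray] = {}
    for pl in config.planted:
        di = name_to_di[normalize_name(pl.drug_name)]
        pj = name_to_pj[normalize_name(pl.pt_name)]
        planted_pjs.add(pj)
        if di not in has_suspected:
            has_suspected[di] = ((draws == di) & (roles == 0) & active).any(axis=1)
        prob[:, pj] = np.where(has_suspected[di], pl.p1, pl.p0)
    events = rng.uniform(size=(n, n_pts)) < prob

    # fallback: every case must carry at least one reaction row
    empty = ~events.any(axis=1)
    if empty.any():
        eligible = np.array([j for j in range(n_pts) if j not in planted_pjs])
        fw = rates[eligible] / rates[eligible].sum()
        chosen = rng.choice(eligible, size=int(empty.sum()), p=fw)
        events[np.flatnonzero(empty), chosen] = True

    case_ids = np.array([f"C{i + 1:06d}" for i in range(n)])

    # drug table rows (version 1), case-major order
    row_case = np.repeat(np.arange(n), k)
    seqs = np.concatenate([np.arange(1, ki + 1) for ki in k])
    flat_mask = active.ravel()
    drug_rows = pd.DataFrame(
        {
            "case_id": case_ids[row_case],
            "version": 1,
            "drug_seq": seqs,
            "role": np.array(ROLES)[roles.ravel()[flat_mask]],
            "drug_name": drug_names[draws.ravel()[flat_mask]],
        }
    )

    ev_case, ev_pt = np.nonzero(events)
    reac_rows = pd.DataFrame(
        {
            "case_id": case_ids[ev_case],
            "version": 1,
            "pt_name": pt_names[ev_pt],
            "pt_code": pt_codes[ev_pt],
        }
    )

    # duplicate report versions: identical content, version incremented
    n_dup = int(config.duplicate_rate * n)
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    dup_cases = set(case_ids[dup_idx])
    if n_dup:
        ddup = drug_rows[drug_rows["case_id"].isin(dup_cases)].assign(version=2)
        rdup = reac_rows[reac_rows["case_id"].isin(dup_cases)].assign(version=2)
        drug_rows = pd.concat([drug_rows, ddup], ignore_index=True)
        reac_rows = pd.concat([reac_rows, rdup], ignore_index=True)
        drug_rows = drug_rows.sort_values(
            ["case_id", "version", "drug_seq"], kind="stable"
        ).reset_index(drop=True)
        reac_rows = reac_rows.sort_values(
            ["case_id", "version", "pt_name"], kind="stable"
        ).reset_index(drop=True)

    # --- independent bookkeeping (arrays, not the pipeline's join) ---
    suspected_mask = (roles == 0) & active
    uniq_s = np.zeros(n, dtype=int)
    for i in range(n):  # per-case distinct suspected drug names
        uniq_s[i] = len(set(draws[i, suspected_mask[i]]))
    ev_per_case = events.sum(axis=1)
    n_pairs_total = int((uniq_s * ev_per_case).sum())
    per_pt_pairs = {
        str(pt_names[j]): int((uniq_s * events[:, j]).sum()) for j in range(n_pts)
    }
    role_counts = {
        role: int(((roles == r) & active).sum()) for r, role in enumerate(ROLES)
    }
    truth_planted = []
    exp = planted_truth(config)
    for pl, row in zip(config.planted, exp.planted):
        di = name_to_di[normalize_name(pl.drug_name)]
        pj = name_to_pj[normalize_name(pl.pt_name)]
        realized_a = int((has_suspected[di] & events[:, pj]).sum())
        truth_planted.append(
            {
                "drug_name": row.drug_name,
                "pt_name": row.pt_name,
                "p1": pl.p1,
                "p0": pl.p0,
                "implied_or": row.implied_or,
                "expected_a": row.expected_a,
                "realized_a": realized_a,
            }
        )

    registry = {
        "n_cases": n,
        "retained_cases": n,
        "duplicate_cases": n_dup,
        "role_counts": role_counts,
        "n_drug_rows": int(k.sum()),
        "n_reac_rows": int(events.sum()),
        "n_drug_rows_written": len(drug_rows),
        "n_reac_rows_written": len(reac_rows),
        "n_pairs_total": n_pairs_total,
        "per_pt_pairs": per_pt_pairs,
        "planted": truth_planted,
    }
    return drug_rows, reac_rows, registry


@dataclass(frozen=True)
class GeneratedFiles:
    drug_path: Path
    reac_path: Path
    truth_path: Path


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> GeneratedFiles:
    """Write one dataset as dialect CSVs plus a JSON truth registry.

    Identical (config, seed) produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drug_df, reac_df, registry = simulate_tables(config)
    paths = GeneratedFiles(out / "drug.csv", out / "reac.csv", out / "truth.json")
    jio.write_table(drug_df, paths.drug_path, "drug", config.dialect)
    jio.write_table(reac_df, paths.reac_path, "reac", config.dialect)
    paths.truth_path.write_text(
        json.dumps(registry, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


# ---------------------------------------------------------------------
# operating characteristics of the composite criterion


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo error rates of the composite signal criterion."""

    n_reps: int
    false_positive_rate: float | None
    fpr_se: float | None
    sensitivity: float | None
    sensitivity_se: float | None
    ci_coverage: float | None
    coverage_se: float | None
    mean_log_ror: float | None  # over planted pairs with defined ROR


def _rate_se(hits: int, total: int) -> tuple[float, float]:
    p = hits / total
    return p, math.sqrt(p * (1 - p) / total)


def pair_universe_from_config(config: SimulationConfig) -> tuple[PairUniverse, dict]:
    """Generate one dataset in memory and push it through the pipeline
    stages (dedup → suspected filter → link)."""
    drug_df, reac_df, registry = simulate_tables(config)
    drugs = jio.deduplicate_cases(drug_df)
    events = jio.deduplicate_cases(reac_df)
    universe = link_drug_event(jio.filter_suspected(drugs), events)
    return universe, registry


def null_candidate_pairs(
    config: SimulationConfig, min_expected_a: float = 3.0
) -> list[tuple[str, str]]:
    """Non-planted (drug, PT) combinations whose expected pair count
    under the configuration reaches ``min_expected_a``."""
    planted = {
        (normalize_name(p.drug_name), normalize_name(p.pt_name)) for p in config.planted
    }
    planted_pts = {normalize_name(p.pt_name) for p in config.planted}
    out = []
    for d in config.drug_catalog:
        p_drug = config.p_case_has_suspected(d.name)
        for p in config.pt_catalog:
            key = (normalize_name(d.name), normalize_name(p.name))
            if key in planted or key[1] in planted_pts:
                continue
            if config.n_cases * p_drug * p.background_rate >= min_expected_a:
                out.append(key)
    return out


def estimate_operating_characteristics(
    config: SimulationConfig,
    n_reps: int,
    seed: int,
    detection: DetectionConfig = DetectionConfig(),
) -> OperatingCharacteristics:
    """Repeatedly simulate and analyze to measure the criterion's
    false-positive rate (among null candidate pairs with expected
    a ≥ 3), sensitivity (planted pairs flagged) and 95%-CI coverage of
    the implied odds ratio.

    Rates carry binomial Monte-Carlo standard errors; absent quantities
    (e.g. sensitivity with no planted pairs) are None.
    """
    if n_reps < 50:
        raise ValueError("n_reps must be at least 50 for stable rate estimates")
    pt_code = {normalize_name(p.name): p.code for p in config.pt_catalog}
    null_pairs = null_candidate_pairs(config)
    planted = [
        (normalize_name(p.drug_name), normalize_name(p.pt_name), p.implied_or)
        for p in config.planted
    ]
    children = np.random.SeedSequence(seed).spawn(n_reps)
    fp = fp_tot = hit = hit_tot = cov = cov_tot = 0
    log_rors: list[float] = []
    for child in children:
        rep_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
        cfg = config.model_copy(update={"seed": rep_seed})
        universe, _ = pair_universe_from_config(cfg)
        for drug, pt, true_or in planted:
            table = build_contingency(universe, drug, PTQuery(pt, pt_code[pt]))
            metrics = compute_metrics(
                table, yates=detection.yates, zero_cell_policy=detection.zero_cell_policy
            )
            _, _, is_signal = evaluate_criteria(metrics, detection.criteria)
            hit += int(is_signal)
            hit_tot += 1
            cov_tot += 1
            if not math.isnan(metrics.ci_low):
                cov += int(metrics.ci_low <= true_or <= metrics.ci_high)
                log_rors.append(math.log(metrics.ror))
        for drug, pt in null_pairs:
            table = build_contingency(universe, drug, PTQuery(pt, pt_code[pt]))
            metrics = compute_metrics(
                table, yates=detection.yates, zero_cell_policy=detection.zero_cell_policy
            )
            _, _, is_signal = evaluate_criteria(metrics, detection.criteria)
            fp += int(is_signal)
            fp_tot += 1
    fpr, fpr_se = _rate_se(fp, fp_tot) if fp_tot else (None, None)
    sens, sens_se = _rate_se(hit, hit_tot) if hit_tot else (None, None)
    coverage, coverage_se = _rate_se(cov, cov_tot) if cov_tot else (None, None)
    return OperatingCharacteristics(
        n_reps=n_reps,
        false_positive_rate=fpr,
        fpr_se=fpr_se,
        sensitivity=sens,
        sensitivity_se=sens_se,
        ci_coverage=coverage,
        coverage_se=coverage_se,
        mean_log_ror=float(np.mean(log_rors)) if log_rors else None,
    )


# ---------------------------------------------------------------------
# preset study conditions


def _zipf_weights(n: int) -> list[float]:
    return [1.0 / r for r in range(1, n + 1)]


_BACKGROUND_PTS = [
    ("Nausea", "10028813", 0.08),
    ("Rash", "10037844", 0.05),
    ("Pyrexia", "10037660", 0.04),
    ("Headache", "10019211", 0.03),
    ("Diarrhoea", "10012735", 0.02),
]

_TARGET_PTS = [
    ("Appetite disorder", "10060961", 0.002),
    ("Decreased appetite", "10061428", 0.010),
    ("Abnormal loss of weight", "10000159", 0.002),
    ("Ageusia", "10001480", 0.004),
    ("Dysgeusia", "10013911", 0.008),
    ("Hypogeusia", "10020989", 0.002),
    ("Taste disorder", "10082490", 0.006),
]


def _pt_specs(entries) -> list[PTSpec]:
    return [PTSpec(name=n, code=c, background_rate=r) for n, c, r in entries]


def _p1_for_or(true_or: float, p0: float) -> float:
    odds1 = true_or * p0 / (1 - p0)
    return odds1 / (1 + odds1)


def nutrition_default_config(seed: int = 0) -> SimulationConfig:
    """A realistic mixed-population preset: 2,000 cases, a 20-drug
    Zipf-popularity catalog (two antineoplastics), the seven
    nutrition-related target PTs plus five background PTs, mixed drug
    roles, 10% duplicate reports, and two planted associations
    (a strong appetite signal and a moderate taste signal)."""
    drugs = [
        DrugSpec(
            name=f"drug{i:02d}",
            category_code="421" if i in (3, 11) else f"{110 + 7 * i}",
            weight=wt,
        )
        for i, wt in enumerate(_zipf_weights(20))
    ]
    return SimulationConfig(
        n_cases=2000,
        drug_catalog=drugs,
        pt_catalog=_pt_specs(_TARGET_PTS + _BACKGROUND_PTS),
        planted=[
            PlantedAssociation(
                drug_name="drug02", pt_name="Decreased appetite",
                p1=_p1_for_or(8.0, 0.010), p0=0.010,
            ),
            PlantedAssociation(
                drug_name="drug05", pt_name="Dysgeusia",
                p1=_p1_for_or(6.0, 0.008), p0=0.008,
            ),
        ],
        drugs_per_case_lambda=1.0,
        role_mix=(0.55, 0.40, 0.05),
        duplicate_rate=0.10,
        seed=seed,
    )


def single_association_config(
    seed: int = 0,
    n_cases: int = 5000,
    true_or: float = 5.0,
    p0: float = 0.01,
    target_a: float = 20.0,
) -> SimulationConfig:
    """Estimator-isolation preset: near-single-drug suspected-only
    reports with one planted pair, sized so the expected target cell
    is ``target_a``.  Used for parameter-recovery and CI-coverage
    studies, where co-suspected-drug contamination of the comparator
    cell must stay negligible."""
    lam = 0.05
    p1 = _p1_for_or(true_or, p0)
    e_k = lam / (1 - math.exp(-lam))
    # solve 1-(1-w)^k ≈ w·E[k] for the planted drug's inclusion probability
    q_needed = target_a / (n_cases * p1)
    w_planted = q_needed / e_k
    if not 0 < w_planted < 0.5:
        raise ValueError("target_a unreachable under this design")
    others = _zipf_weights(14)
    scale = (1 - w_planted) / sum(others)
    drugs = [DrugSpec(name="targetdrug", category_code="119", weight=w_planted)] + [
        DrugSpec(name=f"bg{i:02d}", category_code=f"{200 + 9 * i}", weight=wt * scale)
        for i, wt in enumerate(others)
    ]
    return SimulationConfig(
        n_cases=n_cases,
        drug_catalog=drugs,
        pt_catalog=_pt_specs(_TARGET_PTS + _BACKGROUND_PTS),
        planted=[
            PlantedAssociation(
                drug_name="targetdrug", pt_name="Decreased appetite", p1=p1, p0=p0
            )
        ],
        drugs_per_case_lambda=lam,
        role_mix=(1.0, 0.0, 0.0),
        duplicate_rate=0.0,
        seed=seed,
    )


def all_null_config(seed: int = 0, n_cases: int = 2000) -> SimulationConfig:
    """Independence preset: no planted associations, event rates high
    enough that several (drug, PT) combinations have expected pair
    counts ≥ 3 and therefore qualify as false-positive candidates."""
    drugs = [
        DrugSpec(name=f"drug{i:02d}", category_code=f"{110 + 7 * i}", weight=wt)
        for i, wt in enumerate(_zipf_weights(15))
    ]
    pts = _pt_specs(
        [
            ("Decreased appetite", "10061428", 0.030),
            ("Dysgeusia", "10013911", 0.020),
            ("Taste disorder", "10082490", 0.020),
        ]
        + _BACKGROUND_PTS
    )
    return SimulationConfig(
        n_cases=n_cases,
        drug_catalog=drugs,
        pt_catalog=pts,
        planted=[],
        drugs_per_case_lambda=1.0,
        role_mix=(0.60, 0.35, 0.05),
        duplicate_rate=0.0,
        seed=seed,
    )


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
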
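"""Paired-cohort aggregation and statistics for two nail designs.

Every specimen receives both nails (a fully paired design), so the cohort
table is indexed by specimen id with one fitness report per nail. Outputs
mirror the study-style summary: per-region impingement incidence with a
chi-square / Fisher comparison, and per-metric mean ± SD with a paired
comparison ("repeated measures" over the two conditions is interpreted as a
paired t-test; a Wilcoxon signed-rank alternative is available).

Conventions: percentages rounded half-up to 1 decimal, mm summaries to
2 decimals; the chi-square statistic is Pearson's without continuity
correction when all expected counts are at least 5, otherwise the two-sided
Fisher exact test is used (statistic = odds ratio). No multiplicity
correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, SchemaError
from .metrics import REGIONS, FitnessReport

#: metric fields summarized per nail, with the region whose impingement
#: defines the row denominator (None = all specimens)
METRIC_FIELDS = (
    ("A_max_thickness_proximal", "proximal"),
    ("B_length_proximal", "proximal"),
    ("C_dist_proximal", "proximal"),
    ("D_protrusion", None),
    ("E_thickness_middle", "middle"),
    ("E_length_middle", "middle"),
    ("F_dist_middle", "middle"),
    ("G_max_gap_middle", None),
    ("H_length_distal", "distal"),
)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (display-precision rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortTable:
    """Paired per-specimen fitness reports for each nail design."""

    specimen_ids: list
    reports: dict    # nail_id -> {specimen_id -> FitnessReport}

    def __post_init__(self):
        for nail, by_spec in self.reports.items():
            missing = [s for s in self.specimen_ids if s not in by_spec]
            if missing:
                raise SchemaError(
                    f"paired design violated: nail {nail!r} lacks reports "
                    f"for specimens {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    @property
    def nails(self) -> list:
        return list(self.reports)

    def converged_ids(self) -> list:
        """Specimens whose placement converged for every nail."""
        return [s for s in self.specimen_ids
                if all(self.reports[n][s].converged for n in self.reports)]

    @classmethod
    def from_reports(cls, reports: list[FitnessReport]) -> "CohortTable":
        by_nail: dict = {}
        ids: list = []
        for r in reports:
            by_nail.setdefault(r.nail_id, {})[r.femur_id] = r
            if r.femur_id not in ids:
                ids.append(r.femur_id)
        return cls(ids, by_nail)


def incidence(table: CohortTable, region: str, nail: str) -> tuple[int, float]:
    """(count, percent) of specimens with impingement in ``region``.

    Percent is 100·count/n rounded half-up to 1 decimal.
    """
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}")
    if nail not in table.reports:
        raise KeyError(f"unknown nail {nail!r}")
    count = sum(bool(table.reports[nail][s].impinged[region])
                for s in table.specimen_ids)
    return count, round_half_up(100.0 * count / table.n, 1)


def compare_incidence(count_a: int, count_b: int, n: int):
    """Compare two incidences over the same n specimens.

    Builds the 2×2 table [[a, n−a], [b, n−b]]; Pearson chi-square (no
    continuity correction) when all expected counts ≥ 5, otherwise the
    two-sided Fisher exact test. Returns (test_name, statistic, p).
    """
    if n <= 0:
        raise InsufficientDataError("n must be positive")
    if not (0 <= count_a <= n and 0 <= count_b <= n):
        raise InsufficientDataError("counts must lie in [0, n]")
    obs = np.array([[count_a, n - count_a], [count_b, n - count_b]], float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    if (expected >= 5).all():
        if count_a == count_b:
            return "chi_square", 0.0, 1.0
        res = sps.chi2_contingency(obs, correction=False)
        return "chi_square", float(res.statistic), float(res.pvalue)
    res = sps.fisher_exact(obs, alternative="two-sided")
    return "fisher_exact", float(res.statistic), float(res.pvalue)


def summarize_metric(values) -> tuple[float | None, float | None, int]:
    """(mean, sample SD, n) of non-null values; SD is None for n < 2."""
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if len(vals) == 0:
        return None, None, 0
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) >= 2 else None
    return mean, sd, len(vals)


def compare_paired(values_a, values_b, method: str = "t"):
    """Paired comparison of two equal-length lists (nulls drop the pair).

    ``method='t'``: paired t-test on per-specimen differences;
    ``method='wilcoxon'``: Wilcoxon signed-rank. Returns
    (test_name, statistic, p, n_pairs). Zero-variance differences are
    handled explicitly: all-zero → (0, 1); constant shift → (±inf, 0).
    """
    if len(values_a) != len(values_b):
        raise InsufficientDataError("paired lists must have equal length")
    pairs = [(a, b) for a, b in zip(values_a, values_b)
             if a is not None and b is not None]
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"need >= 2 complete pairs, got {len(pairs)}")
    a = np.array([p[0] for p in pairs], float)
    b = np.array([p[1] for p in pairs], float)
    d = a - b
    if method == "t":
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                return "paired_t", 0.0, 1.0, len(d)
            return ("paired_t", math_copysign_inf(d.mean()), 0.0, len(d))
        res = sps.ttest_rel(a, b)
        return "paired_t", float(res.statistic), float(res.pvalue), len(d)
    if method == "wilcoxon":
        if np.allclose(d, 0.0):
            return "wilcoxon", 0.0, 1.0, len(d)
        res = sps.wilcoxon(a, b)
        return "wilcoxon", float(res.statistic), float(res.pvalue), len(d)
    raise SchemaError(f"unknown paired method {method!r}")


def math_copysign_inf(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


@dataclass
class CohortSummary:
    """Incidence and metric summary rows mirroring the study tables."""

    n: int
    nails: list
    incidence_rows: list = field(default_factory=list)
    metric_rows: list = field(default_factory=list)
    n_unconverged: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n": self.n, "nails": self.nails,
                "incidence": self.incidence_rows,
                "metrics": self.metric_rows,
                "n_unconverged": self.n_unconverged}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "CohortSummary":
        d = json.loads(s)
        return cls(n=d["n"], nails=d["nails"], incidence_rows=d["incidence"],
                   metric_rows=d["metrics"], n_unconverged=d["n_unconverged"])

    def incidence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence_rows)

    def metric_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metric_rows)

    def to_csv(self, path) -> None:
        rows = []
        for r in self.incidence_rows:
            rows.append({"kind": "incidence", "name": r["region"], **{
                k: v for k, v in r.items() if k != "region"}})
        for r in self.metric_rows:
            rows.append({"kind": "metric", "name": r["metric"], **{
                k: v for k, v in r.items() if k != "metric"}})
        pd.DataFrame(rows).to_csv(path, index=False)


def build_summary(table: CohortTable, paired_method: str = "t"
                  ) -> CohortSummary:
    """Full cohort summary: incidences + tests, metric mean±SD + tests.

    Specimens whose placement did not converge for either nail are excluded
    from metric summaries (their count is reported separately); incidence
    uses all specimens.
    """
    nails = table.nails
    summary = CohortSummary(n=table.n, nails=nails)
    for nail in nails:
        bad = sum(not table.reports[nail][s].converged
                  for s in table.specimen_ids)
        summary.n_unconverged[nail] = bad
    ok_ids = table.converged_ids()

    protrusion_row = {"region": "protrusion"}
    for region in REGIONS:
        row = {"region": region}
        counts = {}
        for nail in nails:
            c, pct = incidence(table, region, nail)
            counts[nail] = c
            row[f"count_{nail}"] = c
            row[f"percent_{nail}"] = pct
        if len(nails) == 2:
            a, b = (counts[n_] for n_ in nails)
            if a == 0 and b == 0:
                row.update(test=None, statistic=None, p=None,
                           note="no impingement in either arm")
            else:
                test, statv, p = compare_incidence(a, b, table.n)
                row.update(test=test, statistic=statv, p=p)
        summary.incidence_rows.append(row)
    # protrusion incidence (D > 0), reported like the regions
    pcounts = {}
    for nail in nails:
        c = sum(table.reports[nail][s].D_protrusion > 0
                for s in table.specimen_ids)
        pcounts[nail] = c
        protrusion_row[f"count_{nail}"] = c
        protrusion_row[f"percent_{nail}"] = round_half_up(
            100.0 * c / table.n, 1)
    if len(nails) == 2:
        a, b = (pcounts[n_] for n_ in nails)
        if a or b:
            test, statv, p = compare_incidence(a, b, table.n)
            protrusion_row.update(test=test, statistic=statv, p=p)
        else:
            protrusion_row.update(test=None, statistic=None, p=None,
                                  note="no protrusion in either arm")
    summary.incidence_rows.append(protrusion_row)

    for metric, _region in METRIC_FIELDS:
        row = {"metric": metric}
        per_nail_values = {}
        for nail in nails:
            vals = [getattr(table.reports[nail][s], metric) for s in ok_ids]
            per_nail_values[nail] = vals
            mean, sd, k = summarize_metric(vals)
            row[f"mean_{nail}"] = None if mean is None else round_half_up(mean, 2)
            row[f"sd_{nail}"] = None if sd is None else round_half_up(sd, 2)
            row[f"n_{nail}"] = k
        if len(nails) == 2:
            va, vb = (per_nail_values[n_] for n_ in nails)
            try:
                test, statv, p, npairs = compare_paired(va, vb, paired_method)
                row.update(test=test, statistic=statv, p=p, n_pairs=npairs)
            except InsufficientDataError as exc:
                row.update(test=None, statistic=None, p=None, note=str(exc))
        summary.metric_rows.append(row)
    return summary
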
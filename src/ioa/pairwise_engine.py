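"""All-pairs interobserver comparison and summary aggregation.

Every unordered pair of observers who submitted a given (case, volume kind)
is compared once with the full metric quartet; pairwise values are then
aggregated into min/max/mean/median/std blocks, per case and pooled across
cases (pooling concatenates pairwise values, it does not average summaries).

Conventions (recorded in the report metadata): the median uses midpoint
interpolation for even counts; the standard deviation is the sample (n-1)
form; infinite probabilistic distances are excluded from mean/std with a
logged warning but participate in min/max/median as the largest value;
values are rounded (half-even, 2 decimals by default) only at serialization.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .agreement_metrics import MetricQuartet, metric_quartet
from .volume_model import (
    VOLUME_KINDS,
    CohortStructureSet,
    GridMismatchError,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("dsc", "hd_mm", "pbd", "vs")
STATISTIC_NAMES = ("minimum", "maximum", "mean", "median", "std")


@dataclass(frozen=True)
class PairwiseResult:
    """Metric quartet for one unordered observer pair."""

    case_id: str
    volume_kind: str
    observer_pair: tuple[str, str]
    quartet: MetricQuartet

    def __post_init__(self) -> None:
        a, b = self.observer_pair
        if a == b:
            raise ValueError("observer pair must consist of two distinct observers")
        if a > b:
            object.__setattr__(self, "observer_pair", (b, a))


@dataclass(frozen=True)
class MetricStats:
    minimum: float
    maximum: float
    mean: float
    median: float
    std: float

    def as_dict(self) -> dict[str, float]:
        return {
            "minimum": self.minimum,
            "maximum": self.maximum,
            "mean": self.mean,
            "median": self.median,
            "std": self.std,
        }


@dataclass(frozen=True)
class AgreementSummary:
    """Five statistics per metric over a set of pairwise results."""

    dsc: MetricStats
    hd_mm: MetricStats
    pbd: MetricStats
    vs: MetricStats
    n_pairs: int

    def metric(self, name: str) -> MetricStats:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc.as_dict(),
            "hd_mm": self.hd_mm.as_dict(),
            "pbd": self.pbd.as_dict(),
            "vs": self.vs.as_dict(),
            "n_pairs": self.n_pairs,
        }


def all_pairs(
    cohort: CohortStructureSet, case_id: str, volume_kind: str
) -> list[PairwiseResult]:
    """Compare every unordered observer pair of one (case, kind) group.

    Returns exactly C(n, 2) results for n submitting observers, each pair
    computed once, in lexicographic pair order.
    """
    records = cohort.group(case_id, volume_kind)
    if len(records) < 2:
        raise ValueError(
            f"case {case_id!r} {volume_kind}: need >= 2 observers for pairwise "
            f"comparison, got {len(records)}"
        )
    for rec in records[1:]:
        problem = records[0].mask.grid.mismatch(rec.mask.grid)
        if problem is not None:
            raise GridMismatchError(
                f"case {case_id!r} {volume_kind}: observers "
                f"{records[0].observer_id!r} and {rec.observer_id!r} are on "
                f"different grids ({problem})"
            )
    results = []
    for ra, rb in combinations(records, 2):
        q = metric_quartet(ra.mask, rb.mask)
        results.append(
            PairwiseResult(case_id, volume_kind, (ra.observer_id, rb.observer_id), q)
        )
    return results


def _stats(values: list[float], metric: str) -> MetricStats:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    n_inf = arr.size - finite.size
    if n_inf:
        logger.warning(
            "%d infinite %s value(s) excluded from mean/std "
            "(kept as largest for min/max/median)",
            n_inf,
            metric,
        )
    if finite.size == 0:
        mean = std = math.inf
    else:
        mean = float(finite.mean())
        std = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    return MetricStats(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=mean,
        median=float(np.median(arr)),
        std=std,
    )


def summarize(results: list[PairwiseResult]) -> AgreementSummary:
    """Aggregate pairwise quartets into the five-statistic summary block."""
    if not results:
        raise ValueError("cannot summarize an empty list of pairwise results")
    per_metric = {}
    for name in METRIC_NAMES:
        values = [getattr(r.quartet, name) for r in results]
        per_metric[name] = _stats(values, name)
    return AgreementSummary(n_pairs=len(results), **per_metric)


def pooled_summary(cohort: CohortStructureSet, volume_kind: str) -> AgreementSummary:
    """Summary over the concatenated pairwise results of all eligible cases."""
    pooled: list[PairwiseResult] = []
    for case_id in cohort.case_ids():
        if len(cohort.group(case_id, volume_kind)) >= 2:
            pooled.extend(all_pairs(cohort, case_id, volume_kind))
    if not pooled:
        raise ValueError(f"no case has >= 2 observers for volume kind {volume_kind!r}")
    return summarize(pooled)


def _volume_stats(records) -> dict:
    volumes = sorted(r.mask.volume_ml for r in records)
    return {
        "median_ml": float(np.median(volumes)),
        "min_ml": float(volumes[0]),
        "max_ml": float(volumes[-1]),
        "n_observers": len(volumes),
    }


def table1_report(cohort: CohortStructureSet) -> dict:
    """Nested agreement report: volume kind -> {pooled, per case} -> statistics.

    Also carries per-case (and pooled) delineated-volume statistics in ml.
    Missing volume kinds appear as absent sections. Values are exact floats;
    rounding happens only in the serializers.
    """
    report: dict = {
        "metadata": {
            "median": "midpoint interpolation for even counts",
            "std": "sample standard deviation (n-1)",
            "infinite_pbd": "excluded from mean/std; largest value for min/max/median",
            "rounding": "half-even at serialization only",
        },
        "volume_kinds": {},
    }
    for kind in cohort.volume_kinds():
        case_blocks = {}
        pooled_results: list[PairwiseResult] = []
        for case_id in cohort.case_ids():
            records = cohort.group(case_id, kind)
            if len(records) < 2:
                if records:
                    logger.warning(
                        "case %s %s: only %d observer(s), omitted from pairwise "
                        "analysis",
                        case_id,
                        kind,
                        len(records),
                    )
                continue
            results = all_pairs(cohort, case_id, kind)
            pooled_results.extend(results)
            case_blocks[case_id] = {
                "summary": summarize(results).as_dict(),
                "volume": _volume_stats(records),
            }
        if not case_blocks:
            continue
        all_records = [
            r for r in cohort.records if r.volume_kind == kind
        ]
        report["volume_kinds"][kind] = {
            "pooled": {
                "summary": summarize(pooled_results).as_dict(),
                "volume": _volume_stats(all_records),
            },
            "cases": case_blocks,
        }
    return report


# ---------------------------------------------------------------------------
# serialization


def _round_value(x: float, decimals: int) -> float | str:
    if isinstance(x, (int, np.integer)):
        return int(x)
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "nan"
    return round(float(x), decimals)


def _round_tree(node, decimals: int):
    if isinstance(node, dict):
        return {k: _round_tree(v, decimals) for k, v in node.items()}
    if isinstance(node, str):
        return node
    return _round_value(node, decimals)


def report_to_json(report: dict, decimals: int = 2) -> str:
    """Serialize a report with half-even rounding to the given decimals."""
    return json.dumps(_round_tree(report, decimals), indent=2, sort_keys=True) + "\n"


def report_to_csv(report: dict, decimals: int = 2) -> str:
    """Flat CSV: volume_kind, scope (all|case id), statistic, metrics, n_pairs."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["volume_kind", "scope", "statistic", "dsc", "hd_mm", "pbd", "vs", "n_pairs"]
    )
    for kind in VOLUME_KINDS:
        block = report.get("volume_kinds", {}).get(kind)
        if block is None:
            continue
        scopes = [("all", block["pooled"])] + [
            (case_id, case_block)
            for case_id, case_block in sorted(block["cases"].items())
        ]
        for scope, sub in scopes:
            summary = sub["summary"]
            for stat in STATISTIC_NAMES:
                writer.writerow(
                    [kind, scope, stat]
                    + [
                        _round_value(summary[m][stat], decimals)
                        for m in METRIC_NAMES
                    ]
                    + [summary["n_pairs"]]
                )
    return buf.getvalue()


def parse_report_csv(text: str) -> dict:
    """Parse :func:`report_to_csv` output back into nested rounded values."""
    reader = csv.DictReader(io.StringIO(text))
    out: dict = {}
    for row in reader:
        scope = out.setdefault(row["volume_kind"], {}).setdefault(row["scope"], {})
        for m in METRIC_NAMES:
            scope.setdefault(m, {})[row["statistic"]] = float(row[m])
        scope["n_pairs"] = int(row["n_pairs"])
    return out


def pairs_to_csv(results: list[PairwiseResult], decimals: int | None = None) -> str:
    """Raw per-pair quartets as CSV; full precision unless decimals given."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["case_id", "volume_kind", "observer_a", "observer_b", "dsc", "hd_mm", "pbd", "vs"]
    )
    for r in results:
        values = [getattr(r.quartet, m) for m in METRIC_NAMES]
        if decimals is not None:
            values = [_round_value(v, decimals) for v in values]
        else:
            values = [
                "inf" if (isinstance(v, float) and math.isinf(v)) else repr(float(v))
                for v in values
            ]
        writer.writerow([r.case_id, r.volume_kind, *r.observer_pair, *values])
    return buf.getvalue()
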
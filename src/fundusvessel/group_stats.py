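"""Per-image aggregation and between-genotype comparison statistics.

Each analysed image is reduced to one value per metric and vessel class:
the mean diameter (mean of the per-vessel mean diameters), the vessel
count, and the *combined diameter* — vessel count times mean diameter, a
proxy for total vascularisation that accounts for eyes differing in vessel
number.  Classes are arteries, veins, and "both" (all vessels including
unlabeled ones).

Group comparisons follow the common two-sample workflow of desktop
statistics packages: Shapiro-Wilk normality on each group at alpha; if both
groups pass, a two-tailed pooled-variance (Student's) t-test, otherwise the
Mann-Whitney rank-sum test (exact where feasible).  Effect sizes are
reported both as a rounded percent-of-reference ratio and as a
percent-increase to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, StatsError
from .radial_scan import VesselMeasurement

LABELS = ("artery", "vein", "both")
METRICS = ("mean_diameter", "vessel_count", "combined_diameter")


@dataclass(frozen=True)
class LabelStats:
    vessel_count: int
    mean_diameter: float        # px; NaN when no vessels of this class
    combined_diameter: float    # count * mean, px


@dataclass(frozen=True)
class ImageResult:
    """One image's aggregate metrics per vessel class."""

    image_id: str
    group_label: str
    per_label: Mapping[str, LabelStats]

    def metric(self, metric: str, label: str) -> float:
        ls = self.per_label[label]
        return float(getattr(ls, metric))


def summarize_image(measurements: Sequence[VesselMeasurement],
                    image_id: str, group_label: str) -> ImageResult:
    """Reduce labeled per-vessel measurements to one ImageResult.

    Unknown-label vessels contribute to the "both" class only.
    """
    if not measurements:
        raise InputError(f"image {image_id}: no vessel measurements to summarise")
    per_label: dict[str, LabelStats] = {}
    for label in LABELS:
        if label == "both":
            means = [m.mean for m in measurements]
        else:
            means = [m.mean for m in measurements if m.label == label]
        n = len(means)
        mean_d = float(np.mean(means)) if n else float("nan")
        combined = n * mean_d if n else 0.0
        per_label[label] = LabelStats(vessel_count=n, mean_diameter=mean_d,
                                      combined_diameter=combined)
    return ImageResult(image_id=image_id, group_label=group_label,
                       per_label=per_label)


# ---------------------------------------------------------------------------
# Percent metrics
# ---------------------------------------------------------------------------

def percent_of_reference(group_mean: float, reference_mean: float) -> int:
    """``round(100 * group / reference)`` — the "% of wild type" ratio."""
    if reference_mean <= 0:
        raise StatsError(f"reference mean must be > 0, got {reference_mean}")
    return int(round(100.0 * group_mean / reference_mean))


def percent_increase(group_mean: float, reference_mean: float) -> float:
    """Percent change of ``group_mean`` over the reference, to one decimal."""
    if reference_mean <= 0:
        raise StatsError(f"reference mean must be > 0, got {reference_mean}")
    return round(100.0 * (group_mean - reference_mean) / reference_mean, 1)


# ---------------------------------------------------------------------------
# Two-group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str                 # reference
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    percent_of_reference: int
    percent_increase: float
    normality_passed: tuple[bool, bool]
    test_used: str               # "t" | "mann_whitney"
    statistic: float
    p_value: float


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def compare_groups(values_a: Iterable[float], values_b: Iterable[float],
                   alpha: float = 0.05, welch: bool = False,
                   metric: str = "", group_a: str = "a", group_b: str = "b",
                   ) -> GroupComparison:
    """Compare two per-image metric samples; group b is the reference.

    Shapiro-Wilk at ``alpha`` gates the test choice: both groups normal ->
    two-tailed t-test (pooled variance unless ``welch``); otherwise
    Mann-Whitney, exact when sample sizes permit (no ties, n small).
    Identical groups yield statistic 0 and p = 1 under the t route.
    """
    a = np.asarray(list(values_a), dtype=np.float64)
    b = np.asarray(list(values_b), dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise StatsError(
            f"need >= 3 values per group, got {a.size} and {b.size}")

    def normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:      # Shapiro is undefined for constant samples
            return True
        return bool(stats.shapiro(x).pvalue >= alpha)

    norm_a, norm_b = normal(a), normal(b)
    if norm_a and norm_b:
        if np.ptp(np.concatenate([a, b])) == 0:
            statistic, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            statistic, p = float(res.statistic), float(res.pvalue)
        test_used = "t"
    else:
        # exact null distribution whenever it is both valid (no ties) and
        # cheap; the normal approximation otherwise
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
        test_used = "mann_whitney"

    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b),
        percent_of_reference=percent_of_reference(a.mean(), b.mean()),
        percent_increase=percent_increase(a.mean(), b.mean()),
        normality_passed=(norm_a, norm_b),
        test_used=test_used, statistic=statistic, p_value=float(p))


# ---------------------------------------------------------------------------
# Genotype report
# ---------------------------------------------------------------------------

def genotype_report(image_results: Sequence[ImageResult],
                    reference_group: str,
                    alpha: float = 0.05, welch: bool = False,
                    holm: bool = False) -> pd.DataFrame:
    """Per-genotype comparison table against a reference group.

    One row per (metric in {mean_diameter, vessel_count, combined_diameter})
    x (vessel class in {artery, vein, both}) x (non-reference group).  Also
    reports, for combined_diameter, the product of the group-level mean
    count and mean diameter (``combined_of_means``) alongside the mean of
    per-image products, since either reading of "mean number x mean
    diameter" can be of interest.  ``holm`` applies a Holm step-down
    adjustment across the table's p-values (off by default, matching
    per-comparison reporting).
    """
    by_group: dict[str, list[ImageResult]] = {}
    for r in image_results:
        by_group.setdefault(r.group_label, []).append(r)
    if reference_group not in by_group:
        raise InputError(f"reference group {reference_group!r} not present "
                         f"(groups: {sorted(by_group)})")
    others = [g for g in by_group if g != reference_group]

    rows = []
    for metric in METRICS:
        for label in LABELS:
            ref_vals = [r.metric(metric, label) for r in by_group[reference_group]]
            for g in others:
                vals = [r.metric(metric, label) for r in by_group[g]]
                cmp_ = compare_groups(vals, ref_vals, alpha=alpha, welch=welch,
                                      metric=metric, group_a=g,
                                      group_b=reference_group)
                row = {
                    "metric": metric, "label": label, "group": g,
                    "reference": reference_group,
                    "n": len(vals), "n_reference": len(ref_vals),
                    "group_mean": cmp_.mean_a, "group_sem": cmp_.sem_a,
                    "reference_mean": cmp_.mean_b, "reference_sem": cmp_.sem_b,
                    "percent_of_reference": cmp_.percent_of_reference,
                    "percent_increase": cmp_.percent_increase,
                    "test_used": cmp_.test_used,
                    "statistic": cmp_.statistic, "p_value": cmp_.p_value,
                }
                if metric == "combined_diameter":
                    row["combined_of_means"] = _combined_of_means(by_group[g], label)
                    row["reference_combined_of_means"] = _combined_of_means(
                        by_group[reference_group], label)
                else:
                    row["combined_of_means"] = np.nan
                    row["reference_combined_of_means"] = np.nan
                rows.append(row)
    df = pd.DataFrame(rows)
    if holm and not df.empty:
        df["p_adjusted"] = _holm(df["p_value"].to_numpy())
    return df


def _combined_of_means(results: list[ImageResult], label: str) -> float:
    counts = [r.metric("vessel_count", label) for r in results]
    means = [r.metric("mean_diameter", label) for r in results]
    return float(np.mean(counts) * np.nanmean(means))


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
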
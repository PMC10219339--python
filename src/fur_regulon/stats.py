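"""Comparative statistics and small closed-form assay computations.

Group comparisons default to Student's pooled-variance t-test (Welch is
available behind ``kind="welch"`` and is the better default when group
variances differ; the pooled test is kept as primary for comparability
with the descriptive convention of the source assays). Fold changes are
handled as linear ratios reconstructed from log2 values, with the sign
carried separately.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    group_names: tuple[str, str]
    ns: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    t_statistic: float
    p_value: float
    test_kind: str

    def as_dict(self) -> dict:
        return {
            "groups": list(self.group_names),
            "n": list(self.ns),
            "mean": list(self.means),
            "sem": list(self.sems),
            "t": self.t_statistic,
            "p": self.p_value,
            "test": self.test_kind,
        }


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p": self.p_value,
            "n": self.n,
        }


@dataclass(frozen=True)
class CategoryTally:
    counts: dict[str, int]
    total: int
    top_category: str | None
    top_share_pct: float

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total": self.total,
            "top_category": self.top_category,
            "top_share_pct": self.top_share_pct,
        }


def _mean_sem(xs: np.ndarray) -> tuple[float, float]:
    n = xs.size
    mean = float(np.mean(xs))
    sem = float(np.std(xs, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem


def two_sample_t(
    xs: Sequence[float],
    ys: Sequence[float],
    kind: str = "student",
    names: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided two-sample t-test with per-group mean and SEM.

    ``student`` pools variances; ``welch`` does not. Two degenerate groups
    with zero variance give t=0, p=1 when means agree and raise otherwise.
    """
    if kind not in ("student", "welch"):
        raise StatsError(f"unknown test kind {kind!r}")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("need at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            t, p = 0.0, 1.0
        else:
            raise StatsError("degenerate: zero variance in both groups, unequal means")
    else:
        t, p = sps.ttest_ind(x, y, equal_var=(kind == "student"))
        t, p = float(t), float(p)
    mx, sx = _mean_sem(x)
    my, sy = _mean_sem(y)
    return GroupComparison(
        group_names=names, ns=(x.size, y.size), means=(mx, my), sems=(sx, sy),
        t_statistic=t, p_value=p, test_kind=kind,
    )


def linear_fold_change(log2fc: float) -> float:
    """Signed linear fold change from a log2 ratio: sign(log2fc) * 2**|log2fc|."""
    return math.copysign(2.0 ** abs(log2fc), log2fc) if log2fc != 0 else 1.0


def mean_abs_fc(values: Iterable[float], log_scale: bool = False) -> dict:
    """Mean and SEM of absolute fold changes.

    ``values`` are log2 fold changes; by default they are converted to
    linear ratios (2**|log2fc|) before averaging, the log2 summary is
    reported alongside.
    """
    l2 = np.abs(np.asarray(list(values), dtype=float))
    if l2.size < 2:
        raise StatsError("need at least 2 fold changes for mean +/- SEM")
    lin = 2.0 ** l2
    mean, sem = _mean_sem(l2 if log_scale else lin)
    mean_l2, sem_l2 = _mean_sem(l2)
    return {
        "mean": mean,
        "sem": sem,
        "n": int(l2.size),
        "mean_log2": mean_l2,
        "sem_log2": sem_l2,
    }


def sign_test(n_above: int, n_below: int) -> float:
    """Two-sided binomial sign test at p=1/2, ties excluded upstream."""
    n = n_above + n_below
    if n == 0:
        return float("nan")
    return float(sps.binomtest(n_above, n, p=0.5, alternative="two-sided").pvalue)


def fc_sensitivity_summary(
    pairs: Sequence[tuple[float, float]],
) -> dict:
    """Iron-sensitivity asymmetry of paired fold changes.

    Each pair is ``(log2fc_minusFe, log2fc_plusFe)`` for one gene. Reports
    the fraction of genes whose absolute change is strictly larger with
    iron than without (points above the y=x diagonal when |fc with iron|
    is on the y axis) and a two-sided sign-test p-value; exact ties sit on
    the diagonal and count for neither side.
    """
    if not pairs:
        return {"n": 0, "frac_larger_with_fe": float("nan"), "sign_test_p": float("nan")}
    above = below = 0
    for fc_minus, fc_plus in pairs:
        if abs(fc_plus) > abs(fc_minus):
            above += 1
        elif abs(fc_plus) < abs(fc_minus):
            below += 1
    n = len(pairs)
    return {
        "n": n,
        "frac_larger_with_fe": above / n,
        "sign_test_p": sign_test(above, below),
    }


def fc_binding_regression(
    abs_fcs: Sequence[float], fold_enrichments: Sequence[float]
) -> RegressionFit:
    """OLS of absolute fold change on binding strength, with Pearson r."""
    x = np.asarray(fold_enrichments, dtype=float)
    y = np.asarray(abs_fcs, dtype=float)
    if x.size != y.size:
        raise StatsError("unpaired inputs")
    if x.size < 3:
        raise StatsError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise StatsError("zero variance in binding strength")
    fit = sps.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), p_value=float(fit.pvalue), n=int(x.size),
    )


def delta_delta_ct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by the ddCt method: 2**-((dCt sample) - (dCt calibrator))."""
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return 2.0 ** (-ddct)


def plate_speed(
    diameters_mm: Sequence[float],
    times_h: Sequence[float],
    mode: str = "diameter",
) -> dict:
    """Swimming speed on soft agar as the OLS slope of zone size vs time.

    ``mode="diameter"`` fits the diameter directly (mm/h); ``mode="radius"``
    fits diameter/2, the conventional radial migration speed.
    """
    if mode not in ("diameter", "radius"):
        raise StatsError(f"unknown mode {mode!r}")
    d = np.asarray(diameters_mm, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if d.size != t.size or d.size < 3:
        raise StatsError("need at least 3 paired timepoints")
    if mode == "radius":
        d = d / 2.0
    if np.allclose(d, d[0]):
        slope, intercept, r, p = 0.0, float(d[0]), 0.0, 1.0
    else:
        fit = sps.linregress(t, d)
        slope, intercept, r, p = (
            float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)
        )
    return {
        "speed_mm_per_h": slope,
        "fit": RegressionFit(slope, intercept, r, p, int(d.size)).as_dict(),
        "mode": mode,
    }


def trajectory_speed(path_length_um: float, duration_s: float) -> float:
    """Single-cell motility speed: path length divided by duration (um/s)."""
    if duration_s <= 0:
        raise StatsError("duration must be positive")
    return path_length_um / duration_s


def functional_tally(
    first_gene_ids: Iterable[str],
    category_map: Mapping[str, str],
    unknown_label: str = "Function unknown",
) -> CategoryTally:
    """Per-category counts of transcriptional units by their first gene.

    Genes absent from the category map fall into ``unknown_label``.
    """
    counts: Counter[str] = Counter(
        category_map.get(g, unknown_label) for g in first_gene_ids
    )
    total = sum(counts.values())
    if total == 0:
        return CategoryTally(counts={}, total=0, top_category=None, top_share_pct=0.0)
    top, top_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return CategoryTally(
        counts=dict(counts), total=total, top_category=top,
        top_share_pct=100.0 * top_n / total,
    )
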
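"""Sliding age-window group trajectories of regional complexity.

The cohort is cross-sectional: subjects aged roughly 6-30 are grouped into
overlapping 5-year windows advancing by 1 year ("6 to 10", "7 to 11", ...,
"26 to 30" in the default configuration — 21 windows). Within each
(window x group x region) cell, Rosner's generalized extreme studentized
deviate (GESD) test screens outliers, then mean/SD/SEM/n are tabulated over
the survivors. Group differences per cell use an independent two-sample
t-test (pooled-variance Student by default, Welch by option) with a
Bonferroni-corrected significance level, and the differential complexity
curve of each region is the case-group mean minus the control-group mean
across windows.

A one-sample Kolmogorov-Smirnov check against a normal with the cell's own
mean/SD is recorded for reporting; it never gates the t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io import SubjectRecord

logger = logging.getLogger(__name__)

WHOLE_BRAIN = "whole_brain"


@dataclass(frozen=True)
class AgeWindow:
    """Half-open age interval [lo, lo + width) in years."""

    index: int
    lo: int
    width: int = 5

    @property
    def label(self) -> str:
        return f"{self.lo} to {self.lo + self.width - 1}"

    def contains(self, age: float) -> bool:
        return self.lo <= age < self.lo + self.width


def build_age_windows(min_lo: int = 6, max_lo: int = 26, width: int = 5,
                      step: int = 1) -> list[AgeWindow]:
    """Windows at lo = min_lo, min_lo+step, ..., max_lo."""
    for name, v in (("min_lo", min_lo), ("max_lo", max_lo), ("width", width), ("step", step)):
        if not isinstance(v, (int, np.integer)):
            raise ParameterError(f"{name} must be an integer, got {v!r}")
    if min_lo < 0 or max_lo < min_lo or width < 1 or step < 1:
        raise ParameterError(
            f"invalid window parameters: min_lo={min_lo} max_lo={max_lo} width={width} step={step}")
    return [AgeWindow(index=i + 1, lo=lo, width=width)
            for i, lo in enumerate(range(min_lo, max_lo + 1, step))]


def assign_to_windows(subjects: list[SubjectRecord], windows: list[AgeWindow]
                      ) -> tuple[dict[int, list[str]], list[str]]:
    """Membership map window index -> subject ids, plus ids outside every window."""
    membership: dict[int, list[str]] = {w.index: [] for w in windows}
    unassigned: list[str] = []
    for s in subjects:
        hit = False
        for w in windows:
            if w.contains(s.age):
                membership[w.index].append(s.subject_id)
                hit = True
        if not hit:
            unassigned.append(s.subject_id)
    if unassigned:
        logger.info("assign_to_windows: %d subjects outside all windows: %s",
                    len(unassigned), unassigned)
    return membership, unassigned


def ks_normality(values) -> tuple[float, float] | None:
    """One-sample KS statistic/p against N(sample mean, sample SD); None if n < 5."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        logger.debug("ks_normality skipped: n=%d < 5", x.size)
        return None
    sd = x.std(ddof=1)
    if sd == 0:
        logger.debug("ks_normality skipped: zero variance")
        return None
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def gesd_outliers(values, max_k: int, alpha: float = 0.05) -> list[int]:
    """Rosner's generalized ESD test; returns indices of declared outliers.

    Iteratively removes the most extreme studentized point, comparing each
    statistic R_i to its critical value lambda_i (t distribution at level
    ``alpha``); the largest i with R_i > lambda_i fixes the outlier count.
    If the remaining sample has zero variance the iteration stops early.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not (isinstance(max_k, (int, np.integer)) and max_k >= 1):
        raise ParameterError(f"max_k must be a positive integer, got {max_k}")
    if n < max_k + 3:
        raise ParameterError(f"GESD needs n >= max_k + 3 (n={n}, max_k={max_k})")
    remaining = list(range(n))
    candidates: list[int] = []
    stats_r: list[float] = []
    for _ in range(max_k):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        stats_r.append(float(dev[j] / sd))
        candidates.append(remaining.pop(j))
    n_out = 0
    for i in range(1, len(stats_r) + 1):
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        t = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * t / math.sqrt((n - i - 1 + t * t) * (n - i + 1))
        if stats_r[i - 1] > lam:
            n_out = i
    return sorted(candidates[:n_out])


def default_max_k(n: int) -> int:
    """Default GESD outlier budget: 10% of the cell, at least 1."""
    return max(1, math.ceil(0.1 * n))


def _cell_stats(values: np.ndarray, gesd_alpha: float,
                max_k: int | None) -> dict:
    """Screen one cell with GESD (when feasible) and tabulate survivor stats."""
    v = values[np.isfinite(values)]
    n0 = v.size
    k = default_max_k(n0) if max_k is None else max_k
    removed = 0
    if n0 >= k + 3 and k >= 1:
        out = gesd_outliers(v, max_k=k, alpha=gesd_alpha)
        if out:
            v = np.delete(v, out)
            removed = len(out)
    n = v.size
    if n == 0:
        return dict(mean=np.nan, sd=np.nan, sem=np.nan, n=0, n_outliers_removed=removed,
                    ks_stat=np.nan, ks_p=np.nan, values=v)
    sd = float(v.std(ddof=1)) if n > 1 else 0.0  # n=1: SD 0 by convention, SEM missing
    sem = sd / math.sqrt(n) if n > 1 else np.nan
    ks = ks_normality(v) if n >= 5 else None
    return dict(mean=float(v.mean()), sd=sd, sem=sem, n=n, n_outliers_removed=removed,
                ks_stat=ks[0] if ks else np.nan, ks_p=ks[1] if ks else np.nan, values=v)


def group_trajectory(profiles: pd.DataFrame, records: list[SubjectRecord],
                     windows: list[AgeWindow],
                     membership: dict[int, list[str]] | None = None,
                     gesd_alpha: float = 0.05, gesd_max_k: int | None = None,
                     targets: list[str] | None = None,
                     keep_values: bool = False) -> pd.DataFrame:
    """Per (window x group x target) survivor statistics after GESD screening.

    ``profiles`` is the subject x target frame from
    :func:`braintraj.entropy.profiles_to_frame` (columns ``R<id>`` and
    ``whole_brain``). Returns a tidy frame; with ``keep_values`` the
    screened per-cell samples are kept in a ``values`` column for the group
    tests.
    """
    if membership is None:
        membership, _ = assign_to_windows(records, windows)
    group_of = {r.subject_id: r.group for r in records}
    cols = list(profiles.columns) if targets is None else targets
    rows = []
    for w in windows:
        ids = [s for s in membership.get(w.index, []) if s in profiles.index]
        by_group = {g: [s for s in ids if group_of.get(s) == g] for g in ("case", "control")}
        for g, gids in by_group.items():
            sub = profiles.loc[gids]
            for target in cols:
                cell = _cell_stats(sub[target].to_numpy(dtype=float), gesd_alpha, gesd_max_k)
                row = dict(window_index=w.index, window_label=w.label, window_lo=w.lo,
                           group=g, target=target, **cell)
                if not keep_values:
                    row.pop("values")
                rows.append(row)
    return pd.DataFrame(rows)


def window_ttest(case_values, control_values, welch: bool = False
                 ) -> tuple[float, float] | None:
    """Two-sided independent t-test; None when a group has n < 2 or variance is degenerate."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        logger.debug("window_ttest skipped: group sizes %d/%d", a.size, b.size)
        return None
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.debug("window_ttest skipped: zero variance in both groups, unequal means")
        return None
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bonferroni_alpha(base_alpha: float, n_comparisons: int) -> float:
    """Corrected per-test significance level base_alpha / n_comparisons."""
    if not (isinstance(n_comparisons, (int, np.integer)) and n_comparisons >= 1):
        raise ParameterError(f"n_comparisons must be a positive integer, got {n_comparisons}")
    return base_alpha / n_comparisons


def group_tests(traj: pd.DataFrame, base_alpha: float = 0.05,
                n_comparisons: int | None = None, welch: bool = False) -> pd.DataFrame:
    """Independent t-tests per (window, target) with Bonferroni-corrected level.

    ``traj`` must carry the screened per-cell samples (``keep_values=True``).
    By default the correction counts the number of testable comparisons.
    """
    if "values" not in traj.columns:
        raise ParameterError("group_tests needs a trajectory table built with keep_values=True")
    wide = traj.set_index(["window_index", "window_label", "target", "group"])["values"]
    pairs = []
    for (wi, wl, target) in sorted({(a, b, c) for a, b, c, _ in wide.index}):
        try:
            case_v = wide.loc[(wi, wl, target, "case")]
            ctrl_v = wide.loc[(wi, wl, target, "control")]
        except KeyError:
            continue
        res = window_ttest(case_v, ctrl_v, welch=welch)
        pairs.append(dict(window_index=wi, window_label=wl, target=target,
                          t=res[0] if res else np.nan, p=res[1] if res else np.nan,
                          tested=res is not None))
    tests = pd.DataFrame(pairs)
    if tests.empty:
        tests["corrected_alpha"] = []
        tests["significant"] = []
        return tests
    n_comp = int(tests["tested"].sum()) if n_comparisons is None else n_comparisons
    corrected = bonferroni_alpha(base_alpha, max(n_comp, 1))
    tests["corrected_alpha"] = corrected
    tests["significant"] = tests["p"] < corrected
    return tests


def differential_curves(traj: pd.DataFrame, include_whole_brain: bool = False) -> pd.DataFrame:
    """Case-minus-control mean curve per target: rows targets, columns window indices.

    Entries are NaN wherever either group mean is missing (never imputed as 0).
    """
    means = traj.set_index(["target", "window_index", "group"])["mean"].unstack("group")
    diff = (means["case"] - means["control"]).unstack("window_index")
    if not include_whole_brain and WHOLE_BRAIN in diff.index:
        diff = diff.drop(index=WHOLE_BRAIN)
    return diff


def window_labels(windows: list[AgeWindow]) -> dict[int, str]:
    return {w.index: w.label for w in windows}
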
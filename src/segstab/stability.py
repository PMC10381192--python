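"""ICC(1,1) stability statistics and robustness reporting.

The intraclass correlation is estimated from a one-way random-effects ANOVA
(single rater, absolute agreement): subjects are random, each rated by k
raters. The 95% confidence interval comes from the F statistic MSB/MSW.

A feature is *stable* when the CI lower bound exceeds the threshold (strictly,
default 0.90) in one dataset, and *robust* when the minimum of the two
datasets' lower bounds exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features.extractor import FAMILY_NAMES, FeatureKey

DEFAULT_THRESHOLD = 0.90
ORIGINAL_FILTER = "original"


@dataclass
class RatingsMatrix:
    """n subjects x k raters of one measured quantity."""

    values: np.ndarray
    subject_ids: list[str] | None = None
    rater_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2D (subjects x raters) array")
        n, k = self.values.shape
        if n < 3 or k < 2:
            raise ValueError(f"need n >= 3 subjects and k >= 2 raters, got {n}x{k}")
        if np.isnan(self.values).any():
            raise ValueError("ratings contain NaN; exclude the feature instead")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    alpha: float
    ms_between: float
    ms_within: float
    df1: int
    df2: int
    f_statistic: float
    degenerate: bool = False


def icc_1_1(m: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(1,1) point estimate and F-based confidence interval.

    estimate = (MSB - MSW) / (MSB + (k-1) MSW). The interval transforms
    FL = F0 / F_{1-a/2}(n-1, n(k-1)) and FU = F0 * F_{1-a/2}(n(k-1), n-1)
    through (F - 1) / (F + k - 1).

    A matrix with MSB = MSW = 0 (all values identical) yields a result with
    ``degenerate=True`` and NaN estimate — never a silent 1.
    """
    y = m.values
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssw = ((y - row_means[:, None]) ** 2).sum()
    df1 = n - 1
    df2 = n * (k - 1)
    msb = ssb / df1
    msw = ssw / df2
    if msb == 0 and msw == 0:
        return ICCResult(float("nan"), float("nan"), float("nan"), alpha,
                         0.0, 0.0, df1, df2, float("nan"), degenerate=True)
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, alpha, msb, 0.0, df1, df2,
                         float("inf"))
    f0 = msb / msw
    est = (msb - msw) / (msb + (k - 1) * msw)
    fl = f0 / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * sps.f.ppf(1 - alpha / 2, df2, df1)
    lower = (fl - 1) / (fl + k - 1)
    upper = (fu - 1) / (fu + k - 1)
    return ICCResult(float(est), float(lower), float(upper), alpha,
                     float(msb), float(msw), df1, df2, float(f0))


def classify_stable(r: ICCResult, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Stable iff the CI lower bound strictly exceeds the threshold."""
    if r.degenerate or np.isnan(r.ci_lower):
        return False
    return r.ci_lower > threshold


# --- report structures ------------------------------------------------------


@dataclass
class StabilityReport:
    """Per-feature ICC results and stability flags for one dataset.

    ``results`` maps FeatureKey -> ICCResult; ``excluded`` lists keys dropped
    before ICC (NaN/degenerate ratings).
    """

    results: dict[FeatureKey, ICCResult]
    threshold: float = DEFAULT_THRESHOLD
    excluded: list[FeatureKey] = field(default_factory=list)
    robust_flags: dict[FeatureKey, bool] = field(default_factory=dict)
    overlap: dict[FeatureKey, float] = field(default_factory=dict)

    def stable(self, key: FeatureKey) -> bool:
        r = self.results.get(key)
        return r is not None and classify_stable(r, self.threshold)

    def stable_keys(self) -> set[FeatureKey]:
        return {k for k in self.results if self.stable(k)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, r in self.results.items():
            rows.append({
                "key": str(key), "sequence": key.sequence, "filter": key.filter,
                "family": key.family, "name": key.name,
                "icc": r.estimate, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                "degenerate": r.degenerate, "stable": self.stable(key),
                "robust": self.robust_flags.get(key),
                "overlap": self.overlap.get(key),
            })
        return pd.DataFrame(rows)


def build_report(
    ratings: dict[FeatureKey, RatingsMatrix],
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.05,
) -> StabilityReport:
    """ICC every feature's ratings matrix; NaN-carrying features are excluded
    upstream by :func:`ratings_from_table`."""
    results = {key: icc_1_1(m, alpha) for key, m in ratings.items()}
    return StabilityReport(results, threshold)


def ratings_from_table(
    table: pd.DataFrame,
) -> tuple[dict[FeatureKey, RatingsMatrix], list[FeatureKey]]:
    """Pivot a long feature table into per-feature ratings matrices.

    ``table`` needs columns ``subject``, ``rater``, ``key`` (FeatureKey
    string) and ``value``. Features with any NaN cell are excluded and
    returned separately rather than imputed.
    """
    ratings: dict[FeatureKey, RatingsMatrix] = {}
    excluded: list[FeatureKey] = []
    for key_str, grp in table.groupby("key", sort=False):
        pivot = grp.pivot(index="subject", columns="rater", values="value")
        key = FeatureKey.parse(str(key_str))
        if pivot.isna().any().any():
            excluded.append(key)
            continue
        ratings[key] = RatingsMatrix(
            pivot.to_numpy(),
            subject_ids=[str(s) for s in pivot.index],
            rater_ids=[str(r) for r in pivot.columns],
        )
    return ratings, excluded


# --- robustness across datasets --------------------------------------------


def assess_robustness(
    internal: StabilityReport,
    external: StabilityReport,
    sequence_map: dict[str, str] | None = None,
) -> StabilityReport:
    """Mark features robust when min(lower_int, lower_ext) > threshold.

    ``sequence_map`` translates internal sequence labels to external ones
    (e.g. ``{"sub_win": "sub"}``) before matching keys.
    """
    sequence_map = sequence_map or {}

    def ext_key(key: FeatureKey) -> FeatureKey:
        seq = sequence_map.get(key.sequence, key.sequence)
        return FeatureKey(seq, key.filter, key.family, key.name)

    missing = [k for k in internal.results if ext_key(k) not in external.results]
    if missing:
        raise KeyError(
            f"{len(missing)} features missing from the external report, "
            f"e.g. {[str(k) for k in missing[:5]]}"
        )
    out = StabilityReport(dict(internal.results), internal.threshold,
                          list(internal.excluded))
    for key, r_int in internal.results.items():
        r_ext = external.results[ext_key(key)]
        if r_int.degenerate or r_ext.degenerate:
            out.overlap[key] = float("nan")
            out.robust_flags[key] = False
            continue
        overlap = min(r_int.ci_lower, r_ext.ci_lower)
        out.overlap[key] = overlap
        out.robust_flags[key] = overlap > internal.threshold
    return out


def select_best_filters(
    report: StabilityReport,
) -> dict[tuple[str, str, str], list[str]]:
    """Best filter(s) per base feature: among internally stable variants,
    the argmax of the overlap value (ties all reported).

    Keys are (sequence, family, name); an empty list marks features with no
    stable filter variant.
    """
    grouped: dict[tuple[str, str, str], list[FeatureKey]] = {}
    for key in report.results:
        grouped.setdefault((key.sequence, key.family, key.name), []).append(key)
    best: dict[tuple[str, str, str], list[str]] = {}
    for base, keys in grouped.items():
        stable = [k for k in keys if report.stable(k)]
        if not stable:
            best[base] = []
            continue
        scores = {
            k: report.overlap.get(k, report.results[k].ci_lower) for k in stable
        }
        top = max(scores.values())
        best[base] = sorted(k.filter for k, v in scores.items() if v == top)
    return best


def summarize_fractions(report: StabilityReport) -> pd.DataFrame:
    """Family-level fractions of stable/robust features, Original vs
    Best-Filtered.

    Under BF, a base feature counts as stable (robust) if *any* filter variant
    is stable (robust). Robust columns are NaN when no robustness assessment
    was attached to the report.
    """
    has_robust = bool(report.robust_flags)
    grouped: dict[tuple[str, str, str], list[FeatureKey]] = {}
    for key in report.results:
        grouped.setdefault((key.sequence, key.family, key.name), []).append(key)

    rows = []
    sequences = sorted({seq for seq, _, _ in grouped})
    for seq in sequences:
        per_family: dict[str, dict[str, float]] = {}
        for family in FAMILY_NAMES:
            bases = [b for b in grouped if b[0] == seq and b[1] == family]
            if not bases:
                continue
            n = len(bases)
            o_s = o_r = bf_s = bf_r = 0
            for base in bases:
                keys = grouped[base]
                orig = next((k for k in keys if k.filter == ORIGINAL_FILTER), None)
                if orig is not None and report.stable(orig):
                    o_s += 1
                if orig is not None and report.robust_flags.get(orig, False):
                    o_r += 1
                if any(report.stable(k) for k in keys):
                    bf_s += 1
                if any(report.robust_flags.get(k, False) for k in keys):
                    bf_r += 1
            per_family[family] = {
                "n": n,
                "O_stable": o_s / n,
                "O_robust": (o_r / n) if has_robust else float("nan"),
                "BF_stable": bf_s / n,
                "BF_robust": (bf_r / n) if has_robust else float("nan"),
            }
            rows.append({"sequence": seq, "family": family, **per_family[family]})
        if per_family:
            total = sum(f["n"] for f in per_family.values())
            overall = {"sequence": seq, "family": "overall", "n": total}
            for col in ("O_stable", "O_robust", "BF_stable", "BF_robust"):
                overall[col] = sum(f[col] * f["n"] for f in per_family.values()) / total
            rows.append(overall)
    return pd.DataFrame(rows)
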
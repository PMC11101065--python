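"""Univariate group comparisons and the train/validation split.

The study design compares each image feature between benign and malignant
groups with a two-sample Student t-test (pooled variance), then splits the
image table 7:3 into training and validation partitions by simple random
sampling.  Both the raw-data and summary-statistics routes to the t-test
are provided; the summary route lets reported n/mean/SD cells be re-tested
without the underlying images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "SplitResult",
    "summarize_groups",
    "pooled_t_from_summary",
    "pooled_t_from_data",
    "compare_groups",
    "split_dataset",
]


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test outcome.

    ``sign_convention`` records which group mean is subtracted from which
    ("A-minus-B" for groups passed in order A, B) so that reported signs
    can be matched without guessing.
    """

    t: float
    df: float
    p: float
    sign_convention: str
    welch: bool = False


@dataclass(frozen=True)
class SplitResult:
    """A 7:3-style random partition of row indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    validation_fraction: float
    seed: int

    @property
    def n_train(self) -> int:
        return len(self.train_idx)

    @property
    def n_val(self) -> int:
        return len(self.val_idx)


def summarize_groups(
    table: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    group_key: str = "label",
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group n / mean / sample SD (n-1 denominator) for each feature.

    Returns a tidy DataFrame (group, feature, n, mean, sd); SD is NaN for a
    single-row group.  Requesting a group label absent from the table raises
    with the labels actually observed.
    """
    observed = list(table[group_key].unique())
    if groups is None:
        groups = observed
    unknown = [g for g in groups if g not in observed]
    if unknown:
        raise ValueError(
            f"unknown group label(s) {unknown}; observed labels: {observed}"
        )
    rows = []
    for g in groups:
        sub = table.loc[table[group_key] == g, list(features)]
        for f in features:
            x = sub[f].to_numpy(dtype=np.float64)
            rows.append(
                {
                    "group": g,
                    "feature": f,
                    "n": len(x),
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pooled_t_from_summary(
    n1: int,
    m1: float,
    s1: float,
    n2: int,
    m2: float,
    s2: float,
    sign_convention: str = "first-minus-second",
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test from group summary statistics alone.

    Pooled (Student) form by default: t = (m1-m2) / (s_p sqrt(1/n1+1/n2))
    with s_p^2 the pooled variance and df = n1+n2-2.  ``welch=True`` gives
    the unequal-variance form with Satterthwaite df instead.  Group 1's
    mean is the minuend.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TTestResult(0.0, float(n1 + n2 - 2), 1.0, sign_convention, welch)
        raise ValueError(
            "both SDs are zero with unequal means: t statistic is infinite"
        )
    diff = m1 - m2
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (
            (v1**2 / (n1 - 1) if n1 > 1 else 0) + (v2**2 / (n2 - 1) if n2 > 1 else 0)
        )
    else:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), sign_convention, welch)


def pooled_t_from_data(
    table: pd.DataFrame,
    feature: str,
    group_key: str = "label",
    group_order: tuple[str, str] | None = None,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test from raw rows.

    Routed through :func:`summarize_groups` and
    :func:`pooled_t_from_summary` so the data path and the summary path
    agree exactly.  ``group_order`` fixes the sign convention (first group's
    mean minus second's); defaults to the two labels in sorted order.
    """
    labels = sorted(table[group_key].unique())
    if group_order is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, found {labels}")
        group_order = (labels[0], labels[1])
    summ = summarize_groups(table, [feature], group_key, groups=list(group_order))
    a = summ[summ["group"] == group_order[0]].iloc[0]
    b = summ[summ["group"] == group_order[1]].iloc[0]
    return pooled_t_from_summary(
        int(a["n"]), a["mean"], a["sd"], int(b["n"]), b["mean"], b["sd"],
        sign_convention=f"{group_order[0]}-minus-{group_order[1]}",
        welch=welch,
    )


def compare_groups(
    table: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    group_key: str = "label",
    group_order: tuple[str, str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Summary table with per-feature group means/SDs and t-test columns."""
    rows = []
    for f in features:
        res = pooled_t_from_data(table, f, group_key, group_order, welch)
        summ = summarize_groups(table, [f], group_key)
        rec: dict = {"feature": f}
        for g in summ["group"].unique():
            s = summ[(summ["group"] == g) & (summ["feature"] == f)].iloc[0]
            rec[f"{g}_n"] = int(s["n"])
            rec[f"{g}_mean"] = s["mean"]
            rec[f"{g}_sd"] = s["sd"]
        rec.update({"t": res.t, "df": res.df, "p": res.p,
                    "sign_convention": res.sign_convention})
        rows.append(rec)
    return pd.DataFrame(rows)


def split_dataset(
    table: pd.DataFrame, validation_fraction: float = 0.3, seed: int = 0
) -> SplitResult:
    """Simple random (non-stratified) train/validation partition.

    The validation partition holds exactly ``floor(validation_fraction * N)``
    rows — the floor rule is what makes a 2,723-row table split 1,907/816
    at 7:3.  Deterministic given ``seed``; indices are positional row
    numbers into *table*.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation_fraction must lie in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_val = int(np.floor(validation_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return SplitResult(train, val, validation_fraction, seed)
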
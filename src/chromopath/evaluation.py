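"""Discrimination, calibration and clinical-utility evaluation.

Three complementary views of a risk score:

* discrimination — the ROC curve and its area.  AUC is computed in the
  tie-aware Mann-Whitney form, AUC = [#(s_pos > s_neg) + 0.5 #ties] /
  (n_pos n_neg), which the trapezoidal area under the threshold-swept curve
  equals identically; a percentile bootstrap (case resampling) gives the
  95% CI.
* calibration — the Hosmer-Lemeshow chi-square over risk-decile groups and
  the binned calibration curve (observed event fraction vs mean predicted
  probability).
* clinical utility — decision-curve analysis: net benefit
  NB(p_t) = TP/N - (FP/N) p_t/(1-p_t) across threshold probabilities p_t,
  against the treat-all and treat-none strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "HLResult",
    "roc_auc",
    "bootstrap_auc_ci",
    "hosmer_lemeshow",
    "calibration_curve",
    "decision_curve",
    "gaussian_linear_score_auc",
    "evaluate_model",
    "ModelEvaluation",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("labels must be coded 0/1")
    if len(uniq) < 2:
        raise ValueError("both classes must be present")
    return y.astype(int)


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    # midranks handle ties: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)
    ranks = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ROCResult:
    """ROC curve points plus Mann-Whitney AUC (and optional bootstrap CI)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    n_boot: int | None = None
    seed: int | None = None

    def trapezoid_auc(self) -> float:
        """Area under the swept curve; equals :attr:`auc` identically."""
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and tie-aware AUC.

    The curve sweeps thresholds over the unique score values (classifying
    ``score >= threshold`` as positive), starting at (0,0) and ending at
    (1,1); AUC comes from the Mann-Whitney rank form and is invariant under
    any strictly increasing transform of the scores.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = _check_binary(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each distinct descending threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return ROCResult(fpr, tpr, thresholds, _auc_mann_whitney(s, y))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for AUC by case resampling.

    Rows are resampled with replacement *n_boot* times; a replicate missing
    one class is redrawn (after 100 x n_boot total draws the data are
    declared too degenerate and an error is raised).  Deterministic given
    *seed*.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    s = np.asarray(scores, dtype=np.float64)
    y = _check_binary(labels)
    n = len(s)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    draws = 0
    got = 0
    while got < n_boot:
        draws += 1
        if draws > 100 * n_boot:
            raise ValueError(
                "bootstrap redraw limit exhausted: resamples almost always "
                "lack one class"
            )
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.sum() == 0 or yb.sum() == n:
            continue
        aucs[got] = _auc_mann_whitney(s[idx], yb)
        got += 1
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass
class HLResult:
    """Hosmer-Lemeshow goodness-of-fit outcome with its O/E group table."""

    chi2: float
    df: int
    p: float
    table: pd.DataFrame  # per group: n, observed, expected, mean_pred
    n_groups: int
    merged: bool = False


def _risk_groups(probs: np.ndarray, g: int) -> np.ndarray:
    """Quantile-of-risk group ids; tied probabilities stay together."""
    # qcut with duplicates="drop" collapses tied quantile edges, which is
    # exactly the ties-together rule
    cats = pd.qcut(probs, q=g, labels=False, duplicates="drop")
    return np.asarray(cats)


def hosmer_lemeshow(
    probs: np.ndarray, labels: np.ndarray, g: int = 10
) -> HLResult:
    """Hosmer-Lemeshow chi-square over risk-decile groups.

    Groups are equal-frequency bins of predicted probability (ties kept in
    one group, so heavy ties can yield fewer than *g* groups); per group
    both outcome cells contribute: chi2 = sum (O1-E1)^2/E1 + (O0-E0)^2/E0
    with E1 = sum p and E0 = sum (1-p); df = groups - 2.  Groups whose
    expected cell is zero are merged into a neighbor (flagged).
    """
    p = np.asarray(probs, dtype=np.float64)
    y = _check_binary(labels)
    if len(p) != len(y):
        raise ValueError("probs and labels differ in length")
    if len(p) < g:
        raise ValueError(f"need at least g={g} rows")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly in (0, 1)")

    grp = _risk_groups(p, g)
    rows = []
    for k in np.unique(grp):
        m = grp == k
        rows.append(
            {
                "n": int(m.sum()),
                "observed": int(y[m].sum()),
                "expected": float(p[m].sum()),
                "mean_pred": float(p[m].mean()),
            }
        )
    merged = False
    # merge groups with a vanishing expected cell into the next group
    i = 0
    while i < len(rows):
        r = rows[i]
        e1, e0 = r["expected"], r["n"] - r["expected"]
        if (e1 < 1e-12 or e0 < 1e-12) and len(rows) > 1:
            j = i + 1 if i + 1 < len(rows) else i - 1
            rows[j] = {
                "n": rows[j]["n"] + r["n"],
                "observed": rows[j]["observed"] + r["observed"],
                "expected": rows[j]["expected"] + r["expected"],
                "mean_pred": (
                    rows[j]["mean_pred"] * rows[j]["n"] + r["mean_pred"] * r["n"]
                ) / (rows[j]["n"] + r["n"]),
            }
            rows.pop(i)
            merged = True
        else:
            i += 1

    chi2 = 0.0
    for r in rows:
        e1 = r["expected"]
        e0 = r["n"] - e1
        o1 = r["observed"]
        o0 = r["n"] - o1
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = max(len(rows) - 2, 1)
    return HLResult(
        chi2=float(chi2),
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        table=pd.DataFrame(rows),
        n_groups=len(rows),
        merged=merged,
    )


def calibration_curve(
    probs: np.ndarray, labels: np.ndarray, bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency calibration curve.

    One point per bin: (mean predicted probability, observed event
    fraction, n).  Constant predictions collapse to a single informative
    bin.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = _check_binary(labels)
    if np.unique(p).size == 1:
        return pd.DataFrame(
            {"mean_pred": [float(p.mean())], "frac_obs": [float(y.mean())],
             "n": [len(p)]}
        )
    grp = _risk_groups(p, bins)
    rows = []
    for k in np.unique(grp):
        m = grp == k
        rows.append(
            {"mean_pred": float(p[m].mean()), "frac_obs": float(y[m].mean()),
             "n": int(m.sum())}
        )
    return pd.DataFrame(rows)


def _net_benefit(p: np.ndarray, y: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    n = len(y)
    nb = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        call = p >= t
        tp = int((call & (y == 1)).sum())
        fp = int((call & (y == 0)).sum())
        nb[i] = tp / n - (fp / n) * t / (1.0 - t)
    return nb


def decision_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Decision-curve analysis table.

    Columns: ``threshold, nb_model, nb_all, nb_none`` and, when
    ``n_boot > 0``, the percentile 2.5/97.5% case-resampling band
    ``nb_model_lo, nb_model_hi``.  The treat-all curve is
    pi - (1-pi) p_t/(1-p_t) (crossing zero exactly at the prevalence pi);
    treat-none is identically zero.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds <= 0.0) or np.any(thresholds >= 1.0):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    p = np.asarray(probs, dtype=np.float64)
    y = _check_binary(labels)
    prev = y.mean()
    out = pd.DataFrame(
        {
            "threshold": thresholds,
            "nb_model": _net_benefit(p, y, thresholds),
            "nb_all": prev - (1 - prev) * thresholds / (1 - thresholds),
            "nb_none": 0.0,
        }
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, len(thresholds)))
        n = len(y)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            reps[b] = _net_benefit(p[idx], y[idx], thresholds)
        out["nb_model_lo"] = np.quantile(reps, 0.025, axis=0)
        out["nb_model_hi"] = np.quantile(reps, 0.975, axis=0)
    return out


def gaussian_linear_score_auc(
    beta: np.ndarray,
    mean_pos: np.ndarray,
    sd_pos: np.ndarray,
    mean_neg: np.ndarray,
    sd_neg: np.ndarray,
) -> float:
    """Closed-form AUC of a fixed linear score on independent Gaussian
    features: Phi(delta_mu / sqrt(var_pos + var_neg)) where delta_mu and the
    variances are those of the score s = beta . x in each class."""
    beta = np.asarray(beta, dtype=np.float64)
    d = float(beta @ np.asarray(mean_pos) - beta @ np.asarray(mean_neg))
    v = float((beta**2) @ (np.asarray(sd_pos) ** 2)
              + (beta**2) @ (np.asarray(sd_neg) ** 2))
    return float(stats.norm.cdf(d / np.sqrt(v)))


@dataclass
class ModelEvaluation:
    """Bundle of all evaluation outputs for one scored dataset."""

    roc: ROCResult
    hl: HLResult
    calibration: pd.DataFrame
    dca: pd.DataFrame
    n: int
    prevalence: float
    seeds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "auc": self.roc.auc,
            "auc_ci": list(self.roc.ci) if self.roc.ci else None,
            "n_boot": self.roc.n_boot,
            "hl_chi2": self.hl.chi2,
            "hl_df": self.hl.df,
            "hl_p": self.hl.p,
            "calibration": self.calibration.to_dict(orient="records"),
            "dca": self.dca.to_dict(orient="records"),
            "seeds": self.seeds,
        }


def evaluate_model(
    probs: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    hl_groups: int = 10,
    calibration_bins: int = 10,
    dca_thresholds: np.ndarray | None = None,
    dca_boot: int = 0,
) -> ModelEvaluation:
    """Full evaluation: ROC/AUC + bootstrap CI, HL test, calibration, DCA."""
    y = _check_binary(labels)
    roc = roc_auc(probs, y)
    roc.ci = bootstrap_auc_ci(probs, y, n_boot=n_boot, seed=seed)
    roc.n_boot = n_boot
    roc.seed = seed
    return ModelEvaluation(
        roc=roc,
        hl=hosmer_lemeshow(probs, y, g=hl_groups),
        calibration=calibration_curve(probs, y, bins=calibration_bins),
        dca=decision_curve(probs, y, dca_thresholds, n_boot=dca_boot,
                           seed=seed + 1),
        n=len(y),
        prevalence=float(y.mean()),
        seeds={"bootstrap": seed, "dca": seed + 1},
    )
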
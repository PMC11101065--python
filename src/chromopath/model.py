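"""Multivariable logistic model, Wald/odds-ratio table, and nomogram.

The modelling core follows the statsmodels idiom: :class:`BinaryNomogram`
is built from a feature table (``from_dataframe``), its :meth:`fit` runs
maximum-likelihood logistic regression (Newton scoring, equivalent to
iteratively reweighted least squares, with standard errors from the inverse
observed information) and returns a :class:`NomogramResults` carrying the
coefficients, their covariance, the Wald table and the nomogram
presentation of the model.

The nomogram is the points-scale rewriting of the linear predictor: each
predictor's contribution over its observed range is rescaled so the most
influential predictor (largest |beta| x range) spans exactly 0-100 points;
total points map back to predicted probability through the inverse of the
same affine rescaling, so nomogram scoring and direct logistic scoring are
algebraically identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort import pooled_t_from_data

__all__ = [
    "BinaryNomogram",
    "NomogramResults",
    "NomogramSpec",
    "wald_table_from",
    "logistic_score",
    "select_variables",
]

#: 97.5% normal quantile used for Wald confidence limits (the convention of
#: mainstream statistical software, not the rounded 1.96).
Z_95 = 1.959964


def _sigmoid(eta: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=np.float64)))


def wald_table_from(
    beta: Mapping[str, float] | pd.Series,
    se: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Wald/odds-ratio table from coefficients and standard errors.

    Per variable: Wald chi2 = (beta/se)^2 with a 1-df chi-square p-value,
    OR = exp(beta), and 95% CI = exp(beta +/- 1.959964 se).  Works on any
    beta/se source — a fitted model or published coefficient cells.
    """
    beta = pd.Series(beta, dtype=np.float64)
    se = pd.Series(se, dtype=np.float64).reindex(beta.index)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    chi2 = (beta / se) ** 2
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "wald_chi2": chi2,
            "p": stats.chi2.sf(chi2, df=1),
            "or": np.exp(beta),
            "or_ci_low": np.exp(beta - Z_95 * se),
            "or_ci_high": np.exp(beta + Z_95 * se),
        }
    )


def logistic_score(
    coefficients: Mapping[str, float], table: pd.DataFrame
) -> np.ndarray:
    """Predicted probabilities from a fixed {feature: beta} map.

    ``coefficients`` may include ``"const"`` for the intercept; every other
    key must be a column of *table*.  Useful for applying published
    coefficients as a frozen scoring rule.
    """
    eta = np.full(len(table), float(coefficients.get("const", 0.0)))
    for name, b in coefficients.items():
        if name == "const":
            continue
        if name not in table.columns:
            raise KeyError(f"feature {name!r} missing from table")
        eta = eta + b * table[name].to_numpy(dtype=np.float64)
    return np.asarray(_sigmoid(eta))


@dataclass
class NomogramSpec:
    """Points-scale presentation of a fitted logistic model.

    ``points(v, x)`` maps predictor v's value to [0, ~100] points (the
    dominant predictor spans exactly [0, 100]); ``probability(total)``
    maps summed points to predicted probability.
    """

    features: tuple[str, ...]
    beta: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    ref: dict[str, float]  # range end contributing 0 points
    scale: float  # log-odds per point
    base_eta: float  # linear predictor at the all-reference point
    zero_width: tuple[str, ...] = field(default_factory=tuple)

    def points(self, feature: str, x: np.ndarray | float) -> np.ndarray | float:
        if feature in self.zero_width:
            return np.zeros_like(np.asarray(x, dtype=np.float64))
        # ref is the low-risk range end, so beta*(x - ref) >= 0 in range
        b = self.beta[feature]
        return b * (np.asarray(x, dtype=np.float64) - self.ref[feature]) / self.scale

    def total_points(self, row: Mapping[str, float] | pd.Series) -> float:
        return float(sum(self.points(f, row[f]) for f in self.features))

    def probability(self, total_points: float | np.ndarray) -> np.ndarray | float:
        eta = self.base_eta + self.scale * np.asarray(total_points, dtype=np.float64)
        return _sigmoid(eta)

    def score(self, row: Mapping[str, float] | pd.Series) -> float:
        """Probability via the points pathway (equals direct scoring)."""
        return float(self.probability(self.total_points(row)))

    def axis_maximum(self, feature: str) -> float:
        lo, hi = self.ranges[feature]
        return float(max(self.points(feature, lo), self.points(feature, hi)))


class BinaryNomogram:
    """Logistic model of a binary pathology label on image features.

    Parameters
    ----------
    endog : 0/1 outcome array (1 = positive class, by default malignant).
    exog : DataFrame of predictor columns (an intercept is added).
    feature_names : predictor names, in exog column order.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame):
        endog = np.asarray(endog, dtype=np.float64)
        uniq = np.unique(endog)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("endog must be coded 0/1")
        if len(uniq) < 2:
            raise ValueError(
                "outcome is constant (single class present): model is not "
                "identifiable"
            )
        constant = [c for c in exog.columns if exog[c].nunique() <= 1]
        if constant:
            raise ValueError(f"constant feature column(s): {constant}")
        self.endog = endog
        self.exog = exog.reset_index(drop=True)
        self.feature_names = tuple(exog.columns)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        features: Sequence[str],
        label: str = "label",
        positive: str = "malignant",
    ) -> "BinaryNomogram":
        """Build from a feature table with a categorical label column.

        ``positive`` names the class coded 1 (malignant by default, which
        fixes the coefficient signs: entropy is higher in malignant tissue
        and carries a positive coefficient).
        """
        y = (table[label] == positive).to_numpy()
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(
                f"label column has a single class relative to positive="
                f"{positive!r}; observed labels: {sorted(table[label].unique())}"
            )
        return cls(y.astype(float), table.loc[:, list(features)])

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "NomogramResults":
        """Maximum-likelihood fit via Newton scoring (IRLS).

        Converged when the relative log-likelihood change drops below *tol*
        or after *maxiter* iterations; perfect separation raises rather
        than returning divergent coefficients.
        """
        x = sm.add_constant(self.exog, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = sm.Logit(self.endog, x).fit(
                    method="newton", maxiter=maxiter, tol=tol, disp=False
                )
            except PerfectSeparationWarning as exc:
                raise ValueError(
                    "perfect separation detected: logistic MLE does not "
                    "exist (coefficients diverge)"
                ) from exc
        if not res.mle_retvals.get("converged", False):
            raise ValueError(
                "logistic fit failed to converge in "
                f"{maxiter} iterations (possible quasi-separation)"
            )
        return NomogramResults(self, res)


class NomogramResults:
    """Fitted logistic model: estimates, uncertainty, nomogram, scoring."""

    def __init__(self, model: BinaryNomogram, sm_results):
        self.model = model
        self._res = sm_results
        self.params: pd.Series = sm_results.params
        self.bse: pd.Series = sm_results.bse
        self.cov_params: pd.DataFrame = sm_results.cov_params()
        self.converged: bool = bool(sm_results.mle_retvals.get("converged"))
        self.niter: int = int(sm_results.mle_retvals.get("iterations", -1))
        self.llf: float = float(sm_results.llf)
        self.nobs: int = int(sm_results.nobs)

    # -- inference ---------------------------------------------------------

    def wald_table(self, include_const: bool = True) -> pd.DataFrame:
        """Wald chi2, p, OR and 95% CI per coefficient (OR suppressed for
        the intercept, which has no odds-ratio reading)."""
        tab = wald_table_from(self.params, self.bse)
        if not include_const and "const" in tab.index:
            tab = tab.drop(index="const")
        if include_const and "const" in tab.index:
            tab.loc["const", ["or", "or_ci_low", "or_ci_high"]] = np.nan
        return tab

    def coefficients(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.params.items()}

    # -- prediction --------------------------------------------------------

    def predict(self, table: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Predicted malignancy probability for each row of *table*."""
        if isinstance(table, Mapping):
            table = pd.DataFrame([table])
        missing = [f for f in self.model.feature_names if f not in table.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        return logistic_score(self.coefficients(), table)

    # -- nomogram ----------------------------------------------------------

    def nomogram(
        self, ranges: Mapping[str, tuple[float, float]] | None = None
    ) -> NomogramSpec:
        """Points-scale presentation of the fitted model.

        *ranges* default to the observed min/max of the training features.
        The reference end of each axis (0 points) is its low-risk end given
        the coefficient sign; a zero-width range contributes a flat 0-point
        axis (with a warning) rather than failing.
        """
        feats = self.model.feature_names
        if ranges is None:
            ranges = {
                f: (float(self.model.exog[f].min()), float(self.model.exog[f].max()))
                for f in feats
            }
        spans = {}
        zero_width = []
        for f in feats:
            lo, hi = ranges[f]
            if not np.isfinite([lo, hi]).all():
                raise ValueError(f"non-finite range for {f!r}")
            span = abs(self.params[f]) * (hi - lo)
            if span == 0.0:
                warnings.warn(
                    f"zero-width range (or zero coefficient) for {f!r}: "
                    "flat 0-point axis",
                    stacklevel=2,
                )
                zero_width.append(f)
            spans[f] = span
        max_span = max(spans.values())
        if max_span == 0.0:
            raise ValueError("all nomogram axes are degenerate")
        scale = max_span / 100.0  # log-odds per point
        ref = {}
        for f in feats:
            lo, hi = ranges[f]
            ref[f] = lo if self.params[f] >= 0 else hi
        base_eta = float(
            self.params["const"] + sum(self.params[f] * ref[f] for f in feats)
        )
        return NomogramSpec(
            features=feats,
            beta={f: float(self.params[f]) for f in feats},
            ranges={f: (float(ranges[f][0]), float(ranges[f][1])) for f in feats},
            ref=ref,
            scale=scale,
            base_eta=base_eta,
            zero_width=tuple(zero_width),
        )

    # -- presentation / persistence ---------------------------------------

    def summary(self) -> str:
        """Human-readable coefficient and odds-ratio summary."""
        tab = self.wald_table()
        lines = [
            "Binary logistic nomogram model (positive class coded 1)",
            f"  n = {self.nobs}, log-likelihood = {self.llf:.3f}, "
            f"iterations = {self.niter}",
            "",
            f"  {'variable':<12}{'beta':>10}{'SE':>9}{'Wald chi2':>11}"
            f"{'p':>10}{'OR':>10}  {'OR 95% CI':>18}",
        ]
        for name, row in tab.iterrows():
            p = "<0.001" if row["p"] < 0.001 else f"{row['p']:.3f}"
            if np.isnan(row["or"]):
                or_s, ci_s = "-", "-"
            else:
                or_s = f"{row['or']:.3f}"
                ci_s = f"{row['or_ci_low']:.3f}-{row['or_ci_high']:.3f}"
            lines.append(
                f"  {name:<12}{row['beta']:>10.3f}{row['se']:>9.3f}"
                f"{row['wald_chi2']:>11.3f}{p:>10}{or_s:>10}  {ci_s:>18}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None, **metadata) -> str:
        """Serialize coefficients, SEs and covariance (plus metadata)."""
        payload = {
            "features": list(self.model.feature_names),
            "beta": self.coefficients(),
            "se": {k: float(v) for k, v in self.bse.items()},
            "cov": self.cov_params.to_numpy().tolist(),
            "label_encoding": {"positive": 1, "negative": 0},
            "n": self.nobs,
            "metadata": metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def select_variables(
    table: pd.DataFrame,
    candidates: Sequence[str],
    label: str = "label",
    positive: str = "malignant",
    alpha: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Two-stage variable selection: univariate screen, then backward
    elimination on multivariable Wald p-values.

    Stage 1 keeps candidates whose two-sample pooled t-test between classes
    is significant at *alpha*.  Stage 2 repeatedly refits the multivariable
    logistic model and drops the variable with the largest Wald p >= alpha
    until all survivors are significant.  Returns the final subset and a
    step-by-step trace (auditable record of every elimination).  An empty
    survivor set is returned with a warning rather than an error.
    """
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValueError(f"candidate(s) not in table: {missing}")
    trace: list[dict] = []

    kept: list[str] = []
    for c in candidates:
        res = pooled_t_from_data(table, c, group_key=label)
        passed = res.p < alpha
        trace.append(
            {"stage": "univariate", "variable": c, "t": res.t, "p": res.p,
             "kept": passed}
        )
        if passed:
            kept.append(c)

    while kept:
        fit = BinaryNomogram.from_dataframe(table, kept, label, positive).fit()
        wt = fit.wald_table(include_const=False)
        worst = wt["p"].idxmax()
        if wt.loc[worst, "p"] < alpha:
            break
        trace.append(
            {"stage": "backward", "variable": worst,
             "p": float(wt.loc[worst, "p"]), "kept": False}
        )
        kept = [c for c in kept if c != worst]

    if not kept:
        warnings.warn("no candidate survived selection", stacklevel=2)
    return kept, trace
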
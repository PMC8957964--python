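"""Sparse methylation-based BMI predictor.

The model regresses the transformed trait F(BMI) on beta values with an
L1 (lasso) penalty. The penalty strength is chosen by k-fold
cross-validation over a pathwise grid of 100 log-spaced values running from
lambda_max — the smallest penalty that zeroes every coefficient — down to
a fraction of lambda_max (1e-4 when samples outnumber features, 1e-2
otherwise, the usual pathwise convention), taking the lambda.min rule
(minimum mean CV squared error; ties break toward the sparser, larger
penalty). Features are
standardized inside each fit and coefficients are reported back on the
original beta scale, so the stored model is `intercept + sum coef_p * beta_p`
on the transformed trait scale; predictions are mapped back to kg/m2 with
the exact inverse transform.

Usage follows the model/results convention::

    model = DMBMI(beta, bmi)                # or DMBMI.from_dataframe(...)
    res = model.fit(cv_folds=10, seed=0)    # DMBMIResults
    res.summary()
    dm_bmi = res.predict(new_beta)          # kg/m2
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .containers import BetaMatrix
from .transform import TraitTransform

N_LAMBDA = 100


def _lambda_min_ratio(n_samples: int, n_features: int) -> float:
    """Depth of the penalty path, following the pathwise-fitting convention:
    deeper (1e-4) when samples outnumber features, shallow (1e-2) otherwise."""
    return 1e-4 if n_samples > n_features else 1e-2


class DegenerateFitError(ValueError):
    """The response carries no variation to regress on."""


class MissingFeatureError(KeyError):
    """A probe required by a fitted model is absent from the input matrix."""


@dataclass
class CVResult:
    """Cross-validation curve over the descending penalty grid."""

    lambda_grid: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.mean_mse = np.asarray(self.mean_mse, dtype=float)
        self.se_mse = np.asarray(self.se_mse, dtype=float)
        if not (len(self.lambda_grid) == len(self.mean_mse) == len(self.se_mse)):
            raise ValueError("CV grids must be aligned")
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly descending")
        if np.any(self.mean_mse < 0):
            raise ValueError("mean CV MSE cannot be negative")

    @property
    def lambda_min(self) -> float:
        """Penalty minimizing mean CV MSE; ties go to the larger lambda."""
        return float(self.lambda_grid[int(np.argmin(self.mean_mse))])


@dataclass
class DMBMIModel:
    """Fitted sparse predictor: intercept + nonzero per-probe weights."""

    intercept: float
    coefficients: dict[str, float]
    lambda_selected: float
    cv_folds: int
    seed: int
    transform: TraitTransform = field(default_factory=TraitTransform)

    def __post_init__(self) -> None:
        if any(w == 0.0 for w in self.coefficients.values()):
            raise ValueError("only nonzero coefficients may be stored")
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError("duplicate probes in coefficients")

    @property
    def support(self) -> list[str]:
        return list(self.coefficients)

    def linear_score(self, beta: BetaMatrix) -> np.ndarray:
        """Per-sample score on the transformed trait scale."""
        probes = self.support
        present = set(beta.probe_ids)
        absent = [p for p in probes if p not in present]
        if absent:
            raise MissingFeatureError(
                f"model probes absent from matrix: {absent[:10]}"
            )
        if not probes:
            return np.full(beta.n_samples, self.intercept)
        sub = beta.subset_probes(probes)
        if np.isnan(sub.values).any():
            raise ValueError("missing values among model probes")
        w = np.array([self.coefficients[p] for p in probes])
        return self.intercept + w @ sub.values

    def predict(self, beta: BetaMatrix) -> np.ndarray:
        """Per-sample DM-BMI in kg/m2."""
        return np.asarray(self.transform.inverse(self.linear_score(beta)))

    def to_json(self) -> str:
        return json.dumps({
            "healthy_bmi": self.transform.healthy_bmi,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda_selected": self.lambda_selected,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DMBMIModel":
        d = json.loads(text)
        return cls(intercept=float(d["intercept"]),
                   coefficients={str(k): float(v)
                                 for k, v in d["coefficients"].items()},
                   lambda_selected=float(d["lambda_selected"]),
                   cv_folds=int(d["cv_folds"]),
                   seed=int(d["seed"]),
                   transform=TraitTransform(float(d["healthy_bmi"])))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return Z, mean, sd


def _lasso_path_mse(X_train, y_train, X_test, y_test, lambdas):
    """Test MSE along the path, standardizing on the training fold."""
    Z, mean, sd = _standardize(X_train)
    ybar = y_train.mean()
    _, coefs, _ = lasso_path(Z, y_train - ybar, alphas=lambdas, max_iter=10000,
                            tol=1e-6)
    safe = np.where(sd > 0, sd, 1.0)
    Zt = (X_test - mean) / safe
    Zt[:, sd == 0] = 0.0
    pred = ybar + Zt @ coefs  # n_test x n_lambda
    resid = pred - y_test[:, None]
    return (resid**2).mean(axis=0)


class DMBMI:
    """Lasso model of transformed BMI on a beta-value matrix.

    Parameters
    ----------
    beta : BetaMatrix
        Complete (imputed) probes x samples matrix.
    bmi : array-like
        Per-sample BMI in kg/m2, aligned with ``beta.sample_ids``.
    transform : TraitTransform, optional
        The piecewise trait map; defaults to the healthy-BMI-25 anchor.
    """

    def __init__(self, beta: BetaMatrix, bmi, transform: TraitTransform | None = None):
        if np.isnan(beta.values).any():
            raise ValueError("fit requires a complete matrix; impute first")
        bmi = np.asarray(bmi, dtype=float)
        if bmi.shape != (beta.n_samples,):
            raise ValueError("bmi must align with beta samples")
        self.beta = beta
        self.bmi = bmi
        self.transform = transform or TraitTransform()
        self.endog = np.asarray(self.transform.forward(bmi))
        self.exog = beta.values.T  # samples x probes

    @classmethod
    def from_dataframe(cls, beta_frame: pd.DataFrame, clinical: pd.DataFrame,
                       bmi_col: str = "bmi",
                       transform: TraitTransform | None = None) -> "DMBMI":
        """Build from a probes x samples frame and a clinical table.

        ``clinical`` must be indexed by (or contain a ``sample_id`` column
        matching) the beta columns.
        """
        if "sample_id" in clinical.columns:
            clinical = clinical.set_index("sample_id")
        bmi = clinical.loc[list(beta_frame.columns), bmi_col].to_numpy(float)
        return cls(BetaMatrix.from_frame(beta_frame), bmi, transform)

    def fit(self, cv_folds: int = 10, seed: int = 0) -> "DMBMIResults":
        """Pathwise lasso with k-fold CV penalty selection (lambda.min)."""
        X, y = self.exog, self.endog
        n = X.shape[0]
        if cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if n < cv_folds:
            raise ValueError(f"need at least cv_folds={cv_folds} samples, got {n}")
        if np.ptp(y) == 0:
            raise DegenerateFitError("response is constant; nothing to fit")

        Z, mean, sd = _standardize(X)
        yc = y - y.mean()
        lam_max = float(np.max(np.abs(Z.T @ yc)) / n)
        if lam_max == 0:
            raise DegenerateFitError("all features are uncorrelated constants")
        ratio = _lambda_min_ratio(*X.shape)
        lambdas = np.geomspace(lam_max, ratio * lam_max, N_LAMBDA)

        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        fold_mse = np.empty((cv_folds, N_LAMBDA))
        for f, (tr, te) in enumerate(kf.split(X)):
            fold_mse[f] = _lasso_path_mse(X[tr], y[tr], X[te], y[te], lambdas)
        cv = CVResult(lambdas, fold_mse.mean(axis=0),
                      fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds))

        lam = cv.lambda_min
        _, coefs, _ = lasso_path(Z, yc, alphas=[lam], max_iter=10000, tol=1e-6)
        w_std = coefs[:, 0]
        safe = np.where(sd > 0, sd, 1.0)
        w = np.where(sd > 0, w_std / safe, 0.0)
        intercept = float(y.mean() - w @ mean)
        coefficients = {p: float(c)
                        for p, c in zip(self.beta.probe_ids, w) if c != 0.0}
        model = DMBMIModel(intercept=intercept, coefficients=coefficients,
                           lambda_selected=lam, cv_folds=cv_folds, seed=seed,
                           transform=self.transform)
        return DMBMIResults(self, model, cv)


class DMBMIResults:
    """Fit results: the sparse model, the CV curve, and diagnostics."""

    def __init__(self, model_spec: DMBMI, model: DMBMIModel, cv: CVResult):
        self.model_spec = model_spec
        self.model = model
        self.cv_result = cv

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.model.coefficients, dtype=float)
        return pd.concat([pd.Series({"intercept": self.model.intercept}), s])

    @property
    def support(self) -> list[str]:
        return self.model.support

    def predict(self, beta: BetaMatrix | None = None) -> np.ndarray:
        """DM-BMI (kg/m2) for new samples; training samples if beta is None."""
        return self.model.predict(beta if beta is not None else self.model_spec.beta)

    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def evaluate(self, truth=None) -> dict:
        """Agreement of in-sample DM-BMI with (true) BMI."""
        truth = self.model_spec.bmi if truth is None else np.asarray(truth, float)
        return evaluate_predictions(self.predict(), truth)

    def summary(self) -> str:
        m = self.model
        rep = self.evaluate()
        lines = [
            "DM-BMI lasso fit",
            "=" * 46,
            f"samples:            {self.model_spec.beta.n_samples}",
            f"probes offered:     {self.model_spec.beta.n_probes}",
            f"probes selected:    {len(m.coefficients)}",
            f"lambda (lambda.min): {m.lambda_selected:.6g}",
            f"CV folds / seed:    {m.cv_folds} / {m.seed}",
            f"healthy BMI anchor: {m.transform.healthy_bmi}",
            f"intercept:          {m.intercept:.6g}",
            f"in-sample Spearman r: {rep['spearman_r']:.4f}",
            f"paired t vs BMI:    t={rep['t_stat']:.4g}, df={rep['df']},"
            f" p={rep['p_value']:.4g}",
        ]
        if m.coefficients:
            lines.append("-" * 46)
            lines.append(f"{'probe':<16}{'coefficient':>14}")
            for p, w in sorted(m.coefficients.items(),
                               key=lambda kv: -abs(kv[1])):
                lines.append(f"{p:<16}{w:>14.6g}")
        return "\n".join(lines)


def fit_dm_bmi(beta: BetaMatrix, bmi, t: TraitTransform | None = None,
               cv_folds: int = 10, seed: int = 0):
    """Functional wrapper: returns ``(DMBMIModel, CVResult)``."""
    res = DMBMI(beta, bmi, t).fit(cv_folds=cv_folds, seed=seed)
    return res.model, res.cv_result


def predict_dm_bmi(m: DMBMIModel, beta: BetaMatrix) -> np.ndarray:
    """Apply a fitted model; returns DM-BMI per sample in kg/m2."""
    return m.predict(beta)


def evaluate_predictions(pred, truth) -> dict:
    """Spearman correlation and paired t-test between predictions and truth.

    Returns a dict with spearman_r, spearman_p, t_stat, df, p_value and a
    ``t_undefined`` flag set when the paired differences have zero variance
    (the t statistic is then reported as NaN rather than infinite).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be aligned 1-D arrays")
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    r, rp = stats.spearmanr(pred, truth)
    diff = pred - truth
    df = n - 1
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return {"spearman_r": float(r), "spearman_p": float(rp),
                    "t_stat": 0.0, "df": df, "p_value": 1.0,
                    "t_undefined": False}
        return {"spearman_r": float(r), "spearman_p": float(rp),
                "t_stat": float("nan"), "df": df, "p_value": float("nan"),
                "t_undefined": True}
    t, p = stats.ttest_rel(pred, truth)
    return {"spearman_r": float(r), "spearman_p": float(rp),
            "t_stat": float(t), "df": df, "p_value": float(p),
            "t_undefined": False}
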
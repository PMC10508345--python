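"""L1-penalised logistic Pt-score model and correlated-ROC comparison.

The integration model is an L1-penalised (lasso) logistic regression of
platinum sensitivity on the assembled genomic features.  The penalty
weight lambda multiplies the L1 norm of the coefficients in the
per-observation objective

    (1/n) * deviance(beta) + lambda * ||beta||_1

(the intercept is unpenalised) and is chosen by stratified K-fold
cross-validated deviance over a log-spaced grid.  Continuous features
are standardised inside the fitting routine; the standardisation
parameters are stored on the results object so a fitted model is a
self-contained scoring document.

The Pt-score of a sample is the linear predictor, a monotone transform
of the predicted sensitivity probability.  Model performance is
measured by ROC AUC (rank formula, ties counted half) and compared to a
baseline score on the same samples with DeLong's placement-value test
for paired ROC curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["roc_auc", "delong_test", "RocComparison", "PtScoreModel", "PtScoreResults"]


def roc_auc(scores, labels) -> float:
    """AUC = P(score_case > score_control) + 0.5 P(tie), by midranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)  # midranks
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class RocComparison:
    """Paired-AUC comparison by DeLong's method."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov: float
    z: float
    p_value: float
    comparable: bool = True


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one score vector."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    # V10[i]: fraction of controls a case i beats (ties half)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return v10, v01, auc


def delong_test(scores_a, scores_b, labels) -> RocComparison:
    """DeLong's test for two correlated ROC AUCs on the same samples.

    Variance/covariance of the AUC estimates come from the empirical
    covariance of per-case and per-control placement values; the z
    statistic is the AUC difference over its standard error, with a
    two-sided normal p-value.  Degenerate placement variance (e.g. one
    score constant) is reported as non-comparable rather than raising;
    identical score vectors give z = 0, p = 1.
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(y) or len(b) != len(y):
        raise ValueError("scores and labels must have equal length")
    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValueError("need at least two cases and two controls")
    s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2 across scores
    s01 = np.cov(np.vstack([v01a, v01b]))
    S = s10 / m + s01 / n
    var_a, var_b, cov = S[0, 0], S[1, 1], S[0, 1]
    var_diff = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        if abs(diff) < 1e-12:
            return RocComparison(auc_a, auc_b, var_a, var_b, cov, 0.0, 1.0, True)
        return RocComparison(
            auc_a, auc_b, var_a, var_b, cov, float("nan"), float("nan"), False
        )
    z = diff / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return RocComparison(auc_a, auc_b, var_a, var_b, cov, float(z), float(min(p, 1.0)))


def _is_binary_col(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return np.isin(vals, [0.0, 1.0]).all()


class PtScoreModel:
    """Penalised-logistic platinum-sensitivity model, built from data.

    Parameters
    ----------
    features : pandas.DataFrame
        Samples x named features.  Binary columns (values in {0,1}) are
        used as-is; continuous columns are standardised at fit time.
    outcome : array-like
        Binary platinum sensitivity (1 sensitive, 0 resistant), aligned
        with ``features`` rows, no missing values.
    """

    def __init__(self, features: pd.DataFrame, outcome):
        y = np.asarray(outcome).astype(int)
        if len(y) != len(features):
            raise ValueError("outcome length does not match features")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
            raise ValueError("need at least two samples per outcome class")
        self.feature_names = list(features.columns)
        self.X = features.to_numpy(dtype=float)
        self.y = y
        self.is_binary = np.array([_is_binary_col(self.X[:, j]) for j in range(self.X.shape[1])])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome_col: str = "pt_sensitive", features=None
    ) -> "PtScoreModel":
        if outcome_col not in df.columns:
            raise ValueError(f"missing outcome column {outcome_col!r}")
        if features is None:
            features = [c for c in df.columns if c != outcome_col]
        return cls(df[list(features)], df[outcome_col])

    # -- internals ---------------------------------------------------------

    def _standardize(self):
        means = self.X.mean(axis=0)
        scales = self.X.std(axis=0, ddof=0)
        means[self.is_binary] = 0.0
        scales[self.is_binary] = 1.0
        scales[scales == 0] = 1.0
        return means, scales

    def _fit_at(self, Xs, y, lam: float, seed: int):
        n = len(y)
        ybar = y.mean()
        if lam > 0:
            # KKT: at or above lam_max the solution is exactly beta = 0
            # with the intercept at the outcome log-odds
            lam_max = np.abs(Xs.T @ (y - ybar)).max() / n
            if lam >= lam_max:
                return np.zeros(Xs.shape[1]), float(np.log(ybar / (1 - ybar)))
        if lam <= 0:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
        else:
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (n * lam),
                solver="saga",
                max_iter=30000,
                tol=1e-6,
                random_state=seed,
            )
        clf.fit(Xs, y)
        return clf.coef_[0].copy(), float(clf.intercept_[0])

    def default_lambda_grid(self, n_points: int = 8) -> np.ndarray:
        """Log-spaced grid below the smallest lambda zeroing all coefficients."""
        means, scales = self._standardize()
        Xs = (self.X - means) / scales
        ybar = self.y.mean()
        lam_max = np.abs(Xs.T @ (self.y - ybar)).max() / len(self.y)
        return lam_max * np.logspace(0, -2.5, n_points)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        lambdas=None,
        folds: int = 10,
        seed: int = 0,
        lambda_: float | None = None,
    ) -> "PtScoreResults":
        """Fit the lasso-logistic model.

        ``lambda_`` fixes the penalty directly; otherwise it is chosen
        from ``lambdas`` (default: an automatic log-spaced grid) by
        stratified ``folds``-fold cross-validated deviance, ties broken
        toward the sparser (larger) penalty.  Deterministic given seed.
        """
        means, scales = self._standardize()
        Xs = (self.X - means) / scales
        cv_table = None
        if lambda_ is None:
            grid = np.sort(np.asarray(
                lambdas if lambdas is not None else self.default_lambda_grid()
            , dtype=float))[::-1]
            if len(grid) == 1:
                lambda_ = float(grid[0])
            else:
                folds_eff = min(folds, int(np.bincount(self.y).min()))
                skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
                dev = np.zeros(len(grid))
                for tr, te in skf.split(Xs, self.y):
                    for k, lam in enumerate(grid):
                        coef, icpt = self._fit_at(Xs[tr], self.y[tr], lam, seed)
                        eta = Xs[te] @ coef + icpt
                        # mean negative log-likelihood on the held-out fold
                        dev[k] += np.mean(np.log1p(np.exp(-np.abs(eta))) + np.where(
                            self.y[te] == (eta > 0), 0.0, np.abs(eta)))
                dev /= folds_eff
                cv_table = pd.DataFrame({"lambda": grid, "cv_deviance": dev})
                lambda_ = float(grid[np.argmin(dev)])  # grid descending: ties -> sparser
        coef, intercept = self._fit_at(Xs, self.y, float(lambda_), seed)
        return PtScoreResults(
            model=self,
            feature_names=self.feature_names,
            params=pd.Series(coef, index=self.feature_names),
            intercept=intercept,
            lambda_=float(lambda_),
            means=pd.Series(means, index=self.feature_names),
            scales=pd.Series(scales, index=self.feature_names),
            folds=folds,
            seed=seed,
            cv_table=cv_table,
        )


@dataclass
class PtScoreResults:
    """Fitted Pt-score model: coefficients, penalty, standardisation."""

    model: PtScoreModel | None
    feature_names: list
    params: pd.Series
    intercept: float
    lambda_: float
    means: pd.Series
    scales: pd.Series
    folds: int
    seed: int
    cv_table: pd.DataFrame | None = None

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(features.columns)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        X = features[self.feature_names].to_numpy(dtype=float)
        return (X - self.means.to_numpy()) / self.scales.to_numpy()

    def pt_score(self, features: pd.DataFrame) -> np.ndarray:
        """Linear predictor (the Pt-score) per sample."""
        return self._design(features) @ self.params.to_numpy() + self.intercept

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        eta = self.pt_score(features)
        return 1.0 / (1.0 + np.exp(-eta))

    def auc(self, features: pd.DataFrame, outcome) -> float:
        return roc_auc(self.pt_score(features), outcome)

    def compare_roc(self, features: pd.DataFrame, outcome, baseline_scores) -> RocComparison:
        """DeLong comparison of the Pt-score against a baseline score."""
        return delong_test(self.pt_score(features), baseline_scores, outcome)

    def summary(self) -> str:
        lines = [
            "Pt-score model (L1-penalised logistic regression)",
            f"  lambda = {self.lambda_:.6g}   CV folds = {self.folds}   seed = {self.seed}",
            f"  intercept = {self.intercept:+.4f}",
            f"  {'feature':<20s} {'coef':>10s} {'mean':>10s} {'scale':>10s}",
        ]
        for name in self.feature_names:
            lines.append(
                f"  {name:<20s} {self.params[name]:>+10.4f} "
                f"{self.means[name]:>10.4f} {self.scales[name]:>10.4f}"
            )
        nz = int((self.params != 0).sum())
        lines.append(f"  non-zero coefficients: {nz}/{len(self.feature_names)}")
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "feature_names": self.feature_names,
            "coefficients": self.params.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "folds": self.folds,
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PtScoreResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        names = doc["feature_names"]
        return cls(
            model=None,
            feature_names=names,
            params=pd.Series(doc["coefficients"], index=names),
            intercept=float(doc["intercept"]),
            lambda_=float(doc["lambda"]),
            means=pd.Series(doc["means"], index=names),
            scales=pd.Series(doc["scales"], index=names),
            folds=int(doc["folds"]),
            seed=int(doc["seed"]),
        )
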
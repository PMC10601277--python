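"""Penalized-logistic methylation signatures.

The response classifier is an elastic-net penalized logistic regression
on M values (or CpG-unit methylation), with the penalty weight selected
by stratified five-fold cross-validation minimizing mean binomial
deviance.  ``PenalizedLogisticSignature`` is a scikit-learn estimator so
it composes with pipelines and model selection; the refinement helpers
(arm-specific Mann-Whitney unit selection and the lasso recomposition)
are thin functions on top of it.

Objective (glmnet convention):
    minimize  -(1/n) loglik(b0, b) + lambda * [alpha*||b||_1 + (1-alpha)*||b||_2^2 / 2]

Features are standardized internally; coefficients are reported on the
input scale.  The positive class is the lexicographically larger label,
i.e. 'RD' for CR/RD labels: predicted probabilities are probabilities of
refractory disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PenalizedLogisticSignature",
    "UnitSelection",
    "fit_penalized_logistic",
    "select_refinement_units",
    "recompose_signature",
]


class PenalizedLogisticSignature(ClassifierMixin, BaseEstimator):
    """Elastic-net logistic signature with CV-selected penalty weight.

    Parameters
    ----------
    alpha : float in [0, 1]
        L1 share of the penalty (1 = lasso).
    lambdas : sequence of float, optional
        Explicit penalty path; default is ``n_lambdas`` log-spaced values
        from the smallest lambda that zeroes every coefficient down by
        ``lambda_min_ratio``.
    cv : int
        Stratified folds for deviance-based selection.
    random_state : int
        Seeds the fold assignment; recorded in the fitted model.

    Attributes
    ----------
    coef_ : ndarray, input-scale coefficients (zero-variance features 0).
    intercept_ : float
    lambda_ : selected penalty weight (minimum mean CV deviance).
    lambda_path_, cv_deviance_ : the searched path and its CV deviances.
    selected_features_ : names of features with nonzero coefficients.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lambdas=None,
        n_lambdas: int = 40,
        lambda_min_ratio: float = 1e-3,
        cv: int = 5,
        random_state: int = 0,
        max_iter: int = 5000,
        tol: float = 1e-7,
    ) -> None:
        self.alpha = alpha
        self.lambdas = lambdas
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    # -- internals --------------------------------------------------------

    def _as_array(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        return X, [f"x{j}" for j in range(X.shape[1])]

    def _lambda_path(self, Xs: np.ndarray, y01: np.ndarray) -> np.ndarray:
        if self.lambdas is not None:
            return np.sort(np.asarray(self.lambdas, dtype=float))[::-1]
        n = len(y01)
        resid = y01 - y01.mean()
        lam_max = np.abs(Xs.T @ resid).max() / (n * max(self.alpha, 1e-3))
        lam_max = max(lam_max, 1e-6)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

    def _solver(self, lam: float, n: int) -> LogisticRegression:
        if self.alpha == 1.0:
            # pure lasso: liblinear is much faster on small dense problems;
            # its (weakly) penalized intercept is corrected exactly by the
            # Newton refit after fitting
            return LogisticRegression(
                l1_ratio=1.0,
                solver="liblinear",
                C=1.0 / (n * lam),
                max_iter=self.max_iter,
                tol=self.tol,
                intercept_scaling=100.0,
                random_state=0,
            )
        return LogisticRegression(
            solver="saga",
            C=1.0 / (n * lam),
            l1_ratio=self.alpha,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=0,
        )

    @staticmethod
    def _refit_intercept(Xs: np.ndarray, y01: np.ndarray, coef: np.ndarray,
                         b0: float) -> float:
        # The intercept is unpenalized, so at the optimum it solves
        # mean(sigmoid(b0 + Xb)) = mean(y); a few Newton steps recover it
        # exactly even where saga's tiny-C steps stall.
        eta = Xs @ coef
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(b0 + eta)))
            grad = p.mean() - y01.mean()
            hess = np.mean(p * (1.0 - p))
            if hess < 1e-12 or abs(grad) < 1e-12:
                break
            b0 -= grad / hess
        return float(b0)

    @staticmethod
    def _deviance(model: LogisticRegression, Xs: np.ndarray, y01: np.ndarray) -> float:
        p = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
        return float(-2.0 * np.mean(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y):
        Xa, names = self._as_array(X)
        y = np.asarray(y)
        if np.isnan(Xa).any():
            raise ValueError("X contains missing values")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("need exactly two classes")
        y01 = (y == classes[1]).astype(float)
        counts = np.array([(y01 == v).sum() for v in (0, 1)])
        if (counts < self.cv).any():
            raise ValueError("need >= cv samples per class")

        mean = Xa.mean(axis=0)
        sd = Xa.std(axis=0)
        constant = sd == 0
        if constant.any():
            warnings.warn("constant feature(s); coefficients forced to 0",
                          stacklevel=2)
        sd_safe = np.where(constant, 1.0, sd)
        Xs = (Xa - mean) / sd_safe
        Xs[:, constant] = 0.0

        path = self._lambda_path(Xs, y01)
        folds = StratifiedKFold(self.cv, shuffle=True,
                                random_state=self.random_state)
        fold_assignment = np.empty(len(y01), dtype=int)
        deviance = np.zeros(path.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saga convergence chatter
            for f, (tr, te) in enumerate(folds.split(Xs, y01)):
                fold_assignment[te] = f
                # warm start down the path: each solution seeds the next
                model = self._solver(path[0], len(tr))
                model.warm_start = True
                for i, lam in enumerate(path):
                    model.C = 1.0 / (len(tr) * lam)
                    model.fit(Xs[tr], y01[tr])
                    deviance[i] += self._deviance(model, Xs[te], y01[te])
            deviance /= self.cv
            best = int(np.argmin(deviance))
            final = self._solver(path[0], len(y01))
            final.warm_start = True
            for lam in path[: best + 1]:
                final.C = 1.0 / (len(y01) * lam)
                final.fit(Xs, y01)

        coef_std = final.coef_.ravel()
        b0_std = self._refit_intercept(Xs, y01, coef_std,
                                       float(final.intercept_[0]))
        coef = np.where(constant, 0.0, coef_std / sd_safe)
        self.classes_ = classes
        self.coef_ = coef
        self.intercept_ = float(b0_std - np.sum(coef * mean))
        self.lambda_ = float(path[best])
        self.lambda_path_ = path
        self.cv_deviance_ = deviance
        self.fold_assignment_ = fold_assignment
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.selected_features_ = [n for n, c in zip(names, coef) if c != 0.0]
        return self

    def _validate_columns(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.feature_names_in_ if n not in X.columns]
            if missing:
                raise ValueError(f"missing feature column(s): {missing}")
            return X[list(self.feature_names_in_)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return X

    def decision_function(self, X) -> np.ndarray:
        Xa = self._validate_columns(X)
        return self.intercept_ + Xa @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "features": list(map(str, self.feature_names_in_)),
            "coefficients": [float(c) for c in self.coef_],
            "intercept": self.intercept_,
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "classes": list(map(str, self.classes_)),
            "cv_folds": self.cv,
            "seed": self.random_state,
            "fold_assignment": [int(f) for f in self.fold_assignment_],
            "selected_features": list(self.selected_features_),
        }


def fit_penalized_logistic(
    X, y, alpha: float = 0.5, folds: int = 5, random_state: int = 0, **kwargs
) -> PenalizedLogisticSignature:
    """Functional wrapper over :class:`PenalizedLogisticSignature`."""
    return PenalizedLogisticSignature(
        alpha=alpha, cv=folds, random_state=random_state, **kwargs
    ).fit(X, y)


@dataclass
class UnitSelection:
    """Arm-specific Mann-Whitney screen of CpG units.

    ``retained`` holds units significant in the azacytidine (EXP) arm and
    not significant in the standard arm — the treatment-specific hits.
    """

    exp_significant: list[str]
    std_significant: list[str]
    retained: list[str]
    p_values: pd.DataFrame = field(repr=False, default=None)


def _mwu_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    # Exact null distribution for small groups, normal approximation with
    # tie correction otherwise.
    method = "exact" if max(len(a), len(b)) <= 12 and not _has_ties(a, b) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def select_refinement_units(
    units: pd.DataFrame,
    labels: pd.Series,
    arms: pd.Series,
    alpha_level: float = 0.05,
) -> UnitSelection:
    """Two-sided Mann-Whitney CR-vs-RD per unit, within each arm.

    Retained units have p < ``alpha_level`` in EXP and p >= ``alpha_level``
    in STD, so the retained set never overlaps the standard-arm hits.
    Requires a clean (imputed) unit matrix and >=2 samples per response
    class in each arm.
    """
    labels = pd.Series(labels).reindex(units.columns)
    arms = pd.Series(arms).reindex(units.columns)
    pvals = {}
    for arm in ("EXP", "STD"):
        in_arm = arms == arm
        cr = units.columns[in_arm & (labels == "CR")]
        rd = units.columns[in_arm & (labels == "RD")]
        if len(cr) < 2 or len(rd) < 2:
            raise ValueError(f"arm {arm} has <2 samples in a response class")
        pvals[arm] = units.apply(
            lambda row: _mwu_pvalue(row[cr].to_numpy(), row[rd].to_numpy()), axis=1
        )
    p = pd.DataFrame(pvals)
    exp_sig = list(p.index[p["EXP"] < alpha_level])
    std_sig = list(p.index[p["STD"] < alpha_level])
    retained = [u for u in exp_sig if u not in std_sig]
    return UnitSelection(exp_significant=exp_sig, std_significant=std_sig,
                         retained=retained, p_values=p)


def recompose_signature(
    units: pd.DataFrame,
    labels: pd.Series,
    unit_members: pd.Series | None = None,
    random_state: int = 0,
    **kwargs,
) -> PenalizedLogisticSignature:
    """Lasso (alpha = 1) logistic refit on the retained units.

    ``units`` is units x samples (transposed internally); when
    ``unit_members`` maps unit id -> member-CpG count, the fitted model
    carries the total CpG count of the recomposed signature in
    ``n_member_cpgs_``.  An empty retained set refuses with a clear
    message; a fit that shrinks everything away is flagged degenerate.
    """
    if units.shape[0] < 1:
        raise ValueError("no retained units: nothing to recompose")
    model = PenalizedLogisticSignature(alpha=1.0, random_state=random_state,
                                       **kwargs)
    model.fit(units.T, pd.Series(labels).reindex(units.columns).to_numpy())
    model.degenerate_ = len(model.selected_features_) == 0
    if unit_members is not None:
        model.n_member_cpgs_ = int(
            sum(unit_members.get(u, 1) for u in model.selected_features_)
        )
    return model
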
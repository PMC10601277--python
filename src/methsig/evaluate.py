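"""Classifier evaluation: ROC/AUC, confusion metrics, 0.632+ bootstrap.

The 0.632+ bootstrap blends the apparent (resubstitution) error with the
leave-one-out bootstrap error, weighting by the relative overfitting rate
R against the no-information rate gamma:

    err1' = min(err1, gamma)
    R = (err1' - err_bar) / (gamma - err_bar)   (0 when the denominator
        is non-positive; clipped to [0, 1])
    w = 0.632 / (1 - 0.368 R)
    err632+ = (1 - w) err_bar + w err1'

and the AUC analogue replaces error with (1 - AUC) with gamma = 0.5.
Also provides the multivariable confounder model (unpenalized logistic
regression with Wald intervals) and the integer confusion-matrix
enumeration that reconstructs a printed sensitivity/specificity/PPV/NPV
quadruple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "roc_auc",
    "confusion_metrics",
    "ConfusionMetrics",
    "Boot632Report",
    "bootstrap_632plus",
    "fit_confounder_model",
    "enumerate_confusion",
    "merge_small_karyotypes",
]


def roc_auc(scores, labels, positive) -> tuple[pd.DataFrame, float]:
    """ROC points over all score thresholds and the rank-based AUC.

    AUC is the Mann-Whitney statistic U / (n1 n2) computed from average
    ranks, so tied scores count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n2))

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    points = []
    for t in thresholds:
        called = scores >= t
        tpr = (called & pos).sum() / n1
        fpr = (called & ~pos).sum() / n2
        points.append((t, fpr, tpr))
    roc = pd.DataFrame(points, columns=["threshold", "fpr", "tpr"])
    return roc, auc


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def misclassification(self) -> float:
        return (self.fp + self.fn) / self.n


def confusion_metrics(calls, labels, positive="CR") -> ConfusionMetrics:
    """Confusion counts and derived rates; positive class defaults to CR."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.size == 0:
        raise ValueError("empty input")
    p_call, p_true = calls == positive, labels == positive
    return ConfusionMetrics(
        tp=int((p_call & p_true).sum()),
        fn=int((~p_call & p_true).sum()),
        fp=int((p_call & ~p_true).sum()),
        tn=int((~p_call & ~p_true).sum()),
    )


def enumerate_confusion(
    sensitivity_pct: float,
    specificity_pct: float,
    ppv_pct: float,
    npv_pct: float,
    max_total: int = 57,
    positive_multiple: int = 1,
    negative_multiple: int = 1,
    tol: float = 0.05,
) -> list[ConfusionMetrics]:
    """All integer confusion matrices matching four printed rates.

    Rates are matched to within ``tol`` percentage points (half a unit of
    the last printed digit by default).  Optional divisibility
    constraints on the class totals narrow the search to cohort-plausible
    matrices.
    """
    out = []
    for p_total in range(positive_multiple, max_total + 1, positive_multiple):
        for n_total in range(negative_multiple, max_total + 1 - p_total,
                             negative_multiple):
            for tp in range(p_total + 1):
                sens = 100.0 * tp / p_total
                if abs(sens - sensitivity_pct) > tol:
                    continue
                for tn in range(n_total + 1):
                    spec = 100.0 * tn / n_total
                    if abs(spec - specificity_pct) > tol:
                        continue
                    fp, fn = n_total - tn, p_total - tp
                    if tp + fp == 0 or tn + fn == 0:
                        continue
                    ppv = 100.0 * tp / (tp + fp)
                    npv = 100.0 * tn / (tn + fn)
                    if abs(ppv - ppv_pct) <= tol and abs(npv - npv_pct) <= tol:
                        out.append(ConfusionMetrics(tp=tp, fn=fn, fp=fp, tn=tn))
    return out


@dataclass
class Boot632Report:
    err_bar: float
    err1: float
    gamma: float
    R: float
    w: float
    err632plus: float
    auc_apparent: float
    auc1: float
    auc632: float
    B: int
    seed: int
    n_redrawn: int = 0
    n_uncovered_samples: int = 0


def _632plus(err_bar: float, err1: float, gamma: float) -> tuple[float, float, float]:
    err1p = min(err1, gamma)
    denom = gamma - err_bar
    if denom > 0:
        r = (err1p - err_bar) / denom
    else:
        r = 0.0
    r = float(np.clip(r, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * r)
    return r, w, (1.0 - w) * err_bar + w * err1p


def bootstrap_632plus(
    X,
    y,
    trainer,
    B: int = 1000,
    seed: int = 0,
    positive=None,
    pooled_err1: bool = False,
) -> Boot632Report:
    """0.632+ bootstrap estimates of misclassification error and AUC.

    ``trainer(X, y)`` must run the *entire* training procedure (including
    any CV-based penalty selection) and return an object with ``predict``
    and ``predict_proba``; anything less leaks selection bias into err1.
    Resamples with a single class in-bag are redrawn (counted); samples
    never out-of-bag are dropped from err1 with a warning.  err1 averages
    each sample's out-of-bag error before pooling across samples
    (``pooled_err1`` switches to the replicate-pooled form).
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    X = pd.DataFrame(X)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need two classes")
    positive = classes[1] if positive is None else positive
    rng = np.random.default_rng(seed)

    full = trainer(X, y)
    calls = np.asarray(full.predict(X))
    err_bar = float((calls != y).mean())
    scores = np.asarray(full.predict_proba(X))[:, list(full.classes_).index(positive)]
    _, auc_apparent = roc_auc(scores, y, positive)

    p_hat = float((y == positive).mean())
    q_hat = float((calls == positive).mean())
    gamma = p_hat * (1 - q_hat) + (1 - p_hat) * q_hat

    err_sum = np.zeros(n)
    err_cnt = np.zeros(n)
    pooled_errs: list[float] = []
    oob_aucs: list[float] = []
    n_redrawn = 0
    for _ in range(B):
        for _try in range(100):
            idx = rng.integers(0, n, size=n)
            _, in_bag_counts = np.unique(y[idx], return_counts=True)
            # both classes in-bag, with enough members for a CV trainer
            if in_bag_counts.size == 2 and in_bag_counts.min() >= 2:
                break
            n_redrawn += 1
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        model = trainer(X.iloc[idx], y[idx])
        oob_calls = np.asarray(model.predict(X.iloc[oob]))
        errs = (oob_calls != y[oob]).astype(float)
        err_sum[oob] += errs
        err_cnt[oob] += 1
        pooled_errs.extend(errs)
        if np.unique(y[oob]).size == 2:
            s = np.asarray(model.predict_proba(X.iloc[oob]))[
                :, list(model.classes_).index(positive)
            ]
            _, a = roc_auc(s, y[oob], positive)
            oob_aucs.append(a)

    uncovered = int((err_cnt == 0).sum())
    if uncovered:
        warnings.warn(
            f"{uncovered} sample(s) never out-of-bag; increase B", stacklevel=2
        )
    if pooled_err1:
        err1 = float(np.mean(pooled_errs))
    else:
        covered = err_cnt > 0
        err1 = float(np.mean(err_sum[covered] / err_cnt[covered]))
    r, w, err632 = _632plus(err_bar, err1, gamma)

    auc1 = float(np.mean(oob_aucs)) if oob_aucs else float("nan")
    _, _, e632_auc = _632plus(1.0 - auc_apparent, 1.0 - auc1, 0.5)
    return Boot632Report(
        err_bar=err_bar,
        err1=err1,
        gamma=gamma,
        R=r,
        w=w,
        err632plus=err632,
        auc_apparent=auc_apparent,
        auc1=auc1,
        auc632=1.0 - e632_auc,
        B=B,
        seed=seed,
        n_redrawn=n_redrawn,
        n_uncovered_samples=uncovered,
    )


def merge_small_karyotypes(karyotype: pd.Series, min_n: int = 3) -> pd.Series:
    """Collapse karyotype groups smaller than ``min_n`` into 'other'."""
    counts = karyotype.value_counts()
    small = counts.index[counts < min_n]
    return karyotype.where(~karyotype.isin(small), "other")


def fit_confounder_model(
    signature_score: pd.Series,
    covariates: pd.DataFrame,
    y: pd.Series,
    positive="RD",
) -> pd.DataFrame:
    """Multivariable logistic regression of response on signature + covariates.

    Categorical covariates are dummy-coded (first level dropped).  Returns
    a coefficient table with Wald 95% CIs and p-values.  Collinear designs
    are flagged (``collinear`` attr); perfect separation falls back to an
    L2-penalized fit with the ``penalized_fallback`` flag and no CIs.
    """
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X.insert(0, "signature", np.asarray(signature_score, dtype=float))
    n, p = X.shape
    if n < 10 * (p + 1):
        warnings.warn(
            f"n={n} below 10 x {p + 1} coefficients; estimates may be unstable",
            stacklevel=2,
        )
    y01 = (np.asarray(y) == positive).astype(float)
    design = sm.add_constant(X)
    collinear = np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]

    table = None
    fallback = False
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            warnings.simplefilter("error", category=ConvergenceWarning)
            fit = sm.Logit(y01, design).fit(disp=0)
        if not np.isfinite(fit.bse).all() or (np.abs(fit.params) > 50).any():
            raise ValueError("separation suspected")
        ci = fit.conf_int()
        table = pd.DataFrame(
            {
                "coef": fit.params,
                "se": fit.bse,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_value": fit.pvalues,
            }
        )
    except Exception:
        fallback = True
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=5000)  # ridge-penalized
        lr.fit(design.to_numpy()[:, 1:], y01)  # constant handled by intercept
        coefs = np.concatenate([[lr.intercept_[0]], lr.coef_.ravel()])
        table = pd.DataFrame(
            {
                "coef": coefs,
                "se": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
            },
            index=design.columns,
        )
    table.attrs["collinear"] = bool(collinear)
    table.attrs["penalized_fallback"] = fallback
    return table
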
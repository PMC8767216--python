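"""Criticality decision boundaries: logistic model classes and scoring.

Each network of an ensemble contributes one record ``(k, p, <k_e>,
zeta, R)`` with binary regime label ``R = 1`` for chaotic (``zeta > 1``).
Six logistic model classes of increasing complexity are fitted to predict
``R``, with the connectivity term ``kappa`` taken either as the
structural in-degree ``k`` or the mean effective connectivity ``<k_e>``:

    1. c1*kappa
    2. c1*kappa*p(1-p)
    3. c1*kappa + c2*p(1-p)
    4. c1*kappa + c2*kappa*p(1-p)
    5. c1*kappa*p(1-p) + c2*p(1-p)
    6. c1*kappa + c2*kappa*p(1-p) + c3*p(1-p)

A fitted logistic ``beta0 + sum_i beta_i * t_i`` is rearranged into the
boundary form ``sum_i c_i * t_i = 1`` with ``c_i = -beta_i / beta0`` (the
0.5-probability locus), which makes the class-2 fits directly comparable
with the classical structural criticality condition ``2 k p(1-p) = 1``.
Model performance is scored with MCC, AUC and McFadden's pseudo-R2 under
nested fourfold cross-validation (4 outer x 4 inner = 16 folds).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

__all__ = [
    "MODEL_TERMS",
    "RegimeRecord",
    "FittedBoundary",
    "MetricReport",
    "TTestResult",
    "records_frame",
    "fit_model",
    "fit_interaction_model",
    "st_theoretical_classify",
    "score",
    "mcfadden_r2",
    "nested_cv",
    "paired_one_sided_t_test",
    "pareto_select",
]

# term names per model class; "kappa" resolves to k or mean_ke at fit time
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("kappa",),
    2: ("kappa*pq",),
    3: ("kappa", "pq"),
    4: ("kappa", "kappa*pq"),
    5: ("kappa*pq", "pq"),
    6: ("kappa", "kappa*pq", "pq"),
}


@dataclass(frozen=True)
class RegimeRecord:
    """One network's features and its Derrida regime label."""

    k: int
    p: float
    mean_ke: float
    zeta: float
    chaotic: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"bias must lie in (0, 1), got {self.p}")
        if self.mean_ke > self.k + 1e-9:
            raise ValueError("mean k_e cannot exceed k")


def records_frame(records) -> pd.DataFrame:
    """DataFrame with columns k, p, mean_ke, zeta, chaotic, pq."""
    df = pd.DataFrame(
        [
            {"k": r.k, "p": r.p, "mean_ke": r.mean_ke, "zeta": r.zeta,
             "chaotic": int(r.chaotic)}
            for r in records
        ]
        if not isinstance(records, pd.DataFrame)
        else records
    )
    df = df.copy()
    df["pq"] = df["p"] * (1.0 - df["p"])
    return df


def _design(df: pd.DataFrame, terms: tuple[str, ...], kappa: str) -> np.ndarray:
    kap = df["k"] if kappa == "k" else df["mean_ke"]
    pq = df["p"] * (1.0 - df["p"])
    cols = []
    for t in terms:
        if t == "kappa":
            cols.append(kap.to_numpy(float))
        elif t == "pq":
            cols.append(pq.to_numpy(float))
        elif t == "kappa*pq":
            cols.append((kap * pq).to_numpy(float))
        elif t == "kappa_k*kappa_ke":
            cols.append((df["k"] * df["mean_ke"]).to_numpy(float))
        elif t == "k":
            cols.append(df["k"].to_numpy(float))
        elif t == "mean_ke":
            cols.append(df["mean_ke"].to_numpy(float))
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown term {t}")
    return np.column_stack(cols)


@dataclass
class FittedBoundary:
    """A fitted logistic model rearranged into ``sum c_i * term_i = 1``."""

    class_id: int
    kappa: str  # "k" or "ke" (or "mixed" for the interaction model)
    terms: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    boundary: dict[str, float]
    converged: bool
    threshold: float = 0.5
    llf: float = float("nan")

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.terms, "k" if self.kappa == "k" else "mean_ke")
        beta = np.array([self.coefficients[t] for t in self.terms])
        return self.intercept + X @ beta

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        z = self.linear_predictor(df)
        return special.expit(z)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Binary regime prediction; ties at the threshold go to chaotic."""
        return (self.predict_proba(df) >= self.threshold).astype(int)

    @property
    def critical_kappa(self) -> float:
        """For class 1: the boundary value ``kappa^c = 1 / c1``."""
        if self.terms != ("kappa",):
            raise ValueError("critical_kappa is defined for class 1 only")
        return 1.0 / self.boundary["kappa"]


def _fit_logistic(
    y: np.ndarray, X: np.ndarray, terms: tuple[str, ...], class_id: int,
    kappa: str,
) -> FittedBoundary:
    if len(np.unique(y)) < 2:
        raise ValueError("need both regime labels to fit a boundary")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(method="lbfgs", maxiter=2000, disp=0)
    params = np.asarray(res.params, dtype=float)
    intercept, betas = params[0], params[1:]
    # perfect separation / singular Hessian show up as warnings; fold them
    # into the convergence flag rather than aborting the fit
    converged = (
        bool(res.mle_retvals.get("converged", True))
        and np.all(np.isfinite(params))
        and not caught
    )
    if intercept == 0.0:
        boundary = {t: math.inf for t in terms}
    else:
        boundary = {t: float(-b / intercept) for t, b in zip(terms, betas)}
    return FittedBoundary(
        class_id=class_id,
        kappa=kappa,
        terms=terms,
        intercept=float(intercept),
        coefficients={t: float(b) for t, b in zip(terms, betas)},
        boundary=boundary,
        converged=converged,
        llf=float(res.llf),
    )


def fit_model(records, class_id: int, kappa: str = "ke") -> FittedBoundary:
    """Maximum-likelihood logistic fit of one model class.

    ``kappa`` selects the connectivity variable: ``"k"`` (structural) or
    ``"ke"`` (mean effective connectivity).  Perfect separation does not
    abort the fit; the returned boundary carries ``converged=False`` when
    the optimizer flags trouble.
    """
    if class_id not in MODEL_TERMS:
        raise ValueError(f"model class must be 1..6, got {class_id}")
    if kappa not in ("k", "ke"):
        raise ValueError(f"kappa must be 'k' or 'ke', got {kappa!r}")
    df = records_frame(records)
    terms = MODEL_TERMS[class_id]
    X = _design(df, terms, kappa)
    return _fit_logistic(df["chaotic"].to_numpy(int), X, terms, class_id, kappa)


def fit_interaction_model(records) -> FittedBoundary:
    """Logistic fit on terms ``{k, <k_e>, k*<k_e>}`` (interaction model)."""
    df = records_frame(records)
    terms = ("k", "mean_ke", "kappa_k*kappa_ke")
    X = _design(df, terms, "ke")
    return _fit_logistic(df["chaotic"].to_numpy(int), X, terms,
                         class_id=0, kappa="mixed")


def st_theoretical_classify(k, p):
    """Structural-theory label: chaotic iff ``2 k p (1-p) > 1``."""
    val = 2.0 * np.asarray(k, float) * np.asarray(p, float) * (
        1.0 - np.asarray(p, float))
    out = (val > 1.0).astype(int)
    return out if out.ndim else int(out)


@dataclass(frozen=True)
class MetricReport:
    """Binary classification scores plus confusion counts."""

    mcc: float
    auc: float
    r2: float
    tp: int
    fp: int
    tn: int
    fn: int


def mcfadden_r2(ll_model: float, ll_null: float) -> float:
    """``1 - LL(model) / LL(intercept-only)``; 1.0 when both are zero."""
    if ll_null == 0.0:
        return 1.0 if ll_model == 0.0 else -math.inf
    return 1.0 - ll_model / ll_null


def score(predictions, labels, scores=None,
          ll_model: float | None = None,
          ll_null: float | None = None) -> MetricReport:
    """MCC (explicit confusion formula), AUC (rank statistic), McFadden R2.

    ``scores`` are continuous ranking scores for AUC (``nan`` if omitted
    or single-class); ``ll_model``/``ll_null`` give the log-likelihoods
    for McFadden's R2 (``nan`` if omitted).  Any zero factor in the MCC
    denominator yields MCC = 0.
    """
    y_pred = np.asarray(predictions, int)
    y_true = np.asarray(labels, int)
    if y_pred.shape != y_true.shape or y_pred.size == 0:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, np.asarray(scores, float)))
    else:
        auc = float("nan")
    if ll_model is not None and ll_null is not None:
        r2 = mcfadden_r2(ll_model, ll_null)
    else:
        r2 = float("nan")
    return MetricReport(mcc=float(mcc), auc=auc, r2=float(r2),
                        tp=tp, fp=fp, tn=tn, fn=fn)


def _bernoulli_ll(y: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1.0 - eps)
    return float(np.sum(y * np.log(prob) + (1 - y) * np.log(1.0 - prob)))


def _evaluate_split(boundary: FittedBoundary, train: pd.DataFrame,
                    test: pd.DataFrame) -> MetricReport:
    y_test = test["chaotic"].to_numpy(int)
    probs = boundary.predict_proba(test)
    preds = (probs >= boundary.threshold).astype(int)
    # intercept-only reference fitted on the same training split
    p_null = float(train["chaotic"].mean())
    ll_model = _bernoulli_ll(y_test, probs)
    ll_null = _bernoulli_ll(y_test, np.full_like(probs, p_null))
    return score(preds, y_test, scores=probs,
                 ll_model=ll_model, ll_null=ll_null)


def nested_cv(
    records,
    class_id: int,
    kappa: str = "ke",
    master_seed: int = 0,
    n_outer: int = 4,
    n_inner: int = 4,
) -> list[MetricReport]:
    """Nested fourfold cross-validation of one model class.

    The data are split into ``n_outer`` folds (75/25 train/test); each
    outer training split is itself split into ``n_inner`` folds, and the
    model is fitted on every inner training part and scored on the
    corresponding held-out part — ``n_outer * n_inner`` (default 16)
    train/test pairs in total.
    """
    df = records_frame(records)
    counts = df["chaotic"].value_counts()
    if len(counts) < 2 or counts.min() < n_outer * n_inner:
        raise ValueError(
            f"need at least {n_outer * n_inner} records of each label")
    reports: list[MetricReport] = []
    outer = KFold(n_splits=n_outer, shuffle=True, random_state=master_seed)
    for o_idx, (outer_train, _outer_test) in enumerate(outer.split(df)):
        train_df = df.iloc[outer_train]
        inner = KFold(n_splits=n_inner, shuffle=True,
                      random_state=master_seed + 1 + o_idx)
        for inner_train, inner_test in inner.split(train_df):
            tr = train_df.iloc[inner_train]
            te = train_df.iloc[inner_test]
            boundary = fit_model(tr, class_id, kappa)
            reports.append(_evaluate_split(boundary, tr, te))
    return reports


@dataclass(frozen=True)
class TTestResult:
    """One-sided paired t-test outcome (H1: mean(b) > mean(a))."""

    statistic: float
    p_value: float
    df: int
    degenerate: bool = False

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.p_value


def paired_one_sided_t_test(scores_a, scores_b) -> TTestResult:
    """Paired t-test with alternative ``mean(scores_b) > mean(scores_a)``.

    Zero variance of the paired differences is degenerate: the p-value
    collapses to 0, 1 or 0.5 depending on the sign of the (constant)
    difference and the result is flagged.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score vectors of size >= 2")
    d = b - a
    n = d.size
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd <= 1e-12 * (abs(mean) + 1.0):
        if mean > 0:
            return TTestResult(math.inf, 0.0, n - 1, degenerate=True)
        if mean < 0:
            return TTestResult(-math.inf, 1.0, n - 1, degenerate=True)
        return TTestResult(0.0, 0.5, n - 1, degenerate=True)
    t_stat = mean / (sd / math.sqrt(n))
    p = float(stats.t.sf(t_stat, df=n - 1))
    return TTestResult(float(t_stat), p, n - 1)


def pareto_select(metrics, delta: float = 0.01) -> int:
    """Lowest-complexity model class within ``delta`` of the best score.

    ``metrics`` are mean scores ordered by model class (class 1 first).
    Returns the 1-based class id of the simplest class whose score is
    within ``delta`` of the maximum — the point after which extra
    complexity buys only marginal gains.
    """
    vals = np.asarray(list(metrics), float)
    if vals.size == 0:
        raise ValueError("no metrics given")
    best = float(np.nanmax(vals))
    for i, v in enumerate(vals):
        if v >= best - delta:
            return i + 1
    raise AssertionError("unreachable")  # pragma: no cover
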
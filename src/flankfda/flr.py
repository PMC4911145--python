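"""Logistic regression with scalar and functional (interval-mean) predictors.

A functional predictor enters the model through the discretized normalized
integral of a piecewise-constant coefficient function: one term per
sub-interval, whose regressor value is the curve's mean over that
sub-interval. Model quality is reported as deviance explained,
DE = (D_null - D_model) / D_null, and each final-model predictor's weight
as its relative contribution to the deviance explained,
RCDE = ((D_null - D_model) - (D_null - D_reduced)) / (D_null - D_model),
where D_reduced refits the model without the predictor.

The model-building sequence is: single fits per predictor, set-aside of
dominant predictors (DE above a threshold), LASSO subset selection among
scalar predictors, forward addition of functional predictors (largest DE
gain first, accepted while DE gains exceed a minimum and AIC decreases),
then backward removal of non-significant scalar predictors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .curves import CurveMatrix, ScalarFeatureTable
from .itp import IDL, LDL, Classification

logger = logging.getLogger(__name__)

SCALAR = "scalar"
FUNCTIONAL = "functional"


@dataclass
class PredictorSpec:
    """One model predictor, already evaluated per region.

    ``values`` is (n,) for a scalar predictor and (n, m) for a functional
    one (one column per support sub-interval, holding the curve's mean
    over that sub-interval). ``intervals`` gives the 1-based inclusive
    window range of each functional column.
    """

    name: str
    kind: str
    values: np.ndarray
    intervals: list[tuple[int, int]] | None = None
    log_shift: float | None = None  # shift s of an applied ln(x + s) transform

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == SCALAR:
            self.values = self.values.reshape(-1)
        elif self.kind == FUNCTIONAL:
            self.values = np.atleast_2d(self.values)
            if self.intervals is None or len(self.intervals) != self.values.shape[1]:
                raise ValueError(f"{self.name}: intervals must match value columns")
        else:
            raise ValueError(f"{self.name}: unknown predictor kind {self.kind!r}")

    @property
    def n_columns(self) -> int:
        return 1 if self.kind == SCALAR else self.values.shape[1]

    def column_names(self) -> list[str]:
        if self.kind == SCALAR:
            return [self.name]
        return [f"{self.name}[{lo},{hi}]" for lo, hi in self.intervals]

    def frame(self) -> pd.DataFrame:
        vals = self.values.reshape(len(self.values), -1)
        return pd.DataFrame(vals, columns=self.column_names())


# ---------------------------------------------------------------------------
# shifted-log regularization


def shifted_log(
    values: np.ndarray,
    labels: np.ndarray,
    skew_trigger: float = 1.0,
    grid_size: int = 200,
    force: bool = False,
) -> tuple[np.ndarray, float | None]:
    """ln(x + s), with s maximizing the worse of the two groups' normality.

    Applied only when either group's |sample skewness| exceeds the trigger
    (unless ``force``). The shift is searched on a logarithmic grid scaled
    by the data range and offset so that x + s > 0 everywhere. The score
    is min(Shapiro-Wilk p in group 1, in group 2). Degenerate (constant)
    data is returned unchanged with a warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    g1, g2 = values[labels == 1], values[labels == 0]
    rng_ = values.max() - values.min()
    if rng_ == 0:
        logger.warning("shifted-log skipped: constant predictor")
        return values, None
    if not force:
        sk = max(abs(stats.skew(g1)), abs(stats.skew(g2)))
        if sk <= skew_trigger:
            return values, None
    base = max(0.0, -float(values.min())) + 1e-12 * rng_
    grid = base + np.logspace(np.log10(1e-6 * rng_), np.log10(10 * rng_), grid_size)

    def score(s: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = stats.shapiro(_subsample(np.log(g1 + s))).pvalue
            p2 = stats.shapiro(_subsample(np.log(g2 + s))).pvalue
        return min(p1, p2)

    scores = np.array([score(s) for s in grid])
    best = float(grid[int(np.argmax(scores))])
    out = np.log(values + best)
    if not np.isfinite(out).all():
        raise ValueError("shifted-log produced non-finite values")
    return out, best


def _subsample(x: np.ndarray, cap: int = 4999) -> np.ndarray:
    # Shapiro-Wilk is unreliable beyond ~5000 observations
    if len(x) <= cap:
        return x
    idx = np.linspace(0, len(x) - 1, cap).astype(int)
    return np.sort(x)[idx]


# ---------------------------------------------------------------------------
# predictor construction


def interval_layout(n_windows: int, max_width: int) -> list[tuple[int, int]]:
    """Partition windows 1..K into contiguous ranges of width <= max_width."""
    if not 1 <= max_width <= n_windows:
        raise ValueError("max_width out of range")
    n_parts = -(-n_windows // max_width)  # ceil
    bounds = np.linspace(0, n_windows, n_parts + 1).round().astype(int)
    return [(int(lo) + 1, int(hi)) for lo, hi in zip(bounds[:-1], bounds[1:])]


def interval_means(values: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """(n, m) matrix of curve means over 1-based inclusive window ranges."""
    return np.column_stack(
        [values[:, lo - 1 : hi].mean(axis=1) for lo, hi in intervals]
    )


def build_predictors(
    classifications: dict[str, Classification | str],
    curves: dict[str, CurveMatrix],
    labels: np.ndarray,
    scalars: dict[str, ScalarFeatureTable] | None = None,
    scalar_pvalues: dict[str, float] | None = None,
    alpha: float = 0.05,
    layouts: dict[str, list[tuple[int, int]]] | None = None,
    skew_trigger: float = 1.0,
) -> list[PredictorSpec]:
    """Map feature classifications to model predictors.

    Invariant (IDL) features become scalar predictors (row means over the
    windows); localized (LDL) features become functional predictors whose
    sub-intervals partition the flank at the feature's significant scale
    (explicit per-feature layouts may override). Low-resolution scalar
    features enter as scalar predictors when their univariate test p-value
    is below alpha. Skewed predictors are shifted-log regularized.
    """
    labels = np.asarray(labels).astype(int).ravel()
    layouts = layouts or {}
    specs: list[PredictorSpec] = []
    for name in sorted(classifications):
        cls = classifications[name]
        label = cls if isinstance(cls, str) else cls.label
        if name not in curves:
            raise KeyError(f"classified feature {name!r} has no curve matrix")
        cm = curves[name]
        if label == IDL:
            z, s = shifted_log(cm.values.mean(axis=1), labels, skew_trigger)
            specs.append(PredictorSpec(name=name, kind=SCALAR, values=z, log_shift=s))
        elif label == LDL:
            if name in layouts:
                ivs = layouts[name]
            else:
                scale = cls.scale if isinstance(cls, Classification) else None
                width = scale or cm.n_windows
                ivs = interval_layout(cm.n_windows, max(1, min(width, cm.n_windows)))
            vals = interval_means(cm.values, ivs)
            cols = []
            shift = None
            for j in range(vals.shape[1]):
                col, shift_j = shifted_log(vals[:, j], labels, skew_trigger)
                cols.append(col)
                shift = shift_j if shift_j is not None else shift
            specs.append(
                PredictorSpec(
                    name=name,
                    kind=FUNCTIONAL,
                    values=np.column_stack(cols),
                    intervals=ivs,
                    log_shift=shift,
                )
            )
    for name in sorted(scalars or {}):
        p = (scalar_pvalues or {}).get(name)
        if p is not None and not p < alpha:
            continue
        z, s = shifted_log(scalars[name].values, labels, skew_trigger)
        specs.append(PredictorSpec(name=name, kind=SCALAR, values=z, log_shift=s))
    return specs


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FLRFit:
    predictors: list[PredictorSpec]
    params: pd.Series = field(repr=False)
    pvalues: pd.Series = field(repr=False)
    d_null: float = np.nan
    d_model: float = np.nan
    aic: float = np.nan
    separated: bool = False
    rcde: dict[str, float] = field(default_factory=dict)

    @property
    def de(self) -> float:
        if self.d_null == 0:
            return 0.0
        return (self.d_null - self.d_model) / self.d_null

    def predictor_names(self) -> list[str]:
        return [p.name for p in self.predictors]

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"term": "const", "predictor": "const", "interval": "",
                 "coefficient": self.params.get("const", np.nan),
                 "p_value": self.pvalues.get("const", np.nan),
                 "rcde": np.nan}]
        for p in self.predictors:
            ivs = p.intervals if p.kind == FUNCTIONAL else [None]
            for col, iv in zip(p.column_names(), ivs):
                rows.append({
                    "term": col,
                    "predictor": p.name,
                    "interval": "" if iv is None else f"{iv[0]}-{iv[1]}",
                    "coefficient": self.params.get(col, np.nan),
                    "p_value": self.pvalues.get(col, np.nan),
                    "rcde": self.rcde.get(p.name, np.nan),
                })
        df = pd.DataFrame(rows)
        df["de_total"] = self.de
        return df


def _design(predictors: list[PredictorSpec]) -> pd.DataFrame:
    if not predictors:
        return pd.DataFrame()
    return pd.concat([p.frame() for p in predictors], axis=1)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, pd.Series, float, float, float, bool]:
    """Fit a logistic model; returns (params, pvalues, d_null, d_model, aic, separated).

    On perfect separation (or non-convergence) a weakly ridge-penalized fit
    supplies coefficients and deviances, with NaN p-values and a flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xc = sm.add_constant(X, has_constant="add") if len(X.columns) else pd.DataFrame(
        {"const": np.ones(len(y))}
    )
    d_null = _null_deviance(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logit did not converge")
        return (
            res.params, res.pvalues, d_null, float(-2 * res.llf), float(res.aic), False
        )
    except Exception as exc:  # separation / convergence failure
        logger.warning("logit fallback to ridge-penalized fit: %s", exc)
        if len(X.columns):
            clf = LogisticRegression(C=1e4, max_iter=5000)
            clf.fit(X.to_numpy(), y)
            eta = clf.decision_function(X.to_numpy())
            params = pd.Series(
                np.concatenate([[clf.intercept_[0]], clf.coef_[0]]), index=Xc.columns
            )
        else:
            p1 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            eta = np.full(len(y), np.log(p1 / (1 - p1)))
            params = pd.Series([np.log(p1 / (1 - p1))], index=["const"])
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        d_model = float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        aic = d_model + 2 * len(Xc.columns)
        pvals = pd.Series(np.nan, index=Xc.columns)
        return params, pvals, d_null, d_model, aic, True


def _null_deviance(y: np.ndarray) -> float:
    p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_model(predictors: list[PredictorSpec], y: np.ndarray) -> FLRFit:
    """Maximum-likelihood logistic fit of an arbitrary predictor set."""
    params, pvalues, d_null, d_model, aic, separated = _fit_logit(y, _design(predictors))
    return FLRFit(
        predictors=list(predictors),
        params=params,
        pvalues=pvalues,
        d_null=d_null,
        d_model=d_model,
        aic=aic,
        separated=separated,
    )


def fit_single(predictor: PredictorSpec, y: np.ndarray) -> FLRFit:
    """Single-predictor fit, reporting its individual deviance explained."""
    return fit_model([predictor], y)


def screen_dominant(
    fits: dict[str, FLRFit], threshold: float = 0.20
) -> tuple[list[str], list[str]]:
    """Partition predictors into dominant (DE strictly above threshold) and rest."""
    dominant = sorted(n for n, f in fits.items() if f.de > threshold)
    retained = sorted(n for n in fits if n not in dominant)
    return dominant, retained


def select_scalars_lasso(
    predictors: list[PredictorSpec],
    y: np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
) -> list[str]:
    """L1-penalized subset selection among standardized scalar predictors.

    The penalty is chosen by cross-validated misclassification rate
    (minimized); the subset is the set of predictors with nonzero
    coefficients at the chosen penalty.
    """
    scalars = [p for p in predictors if p.kind == SCALAR]
    if not scalars:
        return []
    X = np.column_stack([p.values for p in scalars])
    X = StandardScaler().fit_transform(X)
    y = np.asarray(y).astype(int).ravel()
    Cs = np.logspace(-4, 2, n_lambdas)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    # integer misclassification counts so that exact ties are exact; ties
    # broken toward the strongest penalty (the first minimum on a
    # decreasing-lambda path, as in glmnet)
    errors = np.zeros(n_lambdas, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn penalty-kwarg deprecation
        for train, test in cv.split(X, y):
            for j, C in enumerate(Cs):
                clf = LogisticRegression(
                    C=C, penalty="l1", solver="liblinear", max_iter=2000
                )
                clf.fit(X[train], y[train])
                errors[j] += int((clf.predict(X[test]) != y[test]).sum())
        best_c = Cs[np.flatnonzero(errors == errors.min())[0]]
        clf = LogisticRegression(
            C=best_c, penalty="l1", solver="liblinear", max_iter=2000
        )
        clf.fit(X, y)
    selected = [p.name for p, c in zip(scalars, clf.coef_[0]) if c != 0.0]
    if not selected:
        logger.warning("LASSO selected no scalar predictors; continuing from intercept")
    return selected


def stepwise_multiple_flr(
    scalar_predictors: list[PredictorSpec],
    functional_candidates: list[PredictorSpec],
    y: np.ndarray,
    min_de_gain: float = 0.01,
    p_remove: float = 0.05,
) -> tuple[FLRFit, pd.DataFrame]:
    """Forward-add functional predictors, then backward-prune scalars.

    Forward: at each step fit every remaining functional candidate on top
    of the current model and add the one with the largest DE gain, provided
    the gain exceeds ``min_de_gain`` and the AIC decreases; stop otherwise.
    Backward: repeatedly drop the scalar predictor with the largest
    coefficient p-value >= ``p_remove``, refitting after each removal.
    Returns the final fit (with RCDE filled in) and a step log.
    """
    current = list(scalar_predictors)
    fit = fit_model(current, y)
    log_rows = [{"step": "initial", "predictor": "", "de": fit.de, "aic": fit.aic}]

    remaining = list(functional_candidates)
    while remaining:
        trials = []
        for cand in remaining:
            try:
                trial = fit_model(current + [cand], y)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("skipping %s: %s", cand.name, exc)
                continue
            trials.append((trial.de - fit.de, cand, trial))
        if not trials:
            break
        gain, best, best_fit = max(trials, key=lambda t: (t[0], t[1].name))
        if gain > min_de_gain and best_fit.aic < fit.aic:
            current.append(best)
            fit = best_fit
            remaining = [c for c in remaining if c.name != best.name]
            log_rows.append(
                {"step": "forward_add", "predictor": best.name, "de": fit.de, "aic": fit.aic}
            )
        else:
            break

    while True:
        removable = [
            (float(fit.pvalues.get(p.name, np.nan)), p)
            for p in fit.predictors
            if p.kind == SCALAR
        ]
        removable = [(pv, p) for pv, p in removable if np.isfinite(pv) and pv >= p_remove]
        if not removable:
            break
        _, worst = max(removable, key=lambda t: (t[0], t[1].name))
        current = [p for p in fit.predictors if p.name != worst.name]
        fit = fit_model(current, y)
        log_rows.append(
            {"step": "backward_drop", "predictor": worst.name, "de": fit.de, "aic": fit.aic}
        )

    fit.rcde = compute_rcde(fit, y)
    return fit, pd.DataFrame(log_rows, columns=["step", "predictor", "de", "aic"])


def compute_rcde(fit: FLRFit, y: np.ndarray) -> dict[str, float]:
    """Per-predictor relative contribution to the deviance explained.

    Each predictor is removed in turn and the model refit;
    RCDE = (D_reduced - D_model) / (D_null - D_model). Zero when removing
    the predictor changes nothing; undefined (NaN) for a null model.
    """
    explained = fit.d_null - fit.d_model
    out: dict[str, float] = {}
    for p in fit.predictors:
        reduced = fit_model([q for q in fit.predictors if q.name != p.name], y)
        if explained == 0:
            out[p.name] = np.nan
        else:
            out[p.name] = (reduced.d_model - fit.d_model) / explained
    return out
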
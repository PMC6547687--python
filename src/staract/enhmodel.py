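"""Cross-validated lasso model of enhancer activity from region features.

Features mix sequence-derived scores with experimentally measured signal
(ChIP-seq, CAGE, ...).  Right-skewed signal features are log(x+1)
transformed, then every feature is z-scored so coefficient magnitudes are
comparable.  An L1-penalized linear model is fit with the penalty
strength chosen by 10-fold cross-validation (minimum mean squared error
by default); model quality is summarized as the Spearman correlation of
out-of-fold predictions with observed activity, and the fitted model is
reported through its largest-magnitude coefficients.

Lambda tuning is nested inside each training fold by default, so the
out-of-fold predictions never see the held-out rows, not even through the
choice of penalty; a cheaper non-nested mode (single lambda tuned on the
full data) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold


class ModelError(ValueError):
    """Unusable model inputs (non-finite features, degenerate response...)."""


SKEW_THRESHOLD = 1.0


@dataclass
class PreprocessInfo:
    skew_flags: pd.Series
    dropped: list[str] = field(default_factory=list)


def preprocess(
    X: pd.DataFrame,
    skew_flags: pd.Series | None = None,
    skew_threshold: float = SKEW_THRESHOLD,
) -> tuple[pd.DataFrame, PreprocessInfo]:
    """log1p skewed features, z-score everything, drop constants.

    ``skew_flags`` marks which features carry right-skewed signal; when
    omitted, features with sample skewness above ``skew_threshold`` are
    auto-flagged.  Flagged features get ``log(x + 1)`` (values must exceed
    -1), then every feature is centered and scaled to unit sd; zero-sd
    features are dropped and recorded.
    """
    bad = X.columns[~np.isfinite(X.to_numpy()).all(axis=0)]
    if len(bad):
        raise ModelError(f"non-finite values in feature(s): {list(bad[:5])}")
    if skew_flags is None:
        vals = X.to_numpy()
        nonconst = vals.std(axis=0) > 0
        sk = np.zeros(vals.shape[1])
        if nonconst.any():
            sk[nonconst] = stats.skew(vals[:, nonconst], axis=0)
        skew_flags = pd.Series(sk > skew_threshold, index=X.columns)
    else:
        skew_flags = skew_flags.reindex(X.columns).fillna(False).astype(bool)

    out = X.copy().astype(float)
    for name in X.columns[skew_flags.to_numpy()]:
        if (out[name] <= -1).any():
            raise ModelError(
                f"feature {name!r} flagged as skewed has values <= -1; cannot log1p"
            )
        out[name] = np.log1p(out[name])

    sd = out.std(axis=0, ddof=0)
    dropped = list(out.columns[sd == 0])
    out = out.drop(columns=dropped)
    sd = sd.drop(index=dropped)
    out = (out - out.mean(axis=0)) / sd
    return out, PreprocessInfo(skew_flags=skew_flags, dropped=dropped)


@dataclass
class LassoModel:
    """A fitted, cross-validated lasso enhancer-activity model."""

    lambda_: float
    lambda_grid: np.ndarray
    coefficients: pd.Series
    intercept: float
    oof_predictions: pd.Series
    fold_ids: pd.Series
    rho: float
    n_folds: int
    nested: bool
    selection: str

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients != 0).sum())


def _select_lambda(cv_model: LassoCV, selection: str) -> float:
    if selection == "min":
        return float(cv_model.alpha_)
    if selection == "1se":
        mse = cv_model.mse_path_.mean(axis=1)
        se = cv_model.mse_path_.std(axis=1, ddof=1) / np.sqrt(
            cv_model.mse_path_.shape[1]
        )
        i_min = int(np.argmin(mse))
        limit = mse[i_min] + se[i_min]
        # alphas_ are descending; take the largest alpha within one SE
        ok = np.where(mse <= limit)[0]
        return float(cv_model.alphas_[ok.min()])
    raise ModelError(f"unknown lambda selection rule {selection!r}")


def fit_cv(
    X: pd.DataFrame,
    y: pd.Series,
    n_folds: int = 10,
    seed: int = 0,
    nested: bool = True,
    n_lambdas: int = 100,
    lambda_grid=None,
    selection: str = "min",
) -> LassoModel:
    """Fit the lasso with K-fold CV and out-of-fold evaluation.

    Every row receives exactly one out-of-fold prediction from a model
    trained without it.  The final model is refit on all rows at the
    lambda minimizing mean CV squared error over a log-spaced grid of
    ``n_lambdas`` values (or an explicit ``lambda_grid``, or the 1-SE
    lambda when ``selection='1se'``).
    """
    if len(X) != len(y):
        raise ModelError("X and y must align row-wise")
    if len(X) < n_folds:
        raise ModelError(f"need at least n_folds={n_folds} rows, got {len(X)}")
    yv = np.asarray(y, dtype=float)
    if np.std(yv) == 0:
        raise ModelError("response has zero variance")
    Xv = X.to_numpy(dtype=float)
    alphas = n_lambdas if lambda_grid is None else np.sort(np.asarray(lambda_grid))[::-1]

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1, dtype=int)
    for k, (train, test) in enumerate(outer.split(Xv)):
        if nested:
            inner = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
            cv_k = LassoCV(
                alphas=alphas, cv=inner, random_state=seed, max_iter=50_000, tol=1e-8
            ).fit(Xv[train], yv[train])
            alpha_k = _select_lambda(cv_k, selection)
            fold_model = Lasso(alpha=alpha_k, max_iter=50_000, tol=1e-8).fit(
                Xv[train], yv[train]
            )
        else:
            fold_model = None  # filled after global lambda is known
        if fold_model is not None:
            oof[test] = fold_model.predict(Xv[test])
        fold_ids[test] = k

    # Global lambda + final refit on the full data.
    full_cv = LassoCV(
        alphas=alphas,
        cv=KFold(n_splits=n_folds, shuffle=True, random_state=seed),
        random_state=seed,
        max_iter=50_000, tol=1e-8,
    ).fit(Xv, yv)
    lambda_ = _select_lambda(full_cv, selection)
    final = Lasso(alpha=lambda_, max_iter=50_000, tol=1e-8).fit(Xv, yv)

    if not nested:
        for train, test in KFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        ).split(Xv):
            m = Lasso(alpha=lambda_, max_iter=50_000, tol=1e-8).fit(Xv[train], yv[train])
            oof[test] = m.predict(Xv[test])

    rho = evaluate(oof, yv)
    return LassoModel(
        lambda_=float(lambda_),
        lambda_grid=np.asarray(full_cv.alphas_),
        coefficients=pd.Series(final.coef_, index=X.columns, name="coefficient"),
        intercept=float(final.intercept_),
        oof_predictions=pd.Series(oof, index=X.index, name="oof_prediction"),
        fold_ids=pd.Series(fold_ids, index=X.index, name="fold"),
        rho=float(rho),
        n_folds=n_folds,
        nested=nested,
        selection=selection,
    )


def evaluate(predictions, observed) -> float:
    """Spearman rank correlation (mid-rank ties) of predictions vs. truth."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ModelError("prediction and observation vectors must align")
    return float(stats.spearmanr(p, o)[0])


def top_coefficients(model: LassoModel, k: int = 30) -> pd.DataFrame:
    """The k nonzero coefficients of greatest magnitude, signs retained.

    Ties in magnitude are broken by feature name; when fewer than k
    coefficients are nonzero, all of them are returned.
    """
    coefs = model.coefficients[model.coefficients != 0]
    order = (
        pd.DataFrame({"feature": coefs.index, "coefficient": coefs.to_numpy()})
        .assign(magnitude=lambda d: d["coefficient"].abs())
        .sort_values(["magnitude", "feature"], ascending=[False, True], kind="mergesort")
        .drop(columns="magnitude")
        .reset_index(drop=True)
    )
    return order.head(k)
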
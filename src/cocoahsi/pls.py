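"""PLS1 calibration by NIPALS with bean-grouped validation.

The calibration chain a chemometrician runs in a package like
Unscrambler, made explicit and seedable:

* a 70:30 holdout split drawn over *beans*, so the two sides of a bean
  can never straddle the calibration/validation boundary;
* NIPALS PLS1 with mean-centring (no autoscaling — conventional for
  spectra, where the units are already commensurate);
* bean-grouped random k-fold cross-validation to pick the latent
  variable count by a parsimony rule on RMSECV;
* the standard metric suite: R2, RMSE, RPD = sd(reference)/RMSE, bias,
  and a paired t-test of predictions against reference values.

NIPALS per component: w = X'y/||X'y||, t = Xw, p = X't/(t't),
q = y't/(t't), then deflate X <- X - t p' and y <- y - t q.  The
regression vector is beta = W (P'W)^-1 q with centring absorbed into
the intercept, and prediction via beta is identical to prediction via
the score recursion (asserted in tests at 1e-8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import RankError
from .preprocessing import PreprocessSpec
from .spectra import SpectraTable
from .synthetic import as_is_to_dmb  # noqa: F401  (re-exported: same conversion)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray                  # p x n_lv weights
    P: np.ndarray                  # p x n_lv x-loadings
    q: np.ndarray                  # n_lv y-loadings
    beta: np.ndarray               # p regression vector (centred space)
    intercept: float
    x_sd: np.ndarray               # sd of pre-treated calibration columns
    wavelengths: np.ndarray
    preprocess: PreprocessSpec = field(default_factory=lambda: PreprocessSpec([]))
    basis: str = "as_is"

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict from already pre-treated spectra."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.beta + self.intercept

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Prediction via the score recursion (deflation replayed per sample)."""
        X = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        yhat = np.full(X.shape[0], self.y_mean)
        for a in range(self.n_lv):
            t = X @ self.W[:, a]
            yhat += t * self.q[a]
            X = X - np.outer(t, self.P[:, a])
        return yhat

    def predict_reflectance(self, R: np.ndarray) -> np.ndarray:
        """Apply the stored pre-treatment chain to reflectance spectra, then predict."""
        return self.predict(self.preprocess.transform(R))

    def to_yaml(self, path) -> None:
        d = {
            "n_lv": int(self.n_lv), "y_mean": float(self.y_mean),
            "intercept": float(self.intercept), "basis": self.basis,
            "x_mean": [float(v) for v in self.x_mean],
            "x_sd": [float(v) for v in self.x_sd],
            "beta": [float(v) for v in self.beta],
            "q": [float(v) for v in self.q],
            "W": self.W.tolist(), "P": self.P.tolist(),
            "wavelengths": [float(v) for v in self.wavelengths],
            "preprocess": self.preprocess.to_dict(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PLSModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(n_lv=d["n_lv"], x_mean=np.asarray(d["x_mean"]),
                   y_mean=d["y_mean"], W=np.asarray(d["W"]), P=np.asarray(d["P"]),
                   q=np.asarray(d["q"]), beta=np.asarray(d["beta"]),
                   intercept=d["intercept"], x_sd=np.asarray(d["x_sd"]),
                   wavelengths=np.asarray(d["wavelengths"]),
                   preprocess=PreprocessSpec.from_dict(d["preprocess"]),
                   basis=d["basis"])


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            wavelengths=None, preprocess=None, basis: str = "as_is",
            strict: bool = True) -> PLSModel:
    """Fit PLS1 by NIPALS on (already pre-treated) spectra.

    With ``strict=False``, exhausting the signal before ``n_lv``
    components returns the truncated model instead of raising
    :class:`RankError` (low-rank data, e.g. noise-free simulations).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv={n_lv} outside [1, min(n-1, p)={min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    x_sd = Xc.std(axis=0, ddof=1)
    yc = y - y_mean
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        exhausted = norm < 1e-12 * max(1.0, np.abs(yd).max(initial=0.0)) or norm == 0.0
        if not exhausted:
            w /= norm
            t = Xd @ w
            tt = t @ t
            exhausted = tt == 0
        if exhausted:
            if strict or a == 0:
                raise RankError(
                    f"signal exhausted after {a} of {n_lv} components", n_extracted=a)
            n_lv = a
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = yd @ t / tt
        W[:, a] = w
        Xd -= np.outer(t, P[:, a])
        yd -= t * q[a]
    beta = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - x_mean @ beta
    return PLSModel(n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q,
                    beta=beta, intercept=float(intercept), x_sd=x_sd,
                    wavelengths=np.asarray(wavelengths if wavelengths is not None
                                           else np.arange(p), dtype=float),
                    preprocess=preprocess or PreprocessSpec([]), basis=basis)


# --------------------------------------------------------------------------
# splitting and cross-validation
# --------------------------------------------------------------------------

def split_holdout(table: SpectraTable, ratio: float = 0.7, seed: int = 0):
    """Bean-grouped holdout split; returns (calibration rows, validation rows).

    ``round(ratio * n_beans)`` beans (round-half-up) go to calibration
    and every row of a bean travels with it.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    beans = np.unique(table.bean_ids)
    if beans.size < 2:
        raise ValueError("need at least 2 beans to split")
    n_cal = int(math.floor(ratio * beans.size + 0.5))
    n_cal = min(max(n_cal, 1), beans.size - 1)
    rng = np.random.default_rng(seed)
    cal_beans = set(rng.choice(beans, size=n_cal, replace=False).tolist())
    in_cal = np.array([b in cal_beans for b in table.bean_ids])
    return np.nonzero(in_cal)[0], np.nonzero(~in_cal)[0]


def group_kfold(bean_ids: np.ndarray, folds: int, seed: int = 0):
    """Random bean-grouped fold assignment; yields (train rows, test rows)."""
    beans = np.unique(bean_ids)
    if folds < 2 or folds > beans.size:
        raise ValueError(f"folds must lie in [2, n_beans={beans.size}]")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(beans)
    fold_of_bean = {b: i % folds for i, b in enumerate(shuffled)}
    fold_of_row = np.array([fold_of_bean[b] for b in bean_ids])
    for f in range(folds):
        yield np.nonzero(fold_of_row != f)[0], np.nonzero(fold_of_row == f)[0]


def cross_validate(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   max_lv: int, folds: int = 10, seed: int = 0,
                   preprocess_factory=None):
    """Grouped k-fold CV; returns (rmsecv, r2cv) arrays indexed by LV-1.

    Out-of-fold predictions are pooled across folds before computing the
    error, so every row contributes exactly once per LV.  If
    ``preprocess_factory`` is given (a zero-argument callable returning a
    fresh :class:`PreprocessSpec`), the chain is re-fitted inside every
    fold on the training rows only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    splits = list(group_kfold(groups, folds, seed))
    smallest = min(tr.size for tr, _ in splits)
    if max_lv > min(smallest - 1, X.shape[1]):
        raise ValueError(
            f"max_lv={max_lv} too large for smallest training fold ({smallest} rows)")
    pooled = np.empty((max_lv, y.size))
    for train, test in splits:
        if preprocess_factory is None:
            Xtr, Xte = X[train], X[test]
        else:
            spec = preprocess_factory()
            Xtr = spec.fit_transform(X[train])
            Xte = spec.transform(X[test])
        model = fit_pls(Xtr, y[train], max_lv, strict=False)
        # evaluate every truncation of the same NIPALS sequence; if the
        # signal ran out early, deeper LVs keep the deepest prediction
        Xc = Xte - model.x_mean
        yhat = np.full(test.size, model.y_mean)
        for a in range(max_lv):
            if a < model.n_lv:
                t = Xc @ model.W[:, a]
                yhat = yhat + t * model.q[a]
                Xc = Xc - np.outer(t, model.P[:, a])
            pooled[a, test] = yhat
    sst = np.sum((y - y.mean()) ** 2)
    rmsecv = np.sqrt(np.mean((pooled - y) ** 2, axis=1))
    r2cv = 1.0 - np.sum((pooled - y) ** 2, axis=1) / sst
    return rmsecv, r2cv


def select_lv(rmsecv_curve, parsimony: float = 0.02) -> int:
    """Smallest LV with RMSECV within (1+parsimony) of the curve minimum."""
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    threshold = (1.0 + parsimony) * curve.min()
    return int(np.nonzero(curve <= threshold)[0][0]) + 1


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def evaluate(y_true, y_pred, label: str = "") -> dict:
    """R2 (1 - SSE/SST), RMSE, RPD = sd(y)/RMSE (n-1 sd), and bias."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err ** 2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    sse = float(np.sum(err ** 2))
    sd = float(np.std(y_true, ddof=1))
    return {
        "label": label,
        "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
        "rmse": rmse,
        "rpd": sd / rmse if rmse > 0 else float("inf"),
        "bias": float(err.mean()),
        "n": int(y_true.size),
    }


def paired_ttest(y_true, y_pred, alpha: float = 0.05) -> dict:
    """Paired t-test of prediction minus reference; 95% CI half-width."""
    from .errors import DegenerateInputError
    d = np.asarray(y_pred, dtype=float).ravel() - np.asarray(y_true, dtype=float).ravel()
    if d.size < 3:
        raise ValueError("need n >= 3 for a paired t-test")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("all prediction-reference differences identical")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return {"t": float(t), "p": float(p), "ci_half_width": float(half), "n": n}


# --------------------------------------------------------------------------
# full calibration workflow
# --------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    """One comparison-table row: calibration / CV / prediction metrics."""

    pretreatment: str
    basis: str
    n_lv: int
    r2_c: float
    rmsec: float
    r2_cv: float
    rmsecv: float
    r2_p: float
    rmsep: float
    rpd_cv: float
    rpd_p: float
    n_cal: int
    n_val: int
    ttest_p: float
    ci_half_width: float

    def as_row(self) -> dict:
        return {
            "Pre-treatment": self.pretreatment, "Basis": self.basis,
            "LV": self.n_lv, "R2_c": self.r2_c, "RMSEC": self.rmsec,
            "R2_cv": self.r2_cv, "RMSECV": self.rmsecv,
            "R2_p": self.r2_p, "RMSEP": self.rmsep,
            "RPD_CV": self.rpd_cv, "RPD_P": self.rpd_p,
            "n_cal": self.n_cal, "n_val": self.n_val,
            "ttest_p": self.ttest_p, "CI_half_width": self.ci_half_width,
        }


def run_calibration(table: SpectraTable, pretreatment: str = "snv",
                    basis: str = "as_is", ratio: float = 0.7, folds: int = 10,
                    max_lv: int = 15, parsimony: float = 0.02,
                    seed: int = 0, n_lv: int | None = None):
    """Split, pre-treat, cross-validate, select LV, fit, validate.

    Returns ``(model, report, extras)`` where ``extras`` carries the
    split indices, the RMSECV curve and validation predictions.
    """
    cal_idx, val_idx = split_holdout(table, ratio, seed)
    y = table.y(basis)
    R_cal, R_val = table.X[cal_idx], table.X[val_idx]
    y_cal, y_val = y[cal_idx], y[val_idx]
    groups = table.bean_ids[cal_idx]

    max_lv = min(max_lv, len(cal_idx) - 1, table.X.shape[1])
    factory = lambda: PreprocessSpec.from_name(pretreatment)  # noqa: E731
    rmsecv_curve, r2cv_curve = cross_validate(
        R_cal, y_cal, groups, max_lv, folds=folds, seed=seed,
        preprocess_factory=factory)
    chosen = n_lv if n_lv is not None else select_lv(rmsecv_curve, parsimony)

    spec = PreprocessSpec.from_name(pretreatment)
    X_cal = spec.fit_transform(R_cal)
    model = fit_pls(X_cal, y_cal, chosen, wavelengths=table.wavelengths,
                    preprocess=spec, basis=basis, strict=False)
    chosen = model.n_lv
    cal_metrics = evaluate(y_cal, model.predict(X_cal), "calibration")
    val_pred = model.predict_reflectance(R_val)
    val_metrics = evaluate(y_val, val_pred, "prediction")
    tt = paired_ttest(y_val, val_pred)
    report = CalibrationReport(
        pretreatment=pretreatment, basis=basis, n_lv=chosen,
        r2_c=cal_metrics["r2"], rmsec=cal_metrics["rmse"],
        r2_cv=float(r2cv_curve[chosen - 1]), rmsecv=float(rmsecv_curve[chosen - 1]),
        r2_p=val_metrics["r2"], rmsep=val_metrics["rmse"],
        rpd_cv=float(np.std(y_cal, ddof=1) / rmsecv_curve[chosen - 1]),
        rpd_p=val_metrics["rpd"], n_cal=len(cal_idx), n_val=len(val_idx),
        ttest_p=tt["p"], ci_half_width=tt["ci_half_width"])
    extras = {"cal_idx": cal_idx, "val_idx": val_idx,
              "rmsecv_curve": rmsecv_curve, "r2cv_curve": r2cv_curve,
              "val_pred": val_pred, "y_val": y_val}
    return model, report, extras


def reports_to_frame(reports: list) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])
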
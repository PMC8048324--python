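"""Two-class OPLS-DA with cross-validation, permutation testing and cv-ANOVA.

Orthogonal projections to latent structures discriminant analysis splits the
predictor variation into one *predictive* component (correlated with class
membership) and ``n_orth`` *orthogonal* components (systematic variation
uncorrelated with class).  The fit is a NIPALS-style sequence: each
orthogonal component is extracted from the loading of a provisional
predictive component by removing its class-correlated part, the data are
deflated, and a final predictive component is computed on the filtered
matrix.  With a single binary response the NIPALS inner loop converges in
one pass, so the fit is fully deterministic.

Diagnostics follow chemometrics conventions:

* ``R2X``    - fraction of (centered) X variation captured by the
  predictive component; ``R2X(o)`` per orthogonal component.
* ``R2Y``    - fraction of class-membership variation modelled.
* ``Q2``     - cross-validated predictive ability, 1 - PRESS/SS.
* ``p(corr)``- Pearson correlation of each (centered) variable with the
  predictive score t[1]; the basis of s-line/S-plot colouring.

Model significance is assessed by label permutation (empirical p-values for
R2Y and Q2) and by ANOVA of the cross-validated residuals (CV-ANOVA, an
F-test of PRESS against the total corrected variation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 1000


class DegenerateWeightsError(ValueError):
    """X carries no covariance with the response (X'y = 0)."""


@dataclass
class OplsdaModel:
    """A fitted two-class OPLS-DA model.

    Class coding is 0/1 over the sorted unique labels with a 0.5 decision
    threshold on the predicted response.
    """

    classes: tuple  # (label coded 0, label coded 1)
    x_mean: np.ndarray
    y_mean: float
    w_pred: np.ndarray  # predictive weights, unit norm
    p_pred: np.ndarray  # predictive loadings
    c_pred: float  # inner y-loading
    t_pred: np.ndarray  # training predictive scores t[1]
    w_orth: np.ndarray  # p x n_orth orthogonal weights
    p_orth: np.ndarray  # p x n_orth orthogonal loadings
    t_orth: np.ndarray  # n x n_orth orthogonal scores
    r2x: float
    r2x_orth: np.ndarray  # per orthogonal component
    r2y: float
    p_corr: np.ndarray
    q2: float | None = None
    p_corr_flags: np.ndarray | None = field(default=None, compare=False)

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[1]

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": list(self.classes),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "w_pred": self.w_pred.tolist(),
            "p_pred": self.p_pred.tolist(),
            "c_pred": self.c_pred,
            "t_pred": self.t_pred.tolist(),
            "w_orth": self.w_orth.tolist(),
            "p_orth": self.p_orth.tolist(),
            "t_orth": self.t_orth.tolist(),
            "r2x": self.r2x,
            "r2x_orth": self.r2x_orth.tolist(),
            "r2y": self.r2y,
            "p_corr": self.p_corr.tolist(),
            "q2": self.q2,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OplsdaModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            x_mean=np.asarray(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            w_pred=np.asarray(d["w_pred"]),
            p_pred=np.asarray(d["p_pred"]),
            c_pred=float(d["c_pred"]),
            t_pred=np.asarray(d["t_pred"]),
            w_orth=np.asarray(d["w_orth"]),
            p_orth=np.asarray(d["p_orth"]),
            t_orth=np.asarray(d["t_orth"]),
            r2x=float(d["r2x"]),
            r2x_orth=np.asarray(d["r2x_orth"]),
            r2y=float(d["r2y"]),
            p_corr=np.asarray(d["p_corr"]),
            q2=d.get("q2"),
        )


@dataclass
class ValidationReport:
    """Validation artefacts for a fitted model."""

    q2: float
    y_cv: np.ndarray  # cross-validated predicted responses (0/1 scale)
    r2y_perm: np.ndarray | None = None
    q2_perm: np.ndarray | None = None
    p_r2y: float | None = None
    p_q2: float | None = None
    cv_anova_f: float | None = None
    cv_anova_p: float | None = None
    misclassification: pd.DataFrame | None = None


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    return (y == classes[1]).astype(float), classes


def _nipals_component(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One PLS component by NIPALS; returns (w, t) with unit-norm w.

    With a single y column the loop converges immediately; the iteration is
    kept for the general contract (relative change < 1e-10, <= 1000 iters).
    """
    u = y.copy()
    w_old = None
    for _ in range(_NIPALS_MAX_ITER):
        w = X.T @ u / (u @ u)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise DegenerateWeightsError("degenerate weight vector (X'y = 0)")
        w /= norm
        t = X @ w
        if w_old is not None and np.linalg.norm(w - w_old) < _NIPALS_TOL:
            break
        w_old = w
        # single-column y: u update is a rescaling, loop exits next pass
        c = (y @ t) / (t @ t)
        u = y * np.sign(c) if c != 0 else y
    return w, t


def fit_oplsda(X: np.ndarray, y, n_orth: int = 2) -> OplsdaModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    X
        Samples x variables matrix.  Pareto scaling (or any scaling) is the
        caller's responsibility; the fit centers columns internally and
        remembers the offsets for prediction.
    y
        Binary labels (any two values; coded 0/1 over sorted uniques).
    n_orth
        Number of orthogonal components (>= 0); must be small relative to
        the matrix rank.

    Deterministic: the weight vector is initialised from the y-covariance,
    no random initialisation is involved.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if p == 0:
        raise ValueError("X has no variables (empty matrix)")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    max_rank = min(n - 1, p)
    if n_orth >= max_rank:
        raise ValueError(f"n_orth={n_orth} too large for an {n}x{p} matrix")
    y01, classes = _encode_labels(y)
    if len(y01) != n:
        raise ValueError("X and y length mismatch")

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    ssx = float((Xc ** 2).sum())
    ssy = float((yc ** 2).sum())
    if ssy == 0:
        raise ValueError("response has no variation")

    Xd = Xc.copy()
    w_orth_list, p_orth_list, t_orth_list, r2xo = [], [], [], []
    for _ in range(n_orth):
        w, t = _nipals_component(Xd, yc)
        p_load = Xd.T @ t / (t @ t)
        wo = p_load - (w @ p_load) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12 * np.linalg.norm(p_load):
            break  # no orthogonal variation left
        wo /= norm
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        Xd = Xd - np.outer(to, po)
        w_orth_list.append(wo)
        p_orth_list.append(po)
        t_orth_list.append(to)
        r2xo.append(float((to @ to) * (po @ po) / ssx))

    w, t = _nipals_component(Xd, yc)
    p_load = Xd.T @ t / (t @ t)
    c = float((yc @ t) / (t @ t))
    r2x = float((t @ t) * (p_load @ p_load) / ssx)
    resid = yc - t * c
    r2y = float(1.0 - (resid @ resid) / ssy)

    # p(corr) against the original centered variables
    sd_t = t.std()
    sd_x = Xc.std(axis=0)
    flags = sd_x == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr = (Xc.T @ (t - t.mean())) / (len(t) * np.where(flags, 1.0, sd_x) * sd_t)
    pcorr = np.where(flags, 0.0, pcorr)
    pcorr = np.clip(pcorr, -1.0, 1.0)

    k = len(w_orth_list)
    return OplsdaModel(
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        w_pred=w,
        p_pred=p_load,
        c_pred=c,
        t_pred=t,
        w_orth=np.column_stack(w_orth_list) if k else np.zeros((p, 0)),
        p_orth=np.column_stack(p_orth_list) if k else np.zeros((p, 0)),
        t_orth=np.column_stack(t_orth_list) if k else np.zeros((n, 0)),
        r2x=r2x,
        r2x_orth=np.asarray(r2xo),
        r2y=r2y,
        p_corr=pcorr,
        p_corr_flags=flags,
    )


def predict(model: OplsdaModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project new samples through the model.

    New rows are centred with the training offsets, filtered through the
    orthogonal components, then projected onto the predictive weight.

    Returns
    -------
    t_ps
        Predicted scores (tPS).
    calls
        Predicted class labels (0.5 threshold on the predicted response).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"column mismatch: model has {model.x_mean.size} variables, "
            f"got {X_new.shape[1]}")
    Xd = X_new - model.x_mean
    for j in range(model.n_orth):
        to = Xd @ model.w_orth[:, j]
        Xd = Xd - np.outer(to, model.p_orth[:, j])
    t_ps = Xd @ model.w_pred
    y_hat = t_ps * model.c_pred + model.y_mean
    calls = np.where(y_hat >= 0.5, model.classes[1], model.classes[0])
    return t_ps, calls


def _fold_assignment(n: int, n_folds: int, y01: np.ndarray) -> np.ndarray:
    """Deterministic interleaved folds; stratified reassignment if a fold
    would lose a class from its training split."""
    folds = np.arange(n) % n_folds
    for k in range(n_folds):
        train = folds != k
        if len(np.unique(y01[train])) < 2:
            warnings.warn("fold lost a class; using stratified interleaving")
            folds = np.empty(n, dtype=int)
            for cls in (0.0, 1.0):
                idx = np.flatnonzero(y01 == cls)
                folds[idx] = np.arange(idx.size) % n_folds
            break
    return folds


def cross_validate(X: np.ndarray, y, n_orth: int = 2, n_folds: int = 7,
                   return_predictions: bool = False):
    """K-fold cross-validated Q2 = 1 - PRESS/SS.

    Folds are assigned by deterministic interleaving over the sample order
    (samples are expected sorted by id); if a training split would lose a
    class, folds are reassigned by within-class interleaving (logged via a
    warning).  Each training fold re-centers internally via ``fit_oplsda``.
    """
    X = np.asarray(X, dtype=float)
    y01, classes = _encode_labels(y)
    n = len(y01)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_folds = min(n_folds, n)
    folds = _fold_assignment(n, n_folds, y01)
    y_arr = np.asarray(y)
    y_cv = np.empty(n)
    for k in range(n_folds):
        test = folds == k
        try:
            model = fit_oplsda(X[~test], y_arr[~test], n_orth=n_orth)
        except DegenerateWeightsError:
            # no class-correlated variation in the training split: the
            # no-information model predicts the training class mean
            y_cv[test] = y01[~test].mean()
            continue
        t_ps, _ = predict(model, X[test])
        # map onto the global 0/1 coding (training coding equals global:
        # both classes present in every training split)
        y_cv[test] = t_ps * model.c_pred + model.y_mean
    press = float(((y01 - y_cv) ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    if return_predictions:
        return q2, y_cv
    return q2


def permutation_test(X: np.ndarray, y, n_orth: int = 2, n_perm: int = 999,
                     seed: int | None = None, n_folds: int = 7) -> ValidationReport:
    """Label-permutation significance test for R2Y and Q2.

    Empirical p = (1 + #{permuted statistic >= observed}) / (n_perm + 1);
    seeded and reproducible.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("a seed is required for permutation testing")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    model = fit_oplsda(X, y_arr, n_orth=n_orth)
    q2_obs, y_cv = cross_validate(X, y_arr, n_orth=n_orth, n_folds=n_folds,
                                  return_predictions=True)
    r2y_perm = np.empty(n_perm)
    q2_perm = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y_arr)
        try:
            m = fit_oplsda(X, yp, n_orth=n_orth)
            r2y_perm[b] = m.r2y
            q2_perm[b] = cross_validate(X, yp, n_orth=n_orth, n_folds=n_folds)
        except ValueError:  # pathological permutation (degenerate weights)
            r2y_perm[b] = 1.0
            q2_perm[b] = 1.0
    p_r2y = (1 + int((r2y_perm >= model.r2y).sum())) / (n_perm + 1)
    p_q2 = (1 + int((q2_perm >= q2_obs).sum())) / (n_perm + 1)
    return ValidationReport(
        q2=q2_obs, y_cv=y_cv, r2y_perm=r2y_perm, q2_perm=q2_perm,
        p_r2y=p_r2y, p_q2=p_q2)


def cv_anova(y, y_cv: np.ndarray, n_components: int) -> tuple[float, float]:
    """ANOVA of the cross-validated residuals (CV-ANOVA).

    F-test of the cross-validated predictive residual sum of squares
    (PRESS) against the total corrected variation of the response,
    following the published CV-ANOVA formulation for PLS/OPLS models:

        SStot = sum (y - ybar)^2,        DFtot = N - 1
        SSreg = SStot - PRESS,           DFreg = A
        F = (SSreg / DFreg) / (PRESS / DFres),  DFres = DFtot - DFreg

    with A the number of model components (predictive + orthogonal).  The
    p-value is the upper tail of F(DFreg, DFres); a negative SSreg (model
    worse than the mean) maps to F <= 0 and p = 1.

    Raises if there are not enough samples for the degrees of freedom, and
    reports a machine-floor p with a warning when PRESS is (numerically)
    zero.
    """
    y01, _ = _encode_labels(y)
    y_cv = np.asarray(y_cv, dtype=float)
    n = len(y01)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    df_reg = n_components
    df_res = n - 1 - df_reg
    if df_res < 1:
        raise ValueError(
            f"too few samples (n={n}) for {n_components} model components")
    press = float(((y01 - y_cv) ** 2).sum())
    ss_tot = float(((y01 - y01.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has no variation")
    if press <= ss_tot * 1e-15:
        warnings.warn("cv-ANOVA: zero cross-validated residual variance; "
                      "p reported at machine floor")
        return float("inf"), float(np.finfo(float).tiny)
    f_stat = ((ss_tot - press) / df_reg) / (press / df_res)
    p_value = float(stats.f.sf(f_stat, df_reg, df_res)) if f_stat > 0 else 1.0
    return float(f_stat), p_value


def p_corr(model: OplsdaModel, X: np.ndarray) -> np.ndarray:
    """Per-variable Pearson correlation with the predictive score t[1].

    Computed against the centered (unscaled-back) variables of ``X``;
    zero-variance variables get p(corr) = 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(model.t_pred):
        raise ValueError("X must be the training matrix (row count mismatch)")
    Xc = X - X.mean(axis=0)
    t = model.t_pred - model.t_pred.mean()
    sd_x = Xc.std(axis=0)
    flags = sd_x == 0
    denom = len(t) * np.where(flags, 1.0, sd_x) * t.std()
    vals = (Xc.T @ t) / denom
    return np.clip(np.where(flags, 0.0, vals), -1.0, 1.0)


def misclassification_table(calls, truth, classes=None) -> pd.DataFrame:
    """Per-class member counts and percent correctly classified.

    One row per class present in ``truth``.  When ``classes`` (the model's
    label set) is given, any call or truth label outside it is rejected.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    if classes is not None:
        known = set(classes)
        unknown = (set(np.unique(calls)) | set(np.unique(truth))) - known
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
    rows = []
    for cls in np.unique(truth):
        members = int((truth == cls).sum())
        correct = int(((truth == cls) & (calls == cls)).sum())
        rows.append({
            "class": cls,
            "members": members,
            "correct": correct,
            "percent_correct": 100.0 * correct / members if members else float("nan"),
        })
    return pd.DataFrame(rows).set_index("class")
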
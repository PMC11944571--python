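"""Partial least squares regression (PLS1, NIPALS) with VIP band analysis.

The latent-variable count is chosen by exact leave-one-out
cross-validation minimising RMSE, as is conventional for calibration sets
of a few hundred spectra. With a single response the NIPALS inner loop is
non-iterative: per component, w = X'y / ||X'y||, t = Xw, p = X't/t't,
q = y't/t't, followed by deflation of X and y. The coefficient path
B_k = W_k (P_k' W_k)^{-1} q_k gives predictions at every candidate LV
count from one fit, which keeps LOO affordable.

Predictors are mean-centred, not variance-scaled (spectroscopy
convention: all bands share units of absorbance).

VIP (variable importance in projection) per wavelength j:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),   SS_a = q_a^2 t_a't_a

with w_a unit-norm; mean(VIP^2) = 1 is an identity, and VIP > 1 flags
informative bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PLSRModel:
    """Fitted PLS1 model (see module docstring for the algebra)."""

    n_lv: int
    weights: np.ndarray          # p x A, unit-norm columns
    x_loadings: np.ndarray       # p x A
    y_loadings: np.ndarray       # A
    x_scores: np.ndarray         # n x A
    coef: np.ndarray             # p, for the chosen n_lv
    x_mean: np.ndarray
    y_mean: float
    cv_rmse_by_lv: np.ndarray    # RMSE at 1..max_lv
    wavelengths: np.ndarray | None = None

    @property
    def vip(self) -> np.ndarray:
        return vip_scores(self)

    def to_dict(self) -> dict:
        """Self-describing JSON-ready artifact."""
        return {
            "model": "plsr",
            "n_lv": int(self.n_lv),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coef": self.coef.tolist(),
            "vip": self.vip.tolist(),
            "cv_rmse_by_lv": self.cv_rmse_by_lv.tolist(),
            "wavelengths": None
            if self.wavelengths is None
            else self.wavelengths.tolist(),
        }


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, max_lv: int):
    """NIPALS components on centred data. Returns (W, P, q, T, n_kept)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    T = np.zeros((n, max_lv))
    eps = 1e-12 * max(1.0, float(np.abs(Xc).max()) ** 2)
    a = 0
    for a in range(max_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= eps:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        W[:, a], T[:, a] = w, t
        P[:, a] = (X.T @ t) / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, P[:, a])
        y -= q[a] * t
    else:
        a = max_lv
        return W, P, q, T, a
    return W[:, :a], P[:, :a], q[:a], T[:, :a], a


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vectors B_k for k = 1..A, columns of a p x A matrix."""
    A = W.shape[1]
    R = P.T @ W  # A x A, upper triangular for PLS1
    coefs = np.empty((W.shape[0], A))
    for k in range(1, A + 1):
        alpha = np.linalg.solve(R[:k, :k], q[:k])
        coefs[:, k - 1] = W[:, :k] @ alpha
    return coefs


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 20,
    cv: str = "loo",
    wavelengths: np.ndarray | None = None,
) -> PLSRModel:
    """Fit PLS1 with the LV count minimising leave-one-out RMSE.

    ``max_lv`` is clipped to the data rank with a warning if it exceeds
    it. Ties in CV RMSE go to the smaller LV count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError(f"X has {n} rows but y has {y.size} values")
    if n < 3:
        raise ValueError("PLSR needs at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to calibrate")
    if not np.any(np.ptp(X, axis=0) > 0):
        raise ValueError("all predictor columns are constant")
    if cv != "loo":
        raise ValueError(f"unsupported cv scheme {cv!r}")
    rank = min(n - 1, p)
    if max_lv > rank:
        warnings.warn(
            f"max_lv={max_lv} exceeds data rank {rank}; clipping", stacklevel=2
        )
        max_lv = rank

    # exact leave-one-out over the whole coefficient path
    press = np.zeros(max_lv)       # sum of squared LOO errors per LV count
    avail = np.zeros(max_lv)       # folds where a given LV count was reachable
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xi, yi = X[keep], y[keep]
        xm, ym = Xi.mean(axis=0), yi.mean()
        W, P, q, _, A = _nipals_pls1(Xi - xm, yi - ym, max_lv)
        if A == 0:
            continue
        coefs = _coef_path(W, P, q)
        preds = ym + (X[i] - xm) @ coefs
        err = (preds - y[i]) ** 2
        press[:A] += err
        if A < max_lv:  # rank ran out in this fold: carry the last reachable
            press[A:] += err[-1]
        avail[:] += 1
    cv_rmse = np.sqrt(press / np.maximum(avail, 1))
    n_lv = int(np.argmin(cv_rmse)) + 1

    xm, ym = X.mean(axis=0), float(y.mean())
    W, P, q, T, A = _nipals_pls1(X - xm, y - ym, max_lv)
    n_lv = min(n_lv, A)
    coef = _coef_path(W, P, q)[:, n_lv - 1]
    return PLSRModel(
        n_lv=n_lv,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coef=coef,
        x_mean=xm,
        y_mean=ym,
        cv_rmse_by_lv=cv_rmse[:A],
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def predict_plsr(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """yhat = y_mean + (X_new - x_mean) @ coef."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} wavelengths, got {X_new.shape[1]} "
            "(wavelength grid mismatch with training)"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coef


def vip_scores(model: PLSRModel) -> np.ndarray:
    """VIP over the wavelengths, using the chosen n_lv components."""
    A = model.n_lv
    W = model.weights[:, :A]
    T = model.x_scores[:, :A]
    q = model.y_loadings[:A]
    ss = q**2 * np.einsum("ij,ij->j", T, T)  # y-variance captured per LV
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ss) / ss.sum())


def important_bands(
    vip: np.ndarray,
    wavelengths: np.ndarray,
    threshold: float = 1.0,
    merge_gap_nm: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal nm intervals where VIP exceeds the threshold.

    Contiguous above-threshold runs become closed intervals
    ``(lo_nm, hi_nm)``; adjacent intervals separated by a gap of at most
    ``merge_gap_nm`` are merged.
    """
    vip = np.asarray(vip, dtype=float).ravel()
    wavelengths = np.asarray(wavelengths, dtype=float).ravel()
    if vip.size != wavelengths.size:
        raise ValueError("vip and wavelengths lengths differ")
    above = vip > threshold
    if not above.any():
        return []
    intervals: list[list[float]] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) for e in edges if above[e]]
    if above[-1]:
        ends.append(vip.size - 1)
    for s, e in zip(starts, ends):
        lo, hi = float(wavelengths[s]), float(wavelengths[e])
        if intervals and lo - intervals[-1][1] <= merge_gap_nm:
            intervals[-1][1] = hi
        else:
            intervals.append([lo, hi])
    return [(lo, hi) for lo, hi in intervals]
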
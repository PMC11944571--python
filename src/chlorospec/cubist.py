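"""Cubist-style rule-based regression (model trees + committees + instance
correction).

This is a re-implementation of the published Cubist/M5 mechanism, not a
bit-compatible clone of the proprietary code:

* **model tree** — greedy variance-reduction splits partition the
  predictor space; every node carries a linear model, grown trees are
  pruned bottom-up where a node's own model does as well as its subtree
  (M5-style), and predictions are smoothed from leaf to root with the M5
  blend (n_child * child + k * parent) / (n_child + k). Node linear
  models are fitted by PLS1 with a capped latent-variable count — on
  full-rank problems (few predictors) this is exactly ordinary least
  squares, while on wide collinear spectra (thousands of bands, a handful
  of rows in a leaf) it stays well-posed and noise-averages across bands
  the way any competent calibration of p >> n spectra must;
* **committees** — tree m+1 is trained on residual-reflected pseudo
  targets y - (ensemble_m(x) - y); the ensemble predicts with the mean of
  its members;
* **nearest-neighbor correction** — the prediction at a query is averaged
  with the model-corrected responses of its k nearest training spectra.

The hyperparameter grid of the study design — committees {2, 4, 6, 8} by
neighbors {10, 20, 30, 40} — is searched with a single seeded 10-fold
partition shared by every cell; because a (c)-committee model is a prefix
of the (c_max)-committee model, each fold is fitted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .plsr import _coef_path, _nipals_pls1

DEFAULT_COMMITTEES = (2, 4, 6, 8)
DEFAULT_NEIGHBORS = (10, 20, 30, 40)


# --------------------------------------------------------------------------
# node linear models
# --------------------------------------------------------------------------

@dataclass
class _LinearModel:
    features: np.ndarray     # column indices into the full predictor matrix
    coef: np.ndarray
    intercept: float
    n_lv: int = 0            # latent variables used by the PLS fit (0 = mean)
    err_est: float = np.inf  # internal-CV RMSE on the node's own rows

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.features.size == 0:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, self.features] @ self.coef


def _fit_linear(
    X: np.ndarray, y: np.ndarray, features: np.ndarray, model_lv: int = 15
) -> _LinearModel:
    """Node linear model: PLS1 on the candidate features.

    Narrow problems (no more features than the LV cap) are fitted at full
    rank — exactly ordinary least squares. Wide problems (spectra) cap
    the LV count at ``model_lv`` and ``n/3`` and pick it by a striped
    3-fold internal cross-validation along the coefficient path, which is
    the model-simplification step keeping small leaves from
    interpolating."""
    feats = np.asarray(features, dtype=int)
    n = X.shape[0]
    if feats.size == 0 or n < 3 or np.ptp(y) == 0:
        err = float(np.std(y)) if n else np.inf
        return _LinearModel(
            np.empty(0, dtype=int), np.empty(0), float(np.mean(y)), err_est=err
        )
    Xf = X[:, feats]
    rank = min(n - 1, feats.size)
    # wide problems: cap the LV count and pick it by internal CV; narrow
    # ones are fitted at full rank (exactly OLS), CV only estimates error
    narrow = feats.size <= model_lv
    cap = rank if narrow else max(1, min(model_lv, rank, n // 3))
    lv, err_est = cap, np.inf
    if n >= 9:
        press = np.zeros(cap)
        stripe = np.arange(n) % 3
        for f in range(3):
            tr = stripe != f
            Xt, yt = Xf[tr], y[tr]
            xm_f, ym_f = Xt.mean(axis=0), yt.mean()
            W, P, q, _, A = _nipals_pls1(Xt - xm_f, yt - ym_f, cap)
            if A == 0:
                press += float(np.sum((y[~tr] - ym_f) ** 2))
                continue
            path = _coef_path(W, P, q)
            preds = ym_f + (Xf[~tr] - xm_f) @ path
            err = np.sum((preds - y[~tr][:, None]) ** 2, axis=0)
            press[:A] += err
            if A < cap:
                press[A:] += err[-1]
        if not narrow:
            lv = int(np.argmin(press)) + 1
        err_est = float(np.sqrt(press[lv - 1] / n))
    else:
        # too few rows for CV: pessimistic training error
        err_est = None  # filled below from the final fit
    xm, ym = Xf.mean(axis=0), float(np.mean(y))
    W, P, q, _, A = _nipals_pls1(Xf - xm, y - ym, lv)
    if A == 0:
        return _LinearModel(
            np.empty(0, dtype=int), np.empty(0), ym, err_est=float(np.std(y))
        )
    coef = _coef_path(W, P, q)[:, A - 1]
    model = _LinearModel(feats, coef, ym - float(xm @ coef), n_lv=A)
    if err_est is None:
        resid = y - model.predict(X)
        nu = A + 1
        err_est = float(
            np.sqrt(np.mean(resid**2)) * (n + nu) / max(n - nu, 1)
        )
    model.err_est = err_est
    return model


# --------------------------------------------------------------------------
# split search (vectorised over candidate features)
# --------------------------------------------------------------------------

def _linreg_sse(
    sx: np.ndarray, sy: np.ndarray, sxx: np.ndarray, syy: np.ndarray,
    sxy: np.ndarray, m: np.ndarray | float,
) -> np.ndarray:
    """Residual SSE of a simple linear regression from running sums; falls
    back to the around-the-mean SSE when x is (nearly) constant."""
    var_term = syy - sy * sy / m
    sxx_c = sxx - sx * sx / m
    sxy_c = sxy - sx * sy / m
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = np.where(sxx_c > 1e-30, sxy_c * sxy_c / sxx_c, 0.0)
    return np.maximum(var_term - fit, 0.0)


def _split_scores(Xc: np.ndarray, y: np.ndarray, min_leaf: int):
    """Per-feature split scoring for a model tree.

    A split is scored by the summed residual SSE of simple linear
    regressions of y on the candidate feature, fitted separately on each
    side — the variance reduction that matters for trees whose leaves
    hold linear models (a mean-based score cannot see a slope kink).
    Returns (xs sorted values, per-position scores, per-feature parent
    SSE); invalid positions are +inf.
    """
    n = Xc.shape[0]
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order]
    cx = np.cumsum(xs, axis=0)
    cy = np.cumsum(ys, axis=0)
    cxx = np.cumsum(xs * xs, axis=0)
    cyy = np.cumsum(ys * ys, axis=0)
    cxy = np.cumsum(xs * ys, axis=0)
    m = np.arange(1, n, dtype=float)[:, None]
    left = _linreg_sse(cx[:-1], cy[:-1], cxx[:-1], cyy[:-1], cxy[:-1], m)
    right = _linreg_sse(
        cx[-1] - cx[:-1], cy[-1] - cy[:-1], cxx[-1] - cxx[:-1],
        cyy[-1] - cyy[:-1], cxy[-1] - cxy[:-1], n - m,
    )
    parent = _linreg_sse(cx[-1], cy[-1], cxx[-1], cyy[-1], cxy[-1], float(n))
    score = left + right
    valid = (m >= min_leaf) & (m <= n - min_leaf) & (xs[1:] > xs[:-1])
    return xs, np.where(valid, score, np.inf), parent


def _best_split(
    X: np.ndarray, y: np.ndarray, candidates: np.ndarray, min_leaf: int
) -> tuple[int, float, float, float] | None:
    """Best (feature, threshold, SSE reduction, parent single-feature
    SSE) over candidate features, or None when no split keeps
    ``min_leaf`` rows on each side.

    The reduction is measured against the parent's best single-feature
    linear fit; ties break to the lowest feature index then the lowest
    threshold."""
    n = X.shape[0]
    if n < 2 * min_leaf:
        return None
    xs, score, parent = _split_scores(X[:, candidates], y, min_leaf)
    if not np.isfinite(score).any():
        return None
    parent_best = float(parent.min())
    # column-major flat argmin => lowest feature index wins ties, then the
    # lowest split position within the feature
    flat = np.argmin(score.T)
    col, row = divmod(flat, score.shape[0])
    threshold = 0.5 * (xs[row, col] + xs[row + 1, col])
    gain = parent_best - float(score[row, col])
    return int(candidates[col]), float(threshold), gain, parent_best


def _feature_gains(X: np.ndarray, y: np.ndarray, min_leaf: int) -> np.ndarray:
    """Best split-SSE reduction per feature (for candidate screening),
    -inf where no valid split exists."""
    n, p = X.shape
    gains = np.full(p, -np.inf)
    if n < 2 * min_leaf:
        return gains
    chunk = 512  # bound peak memory on wide spectra
    for lo in range(0, p, chunk):
        cols = np.arange(lo, min(lo + chunk, p))
        xs, score, parent = _split_scores(X[:, cols], y, min_leaf)
        best = score.min(axis=0)
        gains[cols] = np.where(np.isfinite(best), parent - best, -np.inf)
    return gains


# --------------------------------------------------------------------------
# model tree
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    n: int
    model: _LinearModel
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


@dataclass(frozen=True)
class TreeConfig:
    """Model-tree growth settings.

    min_leaf
        Minimum training rows per leaf.
    max_depth
        Maximum split depth.
    min_gain
        A split must remove at least this fraction of the node's SSE;
        below it the node stays a leaf (this is what keeps pure-noise
        targets at depth 0).
    screen_k
        When set, node linear models are restricted to the split-path
        features plus the ``screen_k`` wavelengths with the highest
        root-level variance reduction; None (default) lets every node
        model see all wavelengths — the PLS fit keeps it well-posed.
    model_lv
        Latent-variable cap for the node PLS models; at full rank the
        fit is exactly OLS.
    max_split_features
        Split search is restricted to the top candidates by root-level
        gain when the predictor count exceeds this.
    smooth_k
        M5 smoothing constant k; 0 disables leaf-to-root blending.
    prune
        M5-style bottom-up pruning: a subtree collapses to its node when
        the node model's penalised training error is no worse than the
        subtree's.
    """

    min_leaf: int = 10
    max_depth: int = 8
    min_gain: float = 0.05
    screen_k: int | None = None
    model_lv: int = 15
    max_split_features: int = 256
    smooth_k: float = 15.0
    prune: bool = True


def fit_model_tree(
    X: np.ndarray, y: np.ndarray, cfg: TreeConfig | None = None
) -> TreeNode:
    """Greedy variance-reduction model tree with linear models at every
    node. Degenerate inputs (too few rows, constant X or y) yield a
    single-leaf tree whose model is the OLS fit."""
    cfg = cfg or TreeConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y row counts differ")
    if n < 2:
        raise ValueError("need at least 2 rows")

    if p > cfg.max_split_features or cfg.screen_k is not None:
        gains = _feature_gains(X, y, cfg.min_leaf)
        ranked = np.argsort(-gains, kind="stable")
    if cfg.screen_k is not None:
        screen = ranked[: cfg.screen_k]
        screen = screen[np.isfinite(gains[screen])]
        if screen.size == 0:
            screen = np.arange(min(p, cfg.screen_k))
    else:
        screen = np.arange(p)
    if p > cfg.max_split_features:
        candidates = np.sort(ranked[: cfg.max_split_features])
        candidates = candidates[np.isfinite(gains[candidates])]
        if candidates.size == 0:
            candidates = np.arange(min(p, cfg.max_split_features))
    else:
        candidates = np.arange(p)

    def model_features(path: list[int]) -> np.ndarray:
        if cfg.screen_k is None:
            return screen  # all features; path is a subset already
        seen: dict[int, None] = dict.fromkeys(path)
        seen.update(dict.fromkeys(int(f) for f in screen))
        return np.fromiter(seen.keys(), dtype=int)

    def grow(rows: np.ndarray, depth: int, path: list[int]) -> tuple[TreeNode, float]:
        """Returns the (possibly pruned) node and its error estimate (the
        node model's internal-CV RMSE); a subtree's estimate is the
        size-weighted mean of its children's, compared bottom-up against
        the node's own model (reduced-error pruning)."""
        Xn, yn = X[rows], y[rows]
        model = _fit_linear(Xn, yn, model_features(path), cfg.model_lv)
        node = TreeNode(n=rows.size, model=model)
        own_err = model.err_est
        if depth >= cfg.max_depth or rows.size < 2 * cfg.min_leaf:
            return node, own_err
        if np.ptp(yn) == 0:
            return node, own_err
        best = _best_split(Xn, yn, candidates, cfg.min_leaf)
        if best is None:
            return node, own_err
        feat, thr, gain, parent_sse = best
        if gain < cfg.min_gain * max(parent_sse, 1e-30):
            return node, own_err
        go_left = X[rows, feat] <= thr
        left, err_l = grow(rows[go_left], depth + 1, path + [feat])
        right, err_r = grow(rows[~go_left], depth + 1, path + [feat])
        sub_err = (left.n * err_l + right.n * err_r) / rows.size
        if cfg.prune and own_err <= sub_err:
            return node, own_err
        node.feature, node.threshold = feat, thr
        node.left, node.right = left, right
        return node, sub_err

    return grow(np.arange(n), 0, [])[0]


def predict_tree(
    node: TreeNode, X: np.ndarray, smooth_k: float = 15.0
) -> np.ndarray:
    """Smoothed model-tree prediction: the leaf model's output is blended
    with each ancestor's model on the way back to the root using
    (n_child * child_pred + k * node_pred) / (n_child + k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))

    def rec(nd: TreeNode, idx: np.ndarray) -> np.ndarray:
        if nd.is_leaf:
            return nd.model.predict(X[idx])
        go_left = X[idx, nd.feature] <= nd.threshold
        out = np.empty(idx.size)
        for child, mask in ((nd.left, go_left), (nd.right, ~go_left)):
            if not mask.any():
                continue
            sub = idx[mask]
            below = rec(child, sub)
            if smooth_k > 0:
                here = nd.model.predict(X[sub])
                below = (child.n * below + smooth_k * here) / (child.n + smooth_k)
            out[mask] = below
        return out

    return rec(node, np.arange(X.shape[0]))


# --------------------------------------------------------------------------
# committees
# --------------------------------------------------------------------------

def fit_committees(
    X: np.ndarray, y: np.ndarray, c: int, cfg: TreeConfig | None = None
) -> list[TreeNode]:
    """Residual-reflected committee of ``c`` model trees.

    Tree m+1 is trained on y_adj = y - (ensemble_m(x) - y), where
    ensemble_m is the mean of the first m members; the first c trees of a
    longer committee are exactly the c-member committee.
    """
    if c < 1:
        raise ValueError("need at least one committee member")
    cfg = cfg or TreeConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    trees: list[TreeNode] = []
    pred_sum = np.zeros(y.size)
    for m in range(c):
        if m == 0:
            target = y
        else:
            target = 2 * y - pred_sum / m  # y - (ensemble - y)
        tree = fit_model_tree(X, target, cfg)
        trees.append(tree)
        pred_sum += predict_tree(tree, X, cfg.smooth_k)
    return trees


def predict_committees(
    trees: Sequence[TreeNode], X: np.ndarray, smooth_k: float = 15.0
) -> np.ndarray:
    """Arithmetic mean of the member trees' predictions."""
    preds = np.stack([predict_tree(t, X, smooth_k) for t in trees])
    return preds.mean(axis=0)


# --------------------------------------------------------------------------
# nearest-neighbour correction and the full model
# --------------------------------------------------------------------------

@dataclass
class CubistLiteModel:
    """Committee ensemble plus the training archive used for instance-based
    correction, and the CV table from the hyperparameter grid search."""

    committees: int
    neighbors: int
    trees: list[TreeNode]
    X_train: np.ndarray
    y_train: np.ndarray
    train_pred: np.ndarray                       # raw ensemble on the archive
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    w_nn: float = 0.5
    cv_table: dict[tuple[int, int], float] = field(default_factory=dict)
    cv_seed: int | None = None
    cv_fold_hash: str | None = None

    def predict(self, X_new: np.ndarray, neighbors: int | None = None) -> np.ndarray:
        k = self.neighbors if neighbors is None else neighbors
        raw = predict_committees(self.trees, X_new, self.tree_config.smooth_k)
        return nn_correct(self, np.atleast_2d(X_new), k, raw=raw)

    def to_dict(self) -> dict:
        def node_dict(nd: TreeNode) -> dict:
            d = {
                "n": nd.n,
                "model": {
                    "features": nd.model.features.tolist(),
                    "coef": nd.model.coef.tolist(),
                    "intercept": nd.model.intercept,
                },
            }
            if not nd.is_leaf:
                d.update(
                    feature=int(nd.feature),
                    threshold=float(nd.threshold),
                    left=node_dict(nd.left),
                    right=node_dict(nd.right),
                )
            return d

        return {
            "model": "cubist-lite",
            "committees": self.committees,
            "neighbors": self.neighbors,
            "w_nn": self.w_nn,
            "smooth_k": self.tree_config.smooth_k,
            "cv_seed": self.cv_seed,
            "cv_fold_hash": self.cv_fold_hash,
            "cv_table": {f"c={c},k={k}": v for (c, k), v in self.cv_table.items()},
            "trees": [node_dict(t) for t in self.trees],
        }


def nn_correct(
    model: CubistLiteModel,
    X_query: np.ndarray,
    k: int,
    raw: np.ndarray | None = None,
) -> np.ndarray:
    """Instance-based correction of the ensemble prediction.

    For each query, the k nearest training spectra (Euclidean) contribute
    y_i + f(query) - f(x_i); their mean is averaged with the raw model
    output using weight ``w_nn``. k = 0 returns the raw prediction.
    """
    if model.X_train.size == 0:
        raise ValueError("empty training archive")
    if k < 0 or k > model.y_train.size:
        raise ValueError(
            f"neighbors must be in [0, {model.y_train.size}], got {k}"
        )
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    if raw is None:
        raw = predict_committees(model.trees, X_query, model.tree_config.smooth_k)
    if k == 0:
        return raw
    d2 = (
        np.einsum("ij,ij->i", X_query, X_query)[:, None]
        - 2 * X_query @ model.X_train.T
        + np.einsum("ij,ij->i", model.X_train, model.X_train)[None, :]
    )
    nearest = np.argpartition(d2, k - 1, axis=1)[:, :k]
    resid = model.y_train - model.train_pred            # y_i - f(x_i)
    corrected = raw + resid[nearest].mean(axis=1)
    return model.w_nn * corrected + (1 - model.w_nn) * raw


def fit_cubist(
    X: np.ndarray,
    y: np.ndarray,
    committees: int,
    neighbors: int,
    cfg: TreeConfig | None = None,
    w_nn: float = 0.5,
) -> CubistLiteModel:
    """Fit a single (committees, neighbors) cell without grid search."""
    cfg = cfg or TreeConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    trees = fit_committees(X, y, committees, cfg)
    return CubistLiteModel(
        committees=committees,
        neighbors=neighbors,
        trees=trees,
        X_train=X.copy(),
        y_train=y.copy(),
        train_pred=predict_committees(trees, X, cfg.smooth_k),
        tree_config=cfg,
        w_nn=w_nn,
    )


def grid_search_cubist(
    X: np.ndarray,
    y: np.ndarray,
    committees: Sequence[int] = DEFAULT_COMMITTEES,
    neighbors: Sequence[int] = DEFAULT_NEIGHBORS,
    folds: int = 10,
    seed: int = 17,
    cfg: TreeConfig | None = None,
    w_nn: float = 0.5,
) -> CubistLiteModel:
    """Grid search over committees x neighbors under seeded k-fold CV.

    Every grid cell is evaluated on the same fold partition (fairness);
    the cell with the lowest mean CV RMSE wins (ties: fewer committees,
    then fewer neighbors) and is refitted on all rows.
    """
    cfg = cfg or TreeConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if n < 20:
        raise ValueError("grid search needs at least 20 samples")
    committees = sorted(int(c) for c in committees)
    neighbors = sorted(int(k) for k in neighbors)
    c_max = committees[-1]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    fold_hash = _fold_hash(splits)

    sse = {(c, k): 0.0 for c in committees for k in neighbors}
    for train_idx, test_idx in splits:
        Xtr, ytr, Xte, yte = X[train_idx], y[train_idx], X[test_idx], y[test_idx]
        trees = fit_committees(Xtr, ytr, c_max, cfg)
        member_tr = np.stack([predict_tree(t, Xtr, cfg.smooth_k) for t in trees])
        member_te = np.stack([predict_tree(t, Xte, cfg.smooth_k) for t in trees])
        for c in committees:
            raw_te = member_te[:c].mean(axis=0)
            archive = CubistLiteModel(
                committees=c,
                neighbors=0,
                trees=trees[:c],
                X_train=Xtr,
                y_train=ytr,
                train_pred=member_tr[:c].mean(axis=0),
                tree_config=cfg,
                w_nn=w_nn,
            )
            for k in neighbors:
                kk = min(k, ytr.size)
                pred = nn_correct(archive, Xte, kk, raw=raw_te)
                sse[(c, k)] += float(np.sum((pred - yte) ** 2))

    cv_table = {cell: float(np.sqrt(s / n)) for cell, s in sse.items()}
    best_cell = min(cv_table, key=lambda cell: (cv_table[cell], cell))
    model = fit_cubist(X, y, best_cell[0], best_cell[1], cfg, w_nn)
    model.cv_table = cv_table
    model.cv_seed = seed
    model.cv_fold_hash = fold_hash
    return model


def _fold_hash(splits: list[tuple[np.ndarray, np.ndarray]]) -> str:
    import hashlib

    h = hashlib.sha256()
    for _, test in splits:
        h.update(np.asarray(test, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]
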
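"""Canonical-correlation feature fusion.

Two matched feature sets X ∈ R^{p×n} and Y ∈ R^{q×n} are fused by
finding transformation matrices Wx, Wy that maximize
corr(WxᵀX, WyᵀY) under unit-variance constraints
(var(X*) = var(Y*) = 1), i.e. the eigen-problem

    Sxx⁻¹ Sxy Syy⁻¹ Syx Ŵx = Δ² Ŵx

whose d = rank(Sxy) solutions, sorted by decreasing canonical
correlation δ1 ≥ … ≥ δd, give the canonical variates.  The fused
feature vector is their concatenation Z = [WxᵀX; WyᵀY] ∈ R^{2d×n},
whose training-set covariance has identity diagonal blocks and
diag(δ) off-diagonal blocks.

Because a subject contributes five scalar features per region, fusion
proceeds sequentially two at a time: Z1 = fuse(f1, f2), then
Zk = fuse(Zk−1, fk+1); each pairwise step has d = 1, so the final
per-region fused vector is 2-dimensional.  The fitted chain is kept for
test-time replay — test folds are transformed, never refit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: ridge added to within-set covariances, scaled by trace/p
RIDGE = 1e-8
#: singular values of the whitened cross-covariance below this fraction
#: of the largest count as zero when determining d = rank(Sxy)
RANK_RTOL = 1e-10


@dataclass
class CCAModel:
    """Fitted canonical correlation transform for one feature pair."""

    Wx: np.ndarray  # p×d
    Wy: np.ndarray  # q×d
    correlations: np.ndarray  # δ1 ≥ … ≥ δd, in [0,1]
    mean_x: np.ndarray  # p
    mean_y: np.ndarray  # q

    @property
    def d(self) -> int:
        return self.Wx.shape[1]


def _as_matrix(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    if A.ndim != 2:
        raise ValueError("feature sets must be 1- or 2-dimensional")
    return A


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, np.finfo(float).tiny)
    return (V / np.sqrt(w)) @ V.T


def cca_fit(X, Y) -> CCAModel:
    """Fit CCA between matched feature sets X (p×n) and Y (q×n).

    Covariances use the 1/n convention (invariant under sample
    duplication).  Near-singular within-set covariances are ridge
    regularized with a warning.  Transform signs are fixed so each Wx
    column's largest-magnitude entry is positive, keeping results
    deterministic; δ ≥ 0 by construction.
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    p, n = X.shape
    q, ny = Y.shape
    if ny != n:
        raise ValueError(f"sample count mismatch: X has {n}, Y has {ny}")
    if n < 3:
        raise ValueError("need at least 3 matched samples")
    mean_x = X.mean(axis=1)
    mean_y = Y.mean(axis=1)
    Xc = X - mean_x[:, None]
    Yc = Y - mean_y[:, None]
    Sxx = Xc @ Xc.T / n
    Syy = Yc @ Yc.T / n
    Sxy = Xc @ Yc.T / n
    for S, dim, name in ((Sxx, p, "X"), (Syy, q, "Y")):
        tr = np.trace(S)
        if tr <= 0 or np.linalg.cond(S) > 1e10:
            logger.warning("near-singular within-set covariance for %s; "
                           "ridge regularized", name)
            S += RIDGE * (tr / dim if tr > 0 else 1.0) * np.eye(dim)
    isx = _inv_sqrt(Sxx)
    isy = _inv_sqrt(Syy)
    K = isx @ Sxy @ isy
    U, s, Vt = np.linalg.svd(K)
    d = int((s > RANK_RTOL * max(s[0], 1e-300)).sum()) if s.size else 0
    Wx = isx @ U[:, :d]
    Wy = isy @ Vt.T[:, :d]
    for j in range(d):
        i = int(np.argmax(np.abs(Wx[:, j])))
        if Wx[i, j] < 0:
            Wx[:, j] *= -1
            Wy[:, j] *= -1
    corr = np.clip(s[:d], 0.0, 1.0)
    return CCAModel(Wx, Wy, corr, mean_x, mean_y)


def cca_transform(model: CCAModel, X, Y) -> np.ndarray:
    """Fused features Z = [Wxᵀ(X−μx); Wyᵀ(Y−μy)] ∈ R^{2d×n}."""
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if X.shape[0] != model.Wx.shape[0] or Y.shape[0] != model.Wy.shape[0]:
        raise ValueError(
            f"dimension mismatch: model expects ({model.Wx.shape[0]}, "
            f"{model.Wy.shape[0]}) features, got ({X.shape[0]}, {Y.shape[0]})"
        )
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same sample count")
    Xs = model.Wx.T @ (X - model.mean_x[:, None])
    Ys = model.Wy.T @ (Y - model.mean_y[:, None])
    return np.vstack([Xs, Ys])


@dataclass
class FusionChain:
    """The fitted sequence of pairwise CCA models for one region."""

    models: list[CCAModel] = field(default_factory=list)
    feature_order: tuple[int, ...] = (0, 1, 2, 3, 4)
    skipped: list[int] = field(default_factory=list)

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Replay the fitted chain on a 5×n feature block."""
        features = np.asarray(features, dtype=float)
        order = list(self.feature_order)
        Z = features[order[0]][None, :]
        k = 1
        for m in self.models:
            while k < len(order) and order[k] in self.skipped:
                k += 1
            nxt = features[order[k]][None, :]
            Z = cca_transform(m, Z, nxt)
            k += 1
        return Z

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_order": list(self.feature_order),
            "skipped": self.skipped,
            "models": [
                {
                    "Wx": m.Wx.tolist(), "Wy": m.Wy.tolist(),
                    "correlations": m.correlations.tolist(),
                    "mean_x": m.mean_x.tolist(), "mean_y": m.mean_y.tolist(),
                }
                for m in self.models
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionChain":
        d = json.loads(Path(path).read_text())
        models = [
            CCAModel(np.array(m["Wx"]), np.array(m["Wy"]),
                     np.array(m["correlations"]),
                     np.array(m["mean_x"]), np.array(m["mean_y"]))
            for m in d["models"]
        ]
        return cls(models, tuple(d["feature_order"]), list(d["skipped"]))


def sequential_fuse(
    features: np.ndarray, feature_order: tuple[int, ...] = (0, 1, 2, 3, 4)
) -> tuple[np.ndarray, FusionChain]:
    """Fuse a region's five feature vectors pairwise into one 2×n block.

    ``features`` is 5×n (already normalized to [0,1]).  The chain runs
    in the fixed canonical feature order (gaussian, mean, sharpness,
    curvedness, volume) unless permuted.  Each step fuses the running
    fused block with the next scalar feature; d = 1 per step, so Z stays
    2-dimensional.  A step whose cross-covariance has rank 0 (constant
    feature) is skipped with a warning rather than collapsing the chain.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("expected a (n_features × n_samples) block")
    n = features.shape[1]
    if n < 6:
        raise ValueError("sequential fusion needs at least 6 samples")
    order = tuple(feature_order)
    if sorted(order) != list(range(features.shape[0])):
        raise ValueError("feature_order must be a permutation of all features")
    chain = FusionChain(models=[], feature_order=order)
    Z = features[order[0]][None, :]
    for k in order[1:]:
        nxt = features[k][None, :]
        model = cca_fit(Z, nxt)
        if model.d == 0:
            logger.warning("fusion step with feature %d has rank-0 "
                           "cross-covariance; feature skipped", k)
            chain.skipped.append(k)
            continue
        Z = cca_transform(model, Z, nxt)
        chain.models.append(model)
    return Z, chain
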
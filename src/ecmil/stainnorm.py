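"""Structure-preserving H&E stain normalization (Vahadane-style).

Stains mix linearly in optical density (OD) space by the Beer-Lambert law:
``OD = -log10(I / I0) = C @ S.T`` with a nonnegative 3x2 stain matrix S
(unit-norm columns, hematoxylin first) and nonnegative per-pixel
concentrations C.  The stain matrix is estimated by sparse nonnegative
matrix factorization of the tissue OD pixels,

    min_{C>=0, S>=0, ||s_k||<=1}  ||X - C S^T||_F^2 + lambda * ||C||_1,

solved by alternating an exact nonnegative-lasso concentration step
(coordinate descent, vectorized over pixels) with a projected block
coordinate dictionary update.  Normalizing an image rescales its stain
concentrations so their 99th percentiles match a target model's, then
reconstructs with the target stain matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StainModel",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stains",
    "concentrations",
    "fit_stain_model",
    "normalize",
    "OD_BACKGROUND_FLOOR",
]

OD_BACKGROUND_FLOOR = 0.15  # pixels with OD norm below this are background


@dataclass
class StainModel:
    """3x2 OD stain matrix (unit-norm nonneg columns, hematoxylin first) with
    99th-percentile concentration scales."""

    S: np.ndarray
    p99: np.ndarray
    objective_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        self.p99 = np.asarray(self.p99, dtype=np.float64)
        if self.S.shape[0] != 3 or np.any(self.S < -1e-12):
            raise ValueError("stain matrix must be 3 x n_stains, nonnegative")
        norms = np.linalg.norm(self.S, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain columns must be unit norm")

    def to_json(self) -> str:
        return json.dumps({"S": self.S.tolist(), "p99": self.p99.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "StainModel":
        obj = json.loads(text)
        return cls(S=np.asarray(obj["S"]), p99=np.asarray(obj["p99"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "StainModel":
        return cls.from_json(Path(path).read_text())


def rgb_to_od(image: np.ndarray, I0: float = 255.0) -> np.ndarray:
    """Optical densities, -log10(max(I,1)/I0); finite and >= 0 for 8-bit input."""
    img = np.maximum(np.asarray(image, dtype=np.float64), 1.0)
    return np.maximum(-np.log10(img / I0), 0.0)


def od_to_rgb(od: np.ndarray, I0: float = 255.0) -> np.ndarray:
    img = I0 * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# sparse NMF


def _nn_lasso_2(X: np.ndarray, S: np.ndarray, lam: float,
                C0: np.ndarray | None = None, sweeps: int = 60,
                tol: float = 1e-12) -> np.ndarray:
    """Exact min over C >= 0 of ||X - C S^T||^2 + lam ||C||_1 for 2 stains,
    by coordinate descent vectorized over pixels (convex, converges)."""
    n_stains = S.shape[1]
    C = np.zeros((X.shape[0], n_stains)) if C0 is None else C0.copy()
    G = S.T @ S                    # (2, 2)
    B = X @ S                      # (N, 2)
    for _ in range(sweeps):
        delta = 0.0
        for k in range(n_stains):
            other = [j for j in range(n_stains) if j != k]
            num = B[:, k] - C[:, other] @ G[other, k] - 0.5 * lam
            new = np.maximum(num / max(G[k, k], 1e-12), 0.0)
            delta = max(delta, float(np.max(np.abs(new - C[:, k]), initial=0.0)))
            C[:, k] = new
        if delta < tol:
            break
    return C


def _objective(X: np.ndarray, C: np.ndarray, S: np.ndarray, lam: float) -> float:
    R = X - C @ S.T
    return float(np.sum(R * R) + lam * np.sum(np.abs(C)))


def _extreme_angle_init(X: np.ndarray, n_stains: int) -> np.ndarray:
    """Macenko-style initialization: project OD pixels onto their top-2
    principal plane and take the extreme-angle directions."""
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    plane = Vt[:2]                             # (2, 3)
    # orient the plane so most pixels have positive first coordinate
    if np.median(X @ plane[0]) < 0:
        plane = -plane
    proj = X @ plane.T                         # (N, 2)
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(ang, [1, 99])
    cols = []
    for a in (lo, hi):
        v = np.cos(a) * plane[0] + np.sin(a) * plane[1]
        if v.sum() < 0:
            v = -v
        v = np.maximum(v, 0.0)
        n = np.linalg.norm(v)
        cols.append(v / n if n > 1e-12 else np.ones(3) / np.sqrt(3.0))
    S = np.stack(cols, axis=1)
    return S[:, :n_stains]


def _order_columns(S: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # hematoxylin (more blue-absorbing) first: descending blue-channel OD
    order = np.argsort(-S[2, :], kind="stable")
    return S[:, order], C[:, order]


def _dictionary_update(S: np.ndarray, C: np.ndarray, X: np.ndarray) -> np.ndarray:
    # projected block coordinate descent on {s >= 0, ||s|| <= 1}; each block
    # update does not increase the quadratic objective in S
    A = C.T @ C
    B = X.T @ C
    for k in range(S.shape[1]):
        sk = S[:, k] + (B[:, k] - S @ A[:, k]) / max(A[k, k], 1e-12)
        sk = np.maximum(sk, 0.0)
        nrm = np.linalg.norm(sk)
        if nrm > 1.0:
            sk = sk / nrm
        elif nrm < 1e-12:
            sk = S[:, k]
        S[:, k] = sk
    return S


def estimate_stains(od_pixels: np.ndarray, n_stains: int = 2,
                    sparsity: float = 0.1, max_iter: int = 200,
                    tol: float = 1e-7, polish_iter: int = 10) -> StainModel:
    """Estimate the stain matrix from non-background OD pixels.

    Alternates the exact concentration step with a projected dictionary
    update; the objective is non-increasing across alternations and the loop
    stops when its relative decrease falls below ``tol``.  Column norms are
    constrained to the unit ball during optimization (the sparsity penalty
    pushes them onto the unit sphere) and normalized exactly at the end.
    The L1 shrinkage slightly biases the fitted columns toward the data
    mass, so the sparse solution is debiased by ``polish_iter`` penalty-free
    alternations before the final normalization.
    """
    X = np.asarray(od_pixels, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("od_pixels must have shape (n_pixels, 3)")
    if X.shape[0] < n_stains:
        raise ValueError("fewer usable pixels than stains")

    S = _extreme_angle_init(X, n_stains)
    C = _nn_lasso_2(X, S, sparsity)
    history = [_objective(X, C, S, sparsity)]
    for _ in range(max_iter):
        S = _dictionary_update(S, C, X)
        C = _nn_lasso_2(X, S, sparsity, C0=C)
        history.append(_objective(X, C, S, sparsity))
        if history[-2] - history[-1] <= tol * max(history[-2], 1e-12):
            break
    else:
        warnings.warn("stain estimation did not converge; returning best iterate")

    for _ in range(polish_iter):
        C = _nn_lasso_2(X, S, 0.0, C0=C)
        S = _dictionary_update(S, C, X)
    C = _nn_lasso_2(X, S, 0.0, C0=C)

    norms = np.linalg.norm(S, axis=0)
    norms[norms < 1e-12] = 1.0
    S = S / norms
    C = C * norms
    S, C = _order_columns(S, C)
    p99 = np.percentile(C, 99, axis=0)
    return StainModel(S=S, p99=p99, objective_history=history)


def concentrations(od_pixels: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel nonnegative least-squares stain concentrations.

    Exact for two stains via the active-set cases; returns (C, residual_norm).
    """
    X = np.atleast_2d(np.asarray(od_pixels, dtype=np.float64))
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[1]
    G = S.T @ S
    B = X @ S
    if n != 2:
        raise ValueError("concentrations supports two stains")
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    C = np.empty((X.shape[0], 2))
    if det > 1e-15:
        C[:, 0] = (G[1, 1] * B[:, 0] - G[0, 1] * B[:, 1]) / det
        C[:, 1] = (G[0, 0] * B[:, 1] - G[0, 1] * B[:, 0]) / det
    else:
        C[:] = 0.0
    bad = (C[:, 0] < 0) | (C[:, 1] < 0) | (det <= 1e-15)
    if np.any(bad):
        # best single-stain fits for pixels where the joint solution is infeasible
        c0 = np.maximum(B[bad, 0] / max(G[0, 0], 1e-15), 0.0)
        c1 = np.maximum(B[bad, 1] / max(G[1, 1], 1e-15), 0.0)
        r0 = -2 * c0 * B[bad, 0] + c0 * c0 * G[0, 0]
        r1 = -2 * c1 * B[bad, 1] + c1 * c1 * G[1, 1]
        use0 = r0 <= r1
        Cb = np.zeros((int(bad.sum()), 2))
        Cb[use0, 0] = c0[use0]
        Cb[~use0, 1] = c1[~use0]
        C[bad] = Cb
    resid = np.linalg.norm(X - C @ S.T, axis=1)
    return C, resid


def fit_stain_model(image: np.ndarray, I0: float = 255.0,
                    sparsity: float = 0.1,
                    od_floor: float = OD_BACKGROUND_FLOOR) -> StainModel:
    """Fit a StainModel on an RGB image, excluding background pixels
    (OD norm below ``od_floor``) from the estimation."""
    od = rgb_to_od(image, I0).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) >= od_floor]
    if tissue.shape[0] < 2:
        raise ValueError("too few non-background pixels to estimate stains")
    return estimate_stains(tissue, sparsity=sparsity)


def normalize(image: np.ndarray, target: StainModel,
              source: StainModel | None = None, I0: float = 255.0) -> np.ndarray:
    """Map an image to the target stain basis.

    Source concentrations are rescaled per stain by target.p99 / source.p99
    and reconstructed with the target stain matrix.  Degenerate sources (a
    stain with p99 = 0) pass the image through with a warning.
    """
    image = np.asarray(image)
    if source is None:
        source = fit_stain_model(image, I0=I0)
    if np.any(source.p99 <= 1e-9):
        warnings.warn("degenerate source stain model (p99 = 0); passing through")
        return image.copy()
    h, w = image.shape[:2]
    od = rgb_to_od(image, I0).reshape(-1, 3)
    C, _ = concentrations(od, source.S)
    C = C * (target.p99 / source.p99)
    od_new = C @ target.S.T
    return od_to_rgb(od_new.reshape(h, w, 3), I0)
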
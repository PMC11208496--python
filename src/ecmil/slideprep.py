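"""Tile-grid planning, mask filtering and tumor-patch selection.

Region images (pre-exported from whole-slide images) are tiled into
fixed-size patches; a binary tissue/tumor mask restricts the grid; a
pluggable patch scorer assigns each patch a tumor probability; and the
selection rules keep patches scoring at least the probability threshold
(default 0.90) with an optional cap of 200 randomly sampled patches for
training extraction.  Tiling itself is purely deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "TileGrid",
    "PatchScore",
    "PatchScorer",
    "IntensityGradientScorer",
    "plan_tiles",
    "filter_by_mask",
    "extract_patches",
    "score_patches",
    "select_tumor_patches",
    "cap_patches",
    "write_tile_manifest",
]


@dataclass
class TileGrid:
    """Top-left tile anchors over an image, row-major, fully inside bounds.

    Coordinates are 0-based half-open pixel intervals: a tile anchored at
    (x, y) covers columns [x, x+patch_size) and rows [y, y+patch_size).
    """

    width: int
    height: int
    patch_size: int
    overlap: float
    positions: list[tuple[int, int]]
    magnification_tag: str = "20x"

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PatchScore:
    position: tuple[int, int]
    tumor_probability: float


class PatchScorer(Protocol):
    def predict_probability(self, patch: np.ndarray) -> float: ...


def _axis_anchors(dim: int, patch_size: int, stride: int) -> list[int]:
    anchors = list(range(0, dim - patch_size + 1, stride))
    last = dim - patch_size
    if anchors[-1] != last:
        anchors.append(last)
    return anchors


def plan_tiles(width: int, height: int, patch_size: int = 512,
               overlap: float = 0.6, magnification_tag: str = "20x") -> TileGrid:
    """Plan the tile grid with stride floor(patch_size * (1 - overlap)).

    The boundary-anchored final position (dim - patch_size) is appended per
    axis when the stride does not land on it, so the grid covers the full
    image.  Flooring the stride guarantees the realized overlap is at least
    the requested one.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if patch_size < 1:
        raise ValueError("patch_size must be positive")
    if width < patch_size or height < patch_size:
        raise ValueError("image too small to tile")
    stride = max(int(patch_size * (1.0 - overlap)), 1)
    xs = _axis_anchors(width, patch_size, stride)
    ys = _axis_anchors(height, patch_size, stride)
    positions = [(x, y) for y in ys for x in xs]
    return TileGrid(width=width, height=height, patch_size=patch_size,
                    overlap=overlap, positions=positions,
                    magnification_tag=magnification_tag)


def filter_by_mask(grid: TileGrid, mask: np.ndarray,
                   min_inside_fraction: float) -> TileGrid:
    """Keep tiles whose fraction of positive mask pixels is >= the floor."""
    mask = np.asarray(mask)
    if mask.shape != (grid.height, grid.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match image "
            f"({grid.height}, {grid.width})"
        )
    # integral image for O(1) per-tile sums
    ii = np.zeros((grid.height + 1, grid.width + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask > 0, axis=0), axis=1)
    p = grid.patch_size
    area = float(p * p)
    kept = []
    for (x, y) in grid.positions:
        s = ii[y + p, x + p] - ii[y, x + p] - ii[y + p, x] + ii[y, x]
        if s / area >= min_inside_fraction:
            kept.append((x, y))
    return TileGrid(width=grid.width, height=grid.height, patch_size=p,
                    overlap=grid.overlap, positions=kept,
                    magnification_tag=grid.magnification_tag)


def extract_patches(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Crop the grid's tiles out of the image (views, not copies)."""
    image = np.asarray(image)
    p = grid.patch_size
    return [image[y:y + p, x:x + p] for (x, y) in grid.positions]


def score_patches(scorer: PatchScorer, patches: Sequence[np.ndarray],
                  positions: Sequence[tuple[int, int]] | None = None) -> list[PatchScore]:
    """One tumor-probability score per patch, order preserved."""
    if positions is None:
        positions = [(0, 0)] * len(patches)
    if len(positions) != len(patches):
        raise ValueError("positions/patches length mismatch")
    out = []
    for pos, patch in zip(positions, patches):
        p = float(scorer.predict_probability(patch))
        if not np.isfinite(p) or not 0.0 <= p <= 1.0:
            raise ValueError(f"scorer returned invalid probability {p!r}")
        out.append(PatchScore(position=tuple(pos), tumor_probability=p))
    return out


def select_tumor_patches(scores: Sequence[PatchScore],
                         threshold: float = 0.90) -> list[tuple[int, int]]:
    """Positions with tumor probability >= threshold (inclusive), stable order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [s.position for s in scores if s.tumor_probability >= threshold]


def cap_patches(positions: Sequence[tuple[int, int]], max_n: int = 200,
                rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Uniform random subset of at most max_n positions (training extraction
    cap); input order is preserved among the kept positions."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    positions = list(positions)
    if len(positions) <= max_n:
        return positions
    if rng is None:
        rng = np.random.default_rng()
    idx = np.sort(rng.choice(len(positions), size=max_n, replace=False))
    return [positions[i] for i in idx]


def write_tile_manifest(slide_id: str, scores: Sequence[PatchScore],
                        selected: Sequence[tuple[int, int]],
                        path: str | Path) -> pd.DataFrame:
    sel = set(map(tuple, selected))
    df = pd.DataFrame({
        "slide_id": slide_id,
        "x": [s.position[0] for s in scores],
        "y": [s.position[1] for s in scores],
        "tumor_probability": [s.tumor_probability for s in scores],
        "selected_flag": [int(s.position in sel) for s in scores],
    })
    df.to_csv(path, sep="\t", index=False)
    return df


class IntensityGradientScorer:
    """Reference tumor/stroma patch scorer.

    Logistic regression on per-channel intensity and gradient summaries —
    a lightweight stand-in for a CNN tumor classifier, adequate for the
    texture-separable fixtures used in tests and demos.
    """

    def __init__(self, C: float = 1.0):
        self._clf = LogisticRegression(C=C, max_iter=1000)
        self._fitted = False

    @staticmethod
    def _features(patch: np.ndarray) -> np.ndarray:
        img = np.asarray(patch, dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        feats = []
        for ch in range(img.shape[2]):
            x = img[..., ch]
            gy, gx = np.gradient(x)
            feats += [x.mean(), x.std(), np.abs(gx).mean(), np.abs(gy).mean()]
        return np.asarray(feats)

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[int]) -> "IntensityGradientScorer":
        X = np.stack([self._features(p) for p in patches])
        self._clf.fit(X, np.asarray(labels, dtype=int))
        self._fitted = True
        return self

    def predict_probability(self, patch: np.ndarray) -> float:
        if not self._fitted:
            raise RuntimeError("scorer must be fitted first")
        X = self._features(patch)[None, :]
        return float(self._clf.predict_proba(X)[0, 1])
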
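"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive re-implementations (flood fill,
per-row run-length scans, rank-sum formulas) kept independent of the
library code paths they check.
"""

from __future__ import annotations

from itertools import groupby

import numpy as np
import pandas as pd
import pytest

from lungquant.morphometry import CalibratedImage
from lungquant.synthetic_data import AIRSPACE_RGB, TISSUE_RGB


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def rle_chords(mask: np.ndarray) -> list[int]:
    """Run-length chord oracle: maximal horizontal airspace runs per row."""
    lengths = []
    for row in np.asarray(mask, dtype=bool):
        for val, run in groupby(row):
            if val:
                lengths.append(sum(1 for _ in run))
    return lengths


def brute_transitions(mask: np.ndarray, rows: np.ndarray) -> int:
    """Pixel-by-pixel airspace-to-tissue transition count along given rows."""
    m = np.asarray(mask, dtype=bool)
    n = 0
    for y in rows:
        for x in range(m.shape[1] - 1):
            if m[y, x] and not m[y, x + 1]:
                n += 1
    return n


def flood_fill_filter(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Area filter oracle: iterative 8-connected flood fill per component."""
    m = np.asarray(mask, dtype=bool).copy()
    seen = np.zeros_like(m)
    H, W = m.shape
    out = m.copy()
    for sy in range(H):
        for sx in range(W):
            if not m[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            comp = []
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and m[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            if len(comp) < min_area:
                for y, x in comp:
                    out[y, x] = False
    return out


def kruskal_oracle(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook rank formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1  # mid-rank, 1-based
        i = j
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return H / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Image helpers
# ---------------------------------------------------------------------------

def mask_to_image(mask: np.ndarray, px_per_micron: float = 2.764) -> CalibratedImage:
    """Render a binary mask as a clean two-tone white/pink image."""
    m = np.asarray(mask, dtype=bool)
    img = np.empty((*m.shape, 3), dtype=np.uint8)
    img[:] = TISSUE_RGB
    img[m] = AIRSPACE_RGB
    return CalibratedImage(pixels=img, px_per_micron=px_per_micron)


def stripe_mask(height: int, width: int, air: int, tissue: int) -> np.ndarray:
    """Vertical stripes: ``air`` airspace columns then ``tissue`` tissue ones."""
    col = (np.arange(width) % (air + tissue)) < air
    return np.tile(col, (height, 1))


@pytest.fixture(scope="session")
def random_masks() -> list[np.ndarray]:
    """A batch of small random blob/speckle masks for oracle fuzzing."""
    rng = np.random.default_rng(2024)
    masks = []
    for _ in range(30):
        m = rng.random((40, 60)) < rng.uniform(0.2, 0.7)
        masks.append(m)
    return masks


@pytest.fixture(scope="session")
def factorial_frame():
    """Balanced 2x2 noise frame builder."""

    def build(cell_means: dict[tuple[str, str], float], n: int,
              noise_sd: float, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        rows = []
        for (diet, smoke), mu in cell_means.items():
            for _ in range(n):
                rows.append({"diet": diet, "smoke": smoke,
                             "group": f"{diet}-{smoke}",
                             "value": mu + rng.normal(0.0, noise_sd) if noise_sd else mu})
        return pd.DataFrame(rows)

    return build
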
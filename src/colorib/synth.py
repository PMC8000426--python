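"""Synthetic palettes and naming systems.

The default grid palette is a stand-in for the World Color Survey stimulus
set: 330 chips arranged as 40 equally spaced hues x 8 equally spaced
lightness rows on a hue circle of fixed chroma, plus 10 achromatic chips on
the lightness axis.  Keeping |U| = 330 means constants tied to the chip
count (the log2 330 complexity ceiling, percentile grids over the 54,285
pairwise distances) carry over unchanged.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .naming import NamingSystem
from .palette import Palette

__all__ = [
    "SyntheticPaletteSpec",
    "SyntheticNamingSpec",
    "make_grid_palette",
    "make_blob_palette",
    "make_synthetic_naming",
    "wcs_standin_palette",
]


@dataclass
class SyntheticPaletteSpec:
    """Hue x lightness grid layout in CIELAB.

    ``n_hues`` columns at equally spaced hue angles and chroma ``chroma``;
    ``n_lightness`` rows with L* equally spaced over ``lightness_range``;
    ``n_achromatic`` extra chips on the L* axis (a = b = 0); optional
    isotropic Gaussian jitter of ``jitter_sd`` CIELAB units.

    The hue circle is displaced ``center_offset`` units along +a*: in
    CIELAB the maximum-saturation hue ring is strongly off-center, and the
    displacement reproduces the asymmetry that lets the discrimination
    game be played at distance percentiles up to 80 (but not beyond) on
    the real 330-chip set — on a centered ring the gray mid-lightness
    chips would run out of far-enough distractors at much lower
    percentiles.
    """

    n_hues: int = 40
    n_lightness: int = 8
    chroma: float = 40.0
    center_offset: float = 32.0
    lightness_range: tuple = (20.0, 90.0)
    n_achromatic: int = 10
    achromatic_range: tuple = (10.0, 96.0)
    jitter_sd: float = 0.0
    seed: int = 0


@dataclass
class SyntheticNamingSpec:
    """Centroid-based naming: ``n_words`` seeded farthest-point centroids;
    ``softness`` is the Gaussian bandwidth of the memberships in CIELAB
    units (0 gives a hard nearest-centroid partition)."""

    n_words: int
    softness: float = 0.0
    seed: int = 0


def make_grid_palette(spec: SyntheticPaletteSpec) -> Palette:
    """Build the hue x lightness grid palette described by ``spec``."""
    if spec.n_hues < 2 or spec.n_lightness < 1:
        raise ValueError("need n_hues >= 2 and n_lightness >= 1")
    if spec.chroma <= 0:
        raise ValueError("chroma must be positive")
    if spec.jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")

    lo, hi = spec.lightness_range
    Ls = np.linspace(hi, lo, spec.n_lightness)  # rows ordered light to dark
    theta = 2 * np.pi * np.arange(spec.n_hues) / spec.n_hues
    row_labels = list(string.ascii_uppercase)

    coords, rows, cols = [], [], []
    for k in range(spec.n_achromatic):
        alo, ahi = spec.achromatic_range
        L = ahi - (ahi - alo) * k / max(spec.n_achromatic - 1, 1)
        coords.append([L, 0.0, 0.0])
        rows.append(row_labels[0])
        cols.append(0)
    for r in range(spec.n_lightness):
        for h in range(spec.n_hues):
            coords.append(
                [Ls[r],
                 spec.center_offset + spec.chroma * np.cos(theta[h]),
                 spec.chroma * np.sin(theta[h])]
            )
            rows.append(row_labels[(r + 1) % len(row_labels)])
            cols.append(h + 1)
    coords = np.asarray(coords)
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.jitter_sd, size=coords.shape)
    n = len(coords)
    return Palette(
        chip_ids=np.arange(1, n + 1),
        rows=rows,
        cols=np.asarray(cols),
        coords=coords,
        prior=np.full(n, 1.0 / n),
        meta={"kind": "grid", "spec": spec},
    )


def wcs_standin_palette(jitter_sd: float = 0.0, seed: int = 0) -> Palette:
    """The default 330-chip synthetic palette (40 hues x 8 rows + 10 grays)."""
    return make_grid_palette(SyntheticPaletteSpec(jitter_sd=jitter_sd, seed=seed))


def make_blob_palette(
    k_blobs: int, n_per_blob: int, separation: float, sd: float, seed: int = 0
) -> Palette:
    """Gaussian clusters of chips in 3-space, blob labels kept as metadata.

    Centroids sit ``separation`` apart along a line; each blob is an
    isotropic Gaussian of scale ``sd``.  Used for recovery tests and for
    fast, easily solvable communication games.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if k_blobs < 1 or n_per_blob < 1:
        raise ValueError("k_blobs and n_per_blob must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k_blobs, 3))
    centers[:, 0] = separation * np.arange(k_blobs)
    coords = np.concatenate(
        [rng.normal(c, sd, size=(n_per_blob, 3)) for c in centers]
    )
    labels = np.repeat(np.arange(k_blobs), n_per_blob)
    n = k_blobs * n_per_blob
    return Palette(
        chip_ids=np.arange(1, n + 1),
        rows=["A"] * n,
        cols=np.arange(n),
        coords=coords,
        prior=np.full(n, 1.0 / n),
        meta={"kind": "blobs", "blob_labels": labels, "blob_centers": centers},
    )


def farthest_point_centroids(palette: Palette, k: int, rng: np.random.Generator):
    """Greedy farthest-point selection of ``k`` chip indices (seeded start)."""
    n = palette.n_chips
    first = int(rng.integers(n))
    chosen = [first]
    mind = palette.dist[first].copy()
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, palette.dist[nxt])
    return np.asarray(chosen)


def make_synthetic_naming(palette: Palette, spec: SyntheticNamingSpec) -> NamingSystem:
    """Gaussian-membership naming around farthest-point centroid chips."""
    if spec.softness < 0:
        raise ValueError("softness must be >= 0")
    if not 1 <= spec.n_words <= palette.n_chips:
        raise ValueError("need 1 <= n_words <= n_chips")
    rng = np.random.default_rng(spec.seed)
    centroids = farthest_point_centroids(palette, spec.n_words, rng)
    d = palette.dist[:, centroids]  # (n_chips, n_words)
    if 2 * spec.softness ** 2 == 0.0:  # includes subnormal softness
        enc = np.zeros_like(d)
        enc[np.arange(palette.n_chips), np.argmin(d, axis=1)] = 1.0
    else:
        logits = -(d ** 2) / (2 * spec.softness ** 2)
        logits -= logits.max(axis=1, keepdims=True)
        enc = np.exp(logits)
        enc /= enc.sum(axis=1, keepdims=True)
    return NamingSystem(
        list(range(spec.n_words)), enc, provenance="synthetic",
        meta={"centroid_chips": centroids},
    )
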
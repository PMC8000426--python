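"""Color palettes and World-Color-Survey-style file IO.

A palette is the universe U of the communication model: a finite set of
color chips embedded in CIELAB space, with a prior p(c) over chips and the
matrix of pairwise Euclidean distances (which approximate perceptual
dissimilarity in CIELAB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .naming import NamingSystem

__all__ = [
    "ColorChip",
    "Palette",
    "HumanNamingData",
    "load_wcs_palette",
    "load_wcs_naming",
    "write_palette_csv",
    "write_naming_csv",
    "read_naming_csv",
]

WCS_N_CHIPS = 330


@dataclass(frozen=True)
class ColorChip:
    chip_id: int
    lightness_row: str
    hue_col: int
    coord: tuple  # (L*, a*, b*)


@dataclass
class Palette:
    """The universe of chips, ordered by ascending chip id.

    ``coords`` is ``(n, 3)`` CIELAB; ``prior`` sums to 1; ``dist`` is the
    symmetric matrix of pairwise Euclidean CIELAB distances.
    """

    chip_ids: np.ndarray
    rows: list
    cols: np.ndarray
    coords: np.ndarray
    prior: np.ndarray
    dist: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chip_ids = np.asarray(self.chip_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("chip coordinates must be finite")
        if len(np.unique(self.chip_ids)) != len(self.chip_ids):
            raise ValueError("chip ids must be unique")
        if self.dist is None:
            self.dist = squareform(pdist(self.coords))
        self.prior = np.asarray(self.prior, dtype=float)
        if np.any(self.prior < 0) or abs(self.prior.sum() - 1.0) > 1e-12:
            raise ValueError("prior must be nonnegative and sum to 1")
        if not np.allclose(self.dist, self.dist.T, atol=1e-12):
            raise ValueError("dist must be symmetric")

    @property
    def n_chips(self) -> int:
        return len(self.chip_ids)

    @property
    def chips(self) -> list:
        return [
            ColorChip(int(i), r, int(c), tuple(x))
            for i, r, c, x in zip(self.chip_ids, self.rows, self.cols, self.coords)
        ]

    def pairwise_distances(self) -> np.ndarray:
        """The n(n-1)/2 distances over unordered pairs of distinct chips."""
        iu = np.triu_indices(self.n_chips, k=1)
        return self.dist[iu]


@dataclass
class HumanNamingData:
    """Per-language naming judgments aggregated over speakers."""

    language_id: str
    counts: pd.DataFrame  # index chip_id, columns term, values judgment counts
    naming: NamingSystem


def _read_table(path, column_map, n_cols_min):
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < n_cols_min:
        raise ValueError(f"{path}: expected at least {n_cols_min} columns, got {df.shape[1]}")
    return df.rename(columns={v: k for k, v in column_map.items()})


def load_wcs_palette(path, column_map=None, strict: bool = False) -> Palette:
    """Read a chip-coordinate table into a :class:`Palette`.

    The table has one row per chip: chip id, lightness row label, hue column
    index, L*, a*, b*.  Whitespace- or tab-separated; lines starting with
    ``#`` are comments.  ``column_map`` maps field names to 0-based column
    positions (defaults: id=0, row=1, col=2, L=3, a=4, b=5).

    The prior is uniform.  A chip count other than 330 warns, or raises when
    ``strict`` is set.
    """
    cmap = {"chip_id": 0, "row": 1, "col": 2, "L": 3, "a": 4, "b": 5}
    if column_map:
        cmap.update(column_map)
    df = _read_table(path, cmap, max(cmap.values()) + 1)
    try:
        ids = df["chip_id"].astype(int).to_numpy()
        coords = df[["L", "a", "b"]].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric chip id or coordinate: {exc}") from exc
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate chip ids")
    if len(ids) != WCS_N_CHIPS:
        msg = f"{path}: expected {WCS_N_CHIPS} chips, found {len(ids)}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    order = np.argsort(ids)
    n = len(ids)
    return Palette(
        chip_ids=ids[order],
        rows=[str(r) for r in df["row"].to_numpy()[order]],
        cols=df["col"].astype(int).to_numpy()[order],
        coords=coords[order],
        prior=np.full(n, 1.0 / n),
    )


def load_wcs_naming(path, palette: Palette, column_map=None):
    """Read a term table into per-language naming data.

    Rows are (language id, speaker id, chip id, term).  Per language, P(w|c)
    is the frequency of each (case-normalized) term among all speaker
    judgments for chip c.  Languages in which some chip was judged by a
    single speaker only (or not at all) are excluded, mirroring the sparse
    -data filter applied to the survey.

    Returns ``(retained, report)`` where ``retained`` is a list of
    :class:`HumanNamingData` and ``report`` a DataFrame with one row per
    input language and its exclusion reason (empty string if retained).
    """
    cmap = {"language": 0, "speaker": 1, "chip_id": 2, "term": 3}
    if column_map:
        cmap.update(column_map)
    df = _read_table(path, cmap, max(cmap.values()) + 1)
    if df.empty:
        raise ValueError(f"{path}: empty term table")
    df["chip_id"] = df["chip_id"].astype(int)
    df["term"] = df["term"].astype(str).str.strip().str.lower()
    known = set(int(i) for i in palette.chip_ids)
    bad = set(df["chip_id"]) - known
    if bad:
        raise ValueError(f"{path}: chip ids absent from palette: {sorted(bad)[:10]}")

    chip_order = [int(i) for i in palette.chip_ids]
    retained, rows = [], []
    for lang, sub in df.groupby("language", sort=True):
        counts = (
            sub.groupby(["chip_id", "term"]).size().unstack(fill_value=0)
        ).reindex(chip_order, fill_value=0)
        judgments = counts.sum(axis=1)
        if (judgments == 0).any():
            rows.append((lang, "missing chips"))
            continue
        if (judgments == 1).any():
            rows.append((lang, "single-judgment chips"))
            continue
        enc = counts.to_numpy(dtype=float)
        enc = enc / enc.sum(axis=1, keepdims=True)
        ns = NamingSystem(list(counts.columns), enc, provenance="human",
                          meta={"language_id": str(lang)})
        retained.append(HumanNamingData(str(lang), counts, ns))
        rows.append((lang, ""))
    report = pd.DataFrame(rows, columns=["language", "excluded_reason"])
    return retained, report


def write_palette_csv(palette: Palette, path) -> None:
    """Write a palette as a chip-coordinate table (readable by
    :func:`load_wcs_palette`)."""
    pd.DataFrame(
        {
            "chip_id": palette.chip_ids,
            "row": palette.rows,
            "col": palette.cols,
            "L": palette.coords[:, 0],
            "a": palette.coords[:, 1],
            "b": palette.coords[:, 2],
        }
    ).to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")


def write_naming_csv(ns: NamingSystem, palette: Palette, path) -> None:
    """Serialize a naming system as (chip_id, word_id, probability) rows.

    Zero-probability cells are omitted; the round trip through
    :func:`read_naming_csv` reproduces ``enc`` to 1e-12.
    """
    chip_col, word_col, prob = [], [], []
    for i, cid in enumerate(palette.chip_ids):
        for j, w in enumerate(ns.words):
            p = ns.enc[i, j]
            if p > 0:
                chip_col.append(int(cid))
                word_col.append(w)
                prob.append(p)
    pd.DataFrame(
        {"chip_id": chip_col, "word_id": word_col, "probability": prob}
    ).to_csv(path, index=False, float_format="%.17g")


def read_naming_csv(path, palette: Palette, provenance: str = "synthetic") -> NamingSystem:
    df = pd.read_csv(path)
    words = sorted(df["word_id"].unique(), key=str)
    widx = {w: j for j, w in enumerate(words)}
    cidx = {int(c): i for i, c in enumerate(palette.chip_ids)}
    enc = np.zeros((palette.n_chips, len(words)))
    for cid, w, p in zip(df["chip_id"], df["word_id"], df["probability"]):
        try:
            i = cidx[int(cid)]
        except KeyError:
            raise ValueError(f"{path}: chip id {cid} absent from palette") from None
        enc[i, widx[w]] += float(p)
    sums = enc.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"{path}: per-chip probabilities do not sum to 1")
    return NamingSystem(list(words), enc / sums[:, None], provenance=provenance)
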
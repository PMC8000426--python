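"""The color-discrimination game: round sampling and the discriminative-need
constraint.

A round draws a target chip from the palette prior and one distractor drawn
uniformly among chips at CIELAB distance >= a threshold from the target.
The threshold is a percentile of the pairwise-distance distribution over
distinct chips; higher percentiles demand less granular discrimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .palette import Palette

__all__ = [
    "GameConfig",
    "Round",
    "distance_threshold",
    "valid_distractor_sets",
    "sample_round",
    "sample_rounds",
    "enumerate_valid_rounds",
]


@dataclass
class GameConfig:
    percentile: float = 50.0
    vocab_size: int = 1024
    seed: int = 0
    drop_isolated_targets: bool = False
    n_distractors: int = 1  # the game always shows 2 candidates

    def __post_init__(self) -> None:
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must lie in [0, 100]")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if self.n_distractors != 1:
            raise ValueError("only 1 distractor (2 candidates) is supported")


@dataclass(frozen=True)
class Round:
    target: int
    distractor: int
    target_position: int  # 0 or 1


def distance_threshold(palette: Palette, percentile: float) -> float:
    """Nearest-rank percentile of the pairwise chip-distance distribution.

    The list ranked is the n(n-1)/2 distances over unordered pairs of
    distinct chips; percentile 50 returns the median, percentile 0 the
    minimum.  Distractors are then required to sit at distance >= this
    threshold from the target (inclusive).
    """
    if palette.n_chips < 2:
        raise ValueError("need at least 2 chips")
    d = np.sort(palette.pairwise_distances())
    rank = max(1, math.ceil(percentile / 100.0 * d.size))
    return float(d[rank - 1])


def valid_distractor_sets(palette: Palette, threshold: float, *, on_empty: str = "raise"):
    """Per-target index arrays {j != i : dist(i, j) >= threshold}.

    ``on_empty`` controls what happens when some target has no valid
    distractor: ``"raise"`` (default) or ``"report"`` (return them).
    Returns ``(sets, empty_targets)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ok = palette.dist >= threshold
    np.fill_diagonal(ok, False)
    sets = [np.flatnonzero(row) for row in ok]
    empty = np.flatnonzero([s.size == 0 for s in sets])
    if empty.size and on_empty == "raise":
        raise ValueError(
            f"{empty.size} target chip(s) have no distractor at distance >= "
            f"{threshold:g}; lower the percentile or set drop_isolated_targets"
        )
    return sets, empty


def _effective_prior(palette: Palette, sets, empty, drop_isolated: bool):
    prior = palette.prior.copy()
    if empty.size:
        if not drop_isolated:
            raise ValueError("isolated targets present; enable drop_isolated_targets")
        prior[empty] = 0.0
        prior = prior / prior.sum()
    return prior


def sample_round(palette: Palette, threshold: float, rng: np.random.Generator,
                 sets=None, drop_isolated_targets: bool = False) -> Round:
    """Draw one round: target ~ prior, distractor uniform over the valid
    set, target position uniform over the two slots."""
    if sets is None:
        sets, empty = valid_distractor_sets(
            palette, threshold, on_empty="report" if drop_isolated_targets else "raise"
        )
    else:
        empty = np.flatnonzero([s.size == 0 for s in sets])
    prior = _effective_prior(palette, sets, empty, drop_isolated_targets)
    t = int(rng.choice(palette.n_chips, p=prior))
    d = int(rng.choice(sets[t]))
    pos = int(rng.integers(2))
    return Round(t, d, pos)


def sample_rounds(palette: Palette, threshold: float, n: int, rng: np.random.Generator,
                  sets=None, drop_isolated_targets: bool = False):
    """Vectorized batch of rounds; returns (targets, distractors, positions)."""
    if sets is None:
        sets, empty = valid_distractor_sets(
            palette, threshold, on_empty="report" if drop_isolated_targets else "raise"
        )
    else:
        empty = np.flatnonzero([s.size == 0 for s in sets])
    prior = _effective_prior(palette, sets, empty, drop_isolated_targets)
    targets = rng.choice(palette.n_chips, size=n, p=prior)
    sizes = np.array([s.size for s in sets])
    picks = rng.random(n)
    distractors = np.array(
        [sets[t][int(u * sizes[t])] for t, u in zip(targets, picks)]
    )
    positions = rng.integers(2, size=n)
    return targets, distractors, positions


def enumerate_valid_rounds(palette: Palette, threshold: float,
                           drop_isolated_targets: bool = False):
    """All ordered (target, distractor) pairs with their sampling weights.

    The weight of (i, j) is prior(i) / |valid(i)|; weights sum to 1.  Used
    for exact (Monte-Carlo-free) evaluation of success rates.
    """
    sets, empty = valid_distractor_sets(
        palette, threshold, on_empty="report" if drop_isolated_targets else "raise"
    )
    prior = _effective_prior(palette, sets, empty, drop_isolated_targets)
    pairs, weights = [], []
    for i, s in enumerate(sets):
        if prior[i] == 0 or s.size == 0:
            continue
        w = prior[i] / s.size
        for j in s:
            pairs.append((i, int(j)))
            weights.append(w)
    return np.asarray(pairs, dtype=int), np.asarray(weights)
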
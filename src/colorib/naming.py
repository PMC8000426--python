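"""Naming systems: conditional distributions P(word | chip).

A naming system (encoder) maps each color chip to a distribution over a
finite set of words.  It is the central object scored on the information
plane: its complexity is I(M;W) and its accuracy I(U;W).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NamingSystem"]

_ROW_TOL = 1e-9


@dataclass
class NamingSystem:
    """An encoder P(w|c) over ``n_chips`` chips and ``n_words`` words.

    Parameters
    ----------
    words
        Word identifiers, one per column of ``enc``.
    enc
        Array of shape ``(n_chips, n_words)``; each row is the distribution
        over words for one chip and must sum to 1.
    provenance
        Free-form tag describing where the system came from
        (``"nn"``, ``"fcm"``, ``"human"`` or ``"synthetic"``).
    """

    words: list
    enc: np.ndarray
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.enc = np.asarray(self.enc, dtype=float)
        if self.enc.ndim != 2:
            raise ValueError("enc must be a 2-D (chips x words) array")
        if len(self.words) != self.enc.shape[1]:
            raise ValueError("len(words) must match enc.shape[1]")
        if np.any(self.enc < -_ROW_TOL):
            raise ValueError("enc entries must be nonnegative")
        rows = self.enc.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise ValueError("each chip's word distribution must sum to 1")

    @property
    def n_chips(self) -> int:
        return self.enc.shape[0]

    @property
    def n_words(self) -> int:
        return self.enc.shape[1]

    def word_marginal(self, prior: np.ndarray) -> np.ndarray:
        """P(w) under a chip prior."""
        return prior @ self.enc

    def pruned(self, prior: np.ndarray, eps: float = 1e-12) -> "NamingSystem":
        """Drop words whose marginal probability under ``prior`` is < ``eps``."""
        keep = self.word_marginal(prior) >= eps
        if keep.all():
            return self
        enc = self.enc[:, keep]
        enc = enc / enc.sum(axis=1, keepdims=True)
        return NamingSystem(
            [w for w, k in zip(self.words, keep) if k],
            enc,
            provenance=self.provenance,
            meta=dict(self.meta),
        )

    def relabeled(self) -> "NamingSystem":
        """Relabel words 0..K-1 in order of first use across chips.

        Label choice never affects complexity, accuracy or inefficiency;
        this is purely cosmetic normalization for serialization.
        """
        first_chip = np.array([np.argmax(self.enc[:, j] > 0) for j in range(self.n_words)])
        order = np.lexsort((np.arange(self.n_words), first_chip))
        return NamingSystem(
            list(range(self.n_words)),
            self.enc[:, order],
            provenance=self.provenance,
            meta=dict(self.meta),
        )
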
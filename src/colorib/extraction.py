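"""Turn trained Speakers into scoreable naming systems.

The default estimator mirrors how fuzzy naming is measured after training:
for each chip, 25 words are sampled with replacement from the Speaker's
categorical output, and P(w|c) is the empirical frequency table.  A Dirac
speaker therefore yields exactly one word per chip; a maximally uncertain
one up to 25 distinct words.  The exact-softmax alternative exists to
quantify the finite-sample bias of the sampled estimate.
"""

from __future__ import annotations

import numpy as np

from .agents import SpeakerParams, speaker_probs
from .naming import NamingSystem
from .palette import Palette

__all__ = ["extract_naming", "naming_from_probs", "effective_vocab"]


def extract_naming(sp: SpeakerParams, palette: Palette, n_samples: int = 25,
                   rng: np.random.Generator | None = None) -> NamingSystem:
    """Empirical P(w|c) from ``n_samples`` draws per chip (default 25).

    Unused vocabulary entries are dropped and word ids relabeled
    contiguously in order of first use; all probabilities are multiples of
    ``1/n_samples``.
    """
    rng = rng or np.random.default_rng()
    probs = speaker_probs(sp, palette.coords)
    counts = np.stack([rng.multinomial(n_samples, p / p.sum()) for p in probs])
    used = counts.sum(axis=0) > 0
    enc = counts[:, used].astype(float) / n_samples
    ns = NamingSystem(list(np.flatnonzero(used)), enc, provenance="nn",
                      meta={"n_samples": n_samples})
    return ns.relabeled()


def naming_from_probs(sp: SpeakerParams, palette: Palette,
                      prune_eps: float = 1e-12) -> NamingSystem:
    """Exact softmax outputs as the naming system (words below
    ``prune_eps`` total mass pruned)."""
    probs = speaker_probs(sp, palette.coords)
    keep = probs.max(axis=0) >= prune_eps
    enc = probs[:, keep]
    enc = enc / enc.sum(axis=1, keepdims=True)
    return NamingSystem(list(np.flatnonzero(keep)), enc, provenance="nn",
                        meta={"exact": True})


def effective_vocab(ns: NamingSystem, prior: np.ndarray | None = None) -> int:
    """Number of words actually in use (nonzero marginal)."""
    if prior is None:
        marg = ns.enc.sum(axis=0)
    else:
        marg = ns.word_marginal(prior)
    return int(np.count_nonzero(marg > 0))
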
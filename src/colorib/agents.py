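"""Speaker/Listener agents and the two training regimes.

The Speaker is a feed-forward network mapping a (scaled) CIELAB coordinate
to a categorical distribution over a fixed vocabulary; the Listener embeds
the received word and scores each candidate chip by the inner product of
the word embedding with a linear projection of the chip's coordinate.

Two gradient estimators train the Speaker through the discrete channel:

* Gumbel-Softmax (GS): at training time the message is the relaxed sample
  y = softmax((g + log p) / tau) with g ~ Gumbel(0,1) i.i.d., which makes
  the whole pipeline differentiable; at evaluation the channel is fully
  discrete (argmax word).
* REINFORCE (RF): words are sampled discretely throughout; the Speaker
  gets the score-function gradient with a running-mean baseline and an
  entropy bonus, the Listener ordinary backprop.

Gradients feed Adam.  Everything is plain numpy: the networks are small and
the whole run is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import GameConfig, distance_threshold, enumerate_valid_rounds, \
    sample_rounds, valid_distractor_sets
from .palette import Palette

__all__ = [
    "SpeakerParams",
    "ListenerParams",
    "TrainConfig",
    "TrainRun",
    "init_speaker",
    "init_listener",
    "speaker_probs",
    "gs_sample",
    "listener_position_dist",
    "game_loss",
    "reinforce_speaker_grad",
    "train",
    "success_rate",
]

_LEAK = 0.01
_LOG_CLAMP = 1e-20
COORD_SCALE = 100.0  # CIELAB coordinates are divided by this before the net


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class SpeakerParams:
    """Weights of the Speaker MLP: 3 -> hidden^depth -> vocab logits,
    leaky-ReLU activations (hidden width/depth configurable for capacity
    sweeps; defaults follow the reference architecture)."""

    weights: list  # [(W, b), ...] including the output layer
    vocab_size: int

    @property
    def hidden_sizes(self):
        return [W.shape[1] for W, _ in self.weights[:-1]]


@dataclass
class ListenerParams:
    """Listener: word-embedding table (vocab x dim) and a linear map from
    chip coordinates to the same dim; candidate scores are inner products."""

    embed: np.ndarray  # (vocab, dim)
    proj: np.ndarray   # (3, dim)


@dataclass
class TrainConfig:
    method: str = "gs"          # "gs" or "reinforce"
    tau: float = 1.0            # GS temperature
    batch_size: int = 1024
    learning_rate: float = 1e-3
    entropy_coeff: float = 0.01
    baseline_decay: float = 0.05  # EMA step for the running-mean baseline
    max_interactions: int = 10_000_000
    eval_every: int = 50        # batches between exact argmax evaluations
    plateau_evals: int = 3      # consecutive passing evals required to stop
    success_threshold: float = 0.95
    speaker_hidden: int = 1000
    speaker_depth: int = 3
    listener_dim: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("gs", "reinforce"):
            raise ValueError("method must be 'gs' or 'reinforce'")
        if self.method == "gs" and self.tau <= 0:
            raise ValueError("tau must be positive for GS")


@dataclass
class TrainRun:
    speaker: SpeakerParams
    listener: ListenerParams
    trajectory: list            # [(interactions, eval success, train loss), ...]
    converged: bool
    interactions: int
    config: TrainConfig
    game: GameConfig
    seed: int
    final_success: float = float("nan")


def init_speaker(vocab_size: int, hidden: int = 1000, depth: int = 3,
                 rng: np.random.Generator | None = None) -> SpeakerParams:
    rng = rng or np.random.default_rng()
    sizes = [3] + [hidden] * depth + [vocab_size]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        weights.append((W, np.zeros(fan_out)))
    return SpeakerParams(weights, vocab_size)


def init_listener(vocab_size: int, dim: int = 5,
                  rng: np.random.Generator | None = None) -> ListenerParams:
    rng = rng or np.random.default_rng()
    return ListenerParams(
        embed=rng.normal(0.0, 0.1, size=(vocab_size, dim)),
        proj=rng.normal(0.0, 0.1, size=(3, dim)),
    )


def _speaker_forward(sp: SpeakerParams, X: np.ndarray):
    """Forward pass on scaled coords X (B,3); returns (probs, cache)."""
    acts = [X]
    h = X
    for W, b in sp.weights[:-1]:
        z = h @ W + b
        h = np.where(z > 0, z, _LEAK * z)
        acts.append(h)
    W, b = sp.weights[-1]
    logits = h @ W + b
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite Speaker activations")
    return _softmax(logits), acts


def _speaker_backward(sp: SpeakerParams, acts, dlogits):
    """Gradients of all speaker weights given d(objective)/d(logits)."""
    grads = [None] * len(sp.weights)
    W, _ = sp.weights[-1]
    grads[-1] = (acts[-1].T @ dlogits, dlogits.sum(axis=0))
    dh = dlogits @ W.T
    for li in range(len(sp.weights) - 2, -1, -1):
        W, _ = sp.weights[li]
        h = acts[li + 1]
        dz = dh * np.where(h > 0, 1.0, _LEAK)
        grads[li] = (acts[li].T @ dz, dz.sum(axis=0))
        dh = dz @ W.T
    return grads


def speaker_probs(sp: SpeakerParams, coords: np.ndarray) -> np.ndarray:
    """Categorical word distribution(s) for raw CIELAB coordinate(s)."""
    X = np.atleast_2d(np.asarray(coords, dtype=float)) / COORD_SCALE
    p, _ = _speaker_forward(sp, X)
    return p[0] if np.asarray(coords).ndim == 1 else p


def gs_sample(p: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Gumbel-Softmax relaxed one-hot sample(s) from categorical p.

    y = softmax((g + log p) / tau), g ~ Gumbel(0,1).  As tau -> 0 samples
    approach one-hot vectors whose argmax follows p exactly (the Gumbel-max
    property); as tau -> inf they approach the uniform vector.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    p = np.asarray(p, dtype=float)
    g = rng.gumbel(size=p.shape)
    return _softmax((g + np.log(np.clip(p, _LOG_CLAMP, None))) / tau, axis=-1)


def listener_position_dist(lp: ListenerParams, message: np.ndarray,
                           candidates: np.ndarray) -> np.ndarray:
    """Distribution over the two candidate positions.

    ``message`` is a one-hot or relaxed vector over the vocabulary (consumed
    as message @ embed); ``candidates`` is (2, 3) raw CIELAB coordinates.
    """
    e = np.asarray(message, dtype=float) @ lp.embed
    u = (np.asarray(candidates, dtype=float) / COORD_SCALE) @ lp.proj
    return _softmax(u @ e)


def game_loss(position_dist: np.ndarray, true_position: int) -> float:
    """Cross-entropy: -log probability assigned to the target's position."""
    return float(-np.log(np.clip(position_dist[true_position], _LOG_CLAMP, None)))


def reinforce_speaker_grad(p: np.ndarray, words: np.ndarray, losses: np.ndarray,
                           baseline: float, entropy_coeff: float) -> np.ndarray:
    """d(surrogate)/d(speaker logits) for a batch.

    The surrogate is mean_b [ sg(L_b - baseline) * log p_b(w_b) ]
    - entropy_coeff * mean_b H(p_b); its gradient is the score-function
    (REINFORCE) estimator with a baseline plus the entropy-bonus gradient.
    """
    p = np.atleast_2d(p)
    B, V = p.shape
    coef = (losses - baseline)[:, None] / B
    onehot = np.zeros_like(p)
    onehot[np.arange(B), words] = 1.0
    dlogits = coef * (onehot - p)
    if entropy_coeff:
        logp = np.log(np.clip(p, _LOG_CLAMP, None))
        H = -(p * logp).sum(axis=1, keepdims=True)
        dH = -p * (logp + H)          # dH/dlogits
        dlogits -= entropy_coeff / B * dH
    return dlogits


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _flatten_params(sp: SpeakerParams, lp: ListenerParams):
    ps = []
    for W, b in sp.weights:
        ps += [W, b]
    ps += [lp.embed, lp.proj]
    return ps


def _unflatten_params(ps, sp: SpeakerParams, lp: ListenerParams):
    k = 0
    new_w = []
    for _ in sp.weights:
        new_w.append((ps[k], ps[k + 1]))
        k += 2
    sp.weights = new_w
    lp.embed, lp.proj = ps[k], ps[k + 1]


def success_rate(sp: SpeakerParams, lp: ListenerParams, palette: Palette,
                 threshold: float, mode: str = "exact",
                 n_rounds: int = 10_000, rng: np.random.Generator | None = None,
                 drop_isolated_targets: bool = False) -> float:
    """Game success with argmax (deterministic) word decoding.

    ``exact`` averages the Listener's argmax outcome over every valid
    (target, distractor) pair with its sampling weight; ``sampled`` is the
    Monte-Carlo estimate of the same quantity.  Listener ties count as
    failures.
    """
    p = speaker_probs(sp, palette.coords)
    words = p.argmax(axis=1)                       # ties -> lowest index
    E = lp.embed[words]                            # (n, dim)
    U = (palette.coords / COORD_SCALE) @ lp.proj   # (n, dim)
    scores = E @ U.T                               # scores[t, c] with word of t
    own = np.diag(scores)

    if mode == "exact":
        pairs, weights = enumerate_valid_rounds(
            palette, threshold, drop_isolated_targets=drop_isolated_targets)
        correct = own[pairs[:, 0]] > scores[pairs[:, 0], pairs[:, 1]]
        return float(weights @ correct)
    if mode == "sampled":
        rng = rng or np.random.default_rng()
        t, d, _ = sample_rounds(palette, threshold, n_rounds, rng,
                                drop_isolated_targets=drop_isolated_targets)
        return float(np.mean(own[t] > scores[t, d]))
    raise ValueError("mode must be 'exact' or 'sampled'")


def train(palette: Palette, game: GameConfig, cfg: TrainConfig) -> TrainRun:
    """Train a Speaker/Listener pair on the discrimination game.

    GS runs use relaxed messages during training and discrete argmax words
    at evaluation; RF runs are discrete throughout.  Training stops when the
    exact argmax success rate stays at or above ``success_threshold`` for
    ``plateau_evals`` consecutive evaluations, or at ``max_interactions``.
    """
    rng = np.random.default_rng(cfg.seed)
    sp = init_speaker(game.vocab_size, cfg.speaker_hidden, cfg.speaker_depth, rng)
    lp = init_listener(game.vocab_size, cfg.listener_dim, rng)

    threshold = distance_threshold(palette, game.percentile)
    sets, _ = valid_distractor_sets(
        palette, threshold,
        on_empty="report" if game.drop_isolated_targets else "raise")
    X = palette.coords / COORD_SCALE

    params = _flatten_params(sp, lp)
    opt = _Adam([p.shape for p in params], cfg.learning_rate)
    baseline = 0.0
    baseline_init = False
    trajectory = []
    interactions = 0
    passing_streak = 0
    converged = False
    recent_losses = []

    while interactions < cfg.max_interactions and not converged:
        for _ in range(cfg.eval_every):
            B = cfg.batch_size
            t, d, pos = sample_rounds(
                palette, threshold, B, rng, sets=sets,
                drop_isolated_targets=game.drop_isolated_targets)
            probs, acts = _speaker_forward(sp, X[t])
            # candidates laid out by position: cand[:, pos] is the target
            cand = np.empty((B, 2, 3))
            cand[np.arange(B), pos] = X[t]
            cand[np.arange(B), 1 - pos] = X[d]
            Ucand = cand @ lp.proj                      # (B, 2, dim)

            if cfg.method == "gs":
                g = rng.gumbel(size=probs.shape)
                y = _softmax((g + np.log(np.clip(probs, _LOG_CLAMP, None))) / cfg.tau)
                e = y @ lp.embed                        # (B, dim)
            else:
                u = rng.random((B, 1))
                words = (probs.cumsum(axis=1) > u).argmax(axis=1)
                e = lp.embed[words]

            scores = np.einsum("bkd,bd->bk", Ucand, e)  # (B, 2)
            q = _softmax(scores, axis=1)
            qt = np.clip(q[np.arange(B), pos], _LOG_CLAMP, None)
            losses = -np.log(qt)
            mean_loss = float(losses.mean())
            if not np.isfinite(mean_loss):
                raise FloatingPointError("training diverged: non-finite loss")
            recent_losses.append(mean_loss)

            # Listener backprop (and, for GS, Speaker backprop through y)
            dscores = q.copy()
            dscores[np.arange(B), pos] -= 1.0
            dscores /= B
            de = np.einsum("bk,bkd->bd", dscores, Ucand)
            dUcand = dscores[:, :, None] * e[:, None, :]
            dproj = np.einsum("bki,bkd->id", cand, dUcand)

            if cfg.method == "gs":
                dembed = y.T @ de
                dy = de @ lp.embed.T
                dz = y * (dy - (dy * y).sum(axis=1, keepdims=True))
                dlogp = dz / cfg.tau
                dlogits = dlogp - probs * dlogp.sum(axis=1, keepdims=True)
            else:
                dembed = np.zeros_like(lp.embed)
                np.add.at(dembed, words, de)
                if not baseline_init:
                    baseline, baseline_init = mean_loss, True
                dlogits = reinforce_speaker_grad(
                    probs, words, losses, baseline, cfg.entropy_coeff)
                baseline += cfg.baseline_decay * (mean_loss - baseline)

            sp_grads = _speaker_backward(sp, acts, dlogits)
            grads = []
            for gW, gb in sp_grads:
                grads += [gW, gb]
            grads += [dembed, dproj]
            params = opt.step(params, grads)
            _unflatten_params(params, sp, lp)
            interactions += B

        succ = success_rate(sp, lp, palette, threshold, mode="exact",
                            drop_isolated_targets=game.drop_isolated_targets)
        trajectory.append((interactions, succ, float(np.mean(recent_losses))))
        recent_losses = []
        passing_streak = passing_streak + 1 if succ >= cfg.success_threshold else 0
        converged = passing_streak >= cfg.plateau_evals

    final = trajectory[-1][1] if trajectory else float("nan")
    converged = bool(trajectory and final >= cfg.success_threshold)
    return TrainRun(sp, lp, trajectory, converged,
                    interactions, cfg, game, cfg.seed, final_success=final)
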
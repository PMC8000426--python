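"""Information Bottleneck scoring of naming systems.

The communication model: a speaker who wants to talk about chip ``c``
entertains a Gaussian belief m(c) over the whole palette, centered at ``c``
with variance ``sigma2`` in squared CIELAB distance.  A naming system
P(w|c) is then scored by

* complexity  I(M;W) = I(C;W)  (bits) — the informational cost of the code
  (equal to I(C;W) because the meaning m(c) is a deterministic function of
  the chip), and
* accuracy    I(U;W)  (bits) — how much a listener can recover about the
  universe from a word, computed from the joint
  p(u, w) = sum_c p(c) P(w|c) m(c)(u).

The theoretical limit is traced by minimizing I(M;W) - beta * I(U;W) over
encoders for beta annealed downward from a large initial value to 1, each
solution warm-starting the next (reverse deterministic annealing with
iterative self-consistent updates).  The inefficiency of a system is its
Euclidean distance, on the (complexity, accuracy) plane, to the curve.

All internal arithmetic is in natural log; reported quantities are bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .naming import NamingSystem
from .palette import Palette

__all__ = [
    "MeaningModel",
    "IBPoint",
    "IBCurve",
    "build_meanings",
    "complexity",
    "accuracy",
    "ib_step",
    "compute_ib_curve",
    "inefficiency",
    "fit_beta",
]

LN2 = np.log(2.0)
_EPS = 1e-300


@dataclass
class MeaningModel:
    """Rows of ``M`` are the speaker meanings m(c): Gaussian-over-chips
    distributions centered at each chip, variance ``sigma2`` (default 64,
    squared CIELAB units), normalized on the discrete palette."""

    sigma2: float
    M: np.ndarray  # (n_chips, n_chips); M[c, u] = m(c)(u)


@dataclass
class IBPoint:
    complexity: float  # bits
    accuracy: float    # bits
    beta: float | None = None


@dataclass
class IBCurve:
    """beta-indexed frontier points, beta decreasing from beta_init to 1.

    ``complexity``/``accuracy`` are in bits, sorted here by ascending
    complexity after the upper-envelope cleanup; ``encoders`` optionally
    keeps the per-beta solutions.
    """

    betas: np.ndarray
    complexity: np.ndarray
    accuracy: np.ndarray
    encoders: list = field(default_factory=list)

    def envelope(self) -> "IBCurve":
        """The concave upper envelope of the recorded points."""
        order = np.argsort(self.complexity, kind="stable")
        cx, acc, b = (self.complexity[order], self.accuracy[order],
                      self.betas[order])
        keep = _upper_envelope(cx, acc)
        encs = [self.encoders[i] for i in order[keep]] if self.encoders else []
        return IBCurve(b[keep], cx[keep], acc[keep], encs)

    def accuracy_at(self, cx) -> np.ndarray:
        """Frontier accuracy at given complexity (flat beyond both ends:
        the curve starts at (0, 0) and saturates at maximal accuracy)."""
        c = np.concatenate(([0.0], self.complexity))
        a = np.concatenate(([0.0], self.accuracy))
        return np.interp(cx, c, a)


def build_meanings(palette: Palette, sigma2: float = 64.0) -> MeaningModel:
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    logM = -(palette.dist ** 2) / (2.0 * sigma2)
    logM -= logM.max(axis=1, keepdims=True)
    M = np.exp(logM)
    M /= M.sum(axis=1, keepdims=True)
    return MeaningModel(sigma2, M)


def _xlogy(x, y):
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log(y[nz])
    return out


def complexity(ns: NamingSystem, palette: Palette) -> float:
    """I(M;W) in bits (= I(C;W); 0 log 0 := 0)."""
    enc = ns.enc
    prior = palette.prior
    pw = prior @ enc
    ratio = np.where(pw > 0, enc / np.where(pw > 0, pw, 1.0), 1.0)
    terms = prior[:, None] * _xlogy(enc, np.clip(ratio, _EPS, None))
    return float(terms.sum() / LN2)


def accuracy(ns: NamingSystem, meanings: MeaningModel, palette: Palette) -> float:
    """I(U;W) in bits under the joint p(u,w) = sum_c p(c) P(w|c) m(c)(u).

    Equivalently sum_w P(w) KL(mhat_w || m0): how far each word's listener
    meaning is from the prior mixture of meanings.
    """
    if ns.enc.shape[0] != meanings.M.shape[0]:
        raise ValueError("naming system and meaning model sizes differ")
    prior = palette.prior
    joint = (ns.enc * prior[:, None]).T @ meanings.M  # (W, U): p(w, u)
    pw = joint.sum(axis=1)
    m0 = prior @ meanings.M
    keep = pw > 0
    ratio = joint[keep] / (pw[keep, None] * m0[None, :])
    return float(_xlogy(joint[keep], np.clip(ratio, _EPS, None)).sum() / LN2)


def _mutual_infos(enc, prior, M):
    """(I(C;W), I(U;W)) in nats for an encoder array."""
    pw = prior @ enc
    cx = _xlogy(prior[:, None] * enc,
                np.clip(enc / np.where(pw > 0, pw, 1.0)[None, :], _EPS, None)).sum()
    joint = (enc * prior[:, None]).T @ M
    m0 = prior @ M
    keep = pw > 0
    acc = _xlogy(joint[keep],
                 np.clip(joint[keep] / (pw[keep, None] * m0[None, :] + _EPS),
                         _EPS, None)).sum()
    return cx, acc


def ib_step(enc: np.ndarray, meanings: MeaningModel, palette: Palette,
            beta: float, _negH: np.ndarray | None = None) -> np.ndarray:
    """One self-consistent update of the encoder at trade-off ``beta``.

    Recomputes P(w) and the listener meanings mhat_w, then
    P(w|c) proportional to P(w) * exp(-beta * KL(m(c) || mhat_w)),
    normalized per chip.  Performed in log space.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    prior = palette.prior
    M = meanings.M
    pw = prior @ enc
    keep = pw > 1e-300
    enc = enc[:, keep]
    pw = pw[keep]
    pcw = enc * prior[:, None] / pw[None, :]          # p(c|w), (n, W)
    mhat = pcw.T @ M                                  # (W, U)
    negH = _xlogy(M, M).sum(axis=1) if _negH is None else _negH
    cross = M @ np.log(np.clip(mhat, _EPS, None)).T   # (n, W)
    kl = negH[:, None] - cross
    log_new = np.log(pw)[None, :] - beta * kl
    log_new -= log_new.max(axis=1, keepdims=True)
    new = np.exp(log_new)
    new /= new.sum(axis=1, keepdims=True)
    return new


def _merge_duplicates(enc, prior, M, tv_tol=1e-9):
    """Merge words whose listener meanings coincide (total variation below
    ``tv_tol``); their encoder columns are summed."""
    pw = prior @ enc
    keep = pw > 0
    enc, pw = enc[:, keep], pw[keep]
    pcw = enc * prior[:, None] / pw[None, :]
    mhat = pcw.T @ M
    W = enc.shape[1]
    groups = []
    assigned = np.full(W, -1)
    for j in range(W):
        if assigned[j] >= 0:
            continue
        tv = 0.5 * np.abs(mhat[j + 1:] - mhat[j]).sum(axis=1)
        dup = j + 1 + np.flatnonzero(tv < tv_tol)
        dup = dup[assigned[dup] < 0]
        assigned[j] = len(groups)
        assigned[dup] = len(groups)
        groups.append(len(groups))
    merged = np.zeros((enc.shape[0], len(groups)))
    np.add.at(merged.T, assigned, enc.T)
    return merged


def _prune_merge(enc, prior, M, prune_eps, merge_tv):
    pw = prior @ enc
    enc = enc[:, pw >= prune_eps]
    enc = enc / enc.sum(axis=1, keepdims=True)
    return _merge_duplicates(enc, prior, M, merge_tv)


def _solve_beta(enc, meanings, palette, beta, negH, tol, max_iter,
                prune_eps, merge_tv):
    """Iterate the self-consistent update to a fixed point at one beta.

    Plain iteration slows to a linear rate near phase transitions (mass
    draining out of redundant words decays geometrically), so every cycle
    applies a SQUAREM-style extrapolation of the fixed-point sequence, and
    words that have become negligible or coincident are removed as soon as
    they appear.  Stops at encoder change below ``tol`` or after
    ``max_iter`` update evaluations.
    """
    prior, M = palette.prior, meanings.M
    evals = 0
    while evals < max_iter:
        x0 = enc
        x1 = ib_step(x0, meanings, palette, beta, _negH=negH)
        evals += 1
        if x1.shape == x0.shape and np.max(np.abs(x1 - x0)) < tol:
            return x1
        x2 = ib_step(x1, meanings, palette, beta, _negH=negH)
        evals += 1
        if x2.shape == x1.shape and np.max(np.abs(x2 - x1)) < tol:
            return x2
        enc = x2
        if x0.shape == x1.shape == x2.shape:
            r = x1 - x0
            v = x2 - 2 * x1 + x0
            nv = float(np.linalg.norm(v))
            if nv > 0:
                alpha = -float(np.linalg.norm(r)) / nv
                xa = np.clip(x0 - 2 * alpha * r + alpha * alpha * v, 0.0, None)
                rows = xa.sum(axis=1, keepdims=True)
                if np.all(rows > 0) and np.all(np.isfinite(xa)):
                    x3 = ib_step(xa / rows, meanings, palette, beta, _negH=negH)
                    evals += 1
                    if np.all(np.isfinite(x3)):
                        enc = x3
        enc = _prune_merge(enc, prior, M, prune_eps, merge_tv)
    return enc


def default_beta_schedule(beta_init: float = 2.0 ** 13, n_beta: int = 1500) -> np.ndarray:
    """Annealing grid from ``beta_init`` down to 1.

    The upper part (down to beta = 1.5) is geometric in beta; the lower
    part is geometric in beta - 1, ending exactly at 1.  The extra density
    near beta = 1 matters because the low-complexity stretch of the curve
    — where attested naming systems live — is traced entirely by
    beta in ]1, ~1.2].
    """
    n_low = n_beta // 2
    n_high = n_beta - n_low
    high = np.geomspace(beta_init, 1.5, n_high, endpoint=False)
    low = 1.0 + np.geomspace(0.5, 1e-3, n_low)
    low[-1] = 1.0
    return np.concatenate([high, low])


def compute_ib_curve(meanings: MeaningModel, palette: Palette,
                     beta_init: float = 2.0 ** 13, n_beta: int = 1500,
                     schedule: np.ndarray | None = None, tol: float = 1e-10,
                     max_iter: int = 30_000, prune_eps: float = 1e-12,
                     merge_tv: float = 1e-9, store_encoders: bool = False,
                     envelope: bool = True) -> IBCurve:
    """Trace the theoretical limit by reverse annealing.

    Starts from the identity encoder (one word per chip) at ``beta_init``;
    at each beta on a decreasing geometric ``schedule`` the encoder is
    iterated to self-consistency, warm-starting from the previous beta.
    The per-beta stopping rule is max absolute encoder change below ``tol``
    or ``max_iter`` iterations (self-consistent iteration slows to a
    linear rate near phase transitions; the envelope cleanup removes any
    point it leaves dominated).  Words with negligible marginal are pruned
    and words with coinciding listener meanings merged, so the support
    size K is itself optimized.
    """
    if schedule is None:
        schedule = default_beta_schedule(beta_init, n_beta)
    schedule = np.asarray(schedule, dtype=float)
    if schedule[0] < schedule[-1] or schedule[-1] < 1:
        raise ValueError("schedule must decrease from beta_init to >= 1")
    prior = palette.prior
    M = meanings.M
    n = palette.n_chips
    enc = np.eye(n)
    betas, cxs, accs, encs = [], [], [], []
    negH = _xlogy(M, M).sum(axis=1)

    for beta in schedule:
        enc = _solve_beta(enc, meanings, palette, beta, negH,
                          tol, max_iter, prune_eps, merge_tv)
        if not np.all(np.isfinite(enc)):
            raise RuntimeError(f"iterative IB diverged at beta={beta:g}")
        pw = prior @ enc
        enc = enc[:, pw >= prune_eps]
        enc /= enc.sum(axis=1, keepdims=True)
        enc = _merge_duplicates(enc, prior, M, merge_tv)
        cx, acc = _mutual_infos(enc, prior, M)
        betas.append(beta)
        cxs.append(cx / LN2)
        accs.append(acc / LN2)
        if store_encoders:
            encs.append(enc.copy())

    betas = np.asarray(betas)
    cxs = np.asarray(cxs)
    accs = np.asarray(accs)
    order = np.argsort(cxs, kind="stable")
    betas, cxs, accs = betas[order], cxs[order], accs[order]
    if store_encoders:
        encs = [encs[i] for i in order]
    if envelope:
        keep = _upper_envelope(cxs, accs)
        betas, cxs, accs = betas[keep], cxs[keep], accs[keep]
        if store_encoders:
            encs = [encs[i] for i in np.flatnonzero(keep)]
    return IBCurve(betas, cxs, accs, encs)


def _upper_envelope(cx, acc):
    """Boolean mask of points on the concave upper envelope of (cx, acc)."""
    idx = list(range(len(cx)))
    # drop points dominated by one with less complexity and more accuracy
    best = -np.inf
    keep1 = []
    for i in idx:
        if acc[i] > best + 1e-15:
            keep1.append(i)
            best = acc[i]
    # monotone-chain upper hull in the complexity/accuracy plane
    hull = []
    for i in keep1:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = (cx[hull[-2]], acc[hull[-2]]), (cx[hull[-1]], acc[hull[-1]])
            x3, y3 = cx[i], acc[i]
            if (x2 - x1) * (y3 - y1) - (y2 - y1) * (x3 - x1) >= -1e-15:
                hull.pop()
            else:
                break
        hull.append(i)
    mask = np.zeros(len(cx), dtype=bool)
    mask[hull] = True
    return mask


def _point_segment_distance(p, a, b):
    ab = b - a
    denom = ab @ ab
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab))), t


def inefficiency(point: IBPoint, curve: IBCurve) -> float:
    """Euclidean distance from (complexity, accuracy) to the piecewise-
    linear interpolation of the curve, both axes in bits."""
    return _nearest_on_curve(point, curve)[0]


def fit_beta(point: IBPoint, curve: IBCurve) -> float:
    """beta of the nearest curve location (log-linear interpolation of beta
    between the two bracketing curve samples)."""
    _, seg, t = _nearest_on_curve(point, curve)
    if seg is None:
        return float(curve.betas[0])
    b0, b1 = curve.betas[seg], curve.betas[seg + 1]
    return float(b0 ** (1 - t) * b1 ** t)


def _nearest_on_curve(point: IBPoint, curve: IBCurve):
    if len(curve.complexity) == 0:
        raise ValueError("empty curve")
    p = np.array([point.complexity, point.accuracy])
    pts = np.column_stack([curve.complexity, curve.accuracy])
    if len(pts) == 1:
        return float(np.linalg.norm(p - pts[0])), None, 0.0
    best, best_seg, best_t = np.inf, None, 0.0
    for s in range(len(pts) - 1):
        d, t = _point_segment_distance(p, pts[s], pts[s + 1])
        if d < best:
            best, best_seg, best_t = d, s, t
    return best, best_seg, best_t
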
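"""Fuzzy c-means baseline: clustering-derived naming systems played with
Bayesian listeners.

Cluster labels act as color names and the soft membership rows as P(w|c).
Swept over the number of clusters, the baseline answers whether perfectly
discriminating systems exist at each percentile and how complex the least
complex fully successful one is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import enumerate_valid_rounds
from .ib import complexity
from .naming import NamingSystem
from .palette import Palette

__all__ = ["FCMResult", "fcm_fit", "fcm_naming", "bayesian_expected_success", "fcm_sweep"]


@dataclass
class FCMResult:
    k: int
    fuzzifier: float
    centers: np.ndarray       # (k, 3)
    memberships: np.ndarray   # (n_chips, k), rows sum to 1
    objective: float
    converged: bool


def _fcm_once(X, k, m, tol, max_iter, rng):
    n = X.shape[0]
    U = rng.dirichlet(np.ones(k), size=n)
    obj_prev = np.inf
    converged = False
    for _ in range(max_iter):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-30
        if zero.any():
            U = np.where(zero, 1.0, 0.0)
            U = U / U.sum(axis=1, keepdims=True)
        else:
            inv = d2 ** (-1.0 / (m - 1.0))
            U = inv / inv.sum(axis=1, keepdims=True)
        obj = float((U ** m * d2).sum())
        if abs(obj_prev - obj) < tol:
            converged = True
            break
        obj_prev = obj
    return U, centers, obj, converged


def fcm_fit(palette: Palette, k: int, fuzzifier: float = 2.0, tol: float = 1e-6,
            max_iter: int = 300, restarts: int = 10, seed: int = 0) -> FCMResult:
    """Standard FCM on chip coordinates; best of ``restarts`` random starts
    by the within-cluster objective sum_ik u_ik^m d_ik^2."""
    if not 2 <= k <= palette.n_chips:
        raise ValueError("need 2 <= k <= n_chips")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        U, centers, obj, conv = _fcm_once(palette.coords, k, fuzzifier, tol, max_iter, rng)
        if best is None or obj < best[2]:
            best = (U, centers, obj, conv)
    U, centers, obj, conv = best
    return FCMResult(k, fuzzifier, centers, U, obj, conv)


def fcm_naming(res: FCMResult, mode: str = "membership") -> NamingSystem:
    """Naming system from a clustering, cluster indices as words.

    ``mode="membership"`` uses the soft membership rows as P(w|c);
    ``mode="hard"`` assigns each chip its modal cluster deterministically
    (ties to the lowest index).  Soft membership rows are strictly positive
    everywhere, so a sampled-word game can never be perfect in exact
    expectation; the hard mode is what makes "100% success" a well-defined
    exact statement and is what the sweep uses.
    """
    if mode == "membership":
        enc = res.memberships.copy()
    elif mode == "hard":
        enc = np.zeros_like(res.memberships)
        enc[np.arange(len(enc)), res.memberships.argmax(axis=1)] = 1.0
    else:
        raise ValueError("mode must be 'membership' or 'hard'")
    return NamingSystem(list(range(res.k)), enc, provenance="fcm")


def bayesian_expected_success(ns: NamingSystem, palette: Palette,
                              threshold: float) -> float:
    """Exact expected discrimination success of ``ns`` with a Bayesian
    listener.

    The speaker samples w ~ P(w|target); the listener, holding the two
    candidates, picks the chip with the larger P(w|chip) (equivalent to the
    Bayes rule under the symmetric pair prior); exact ties score 1/2.  The
    expectation runs over all valid rounds and speaker draws — no Monte
    Carlo, so the value is seed-free.
    """
    pairs, weights = enumerate_valid_rounds(palette, threshold)
    enc = ns.enc
    t, d = pairs[:, 0], pairs[:, 1]
    pt, pd_ = enc[t], enc[d]  # (n_pairs, W)
    win = (pt > pd_).astype(float) + 0.5 * (pt == pd_)
    per_pair = (pt * win).sum(axis=1)
    return float(weights @ per_pair)


def fcm_sweep(palette: Palette, threshold: float, k_range=range(2, 21),
              fuzzifier: float = 2.0, restarts: int = 10, seed: int = 0,
              success_tol: float = 1e-12, naming_mode: str = "hard"):
    """Fit FCM for each k; among fully successful systems return the least
    complex.

    Success is the exact Bayesian-listener expectation over valid rounds;
    the default ``naming_mode="hard"`` plays modal cluster labels, under
    which full success holds exactly whenever no valid pair shares a
    cluster.

    Returns ``(best_ns, table)`` where ``table`` has one row per k with the
    system's complexity (bits) and exact Bayesian success, and ``best_ns``
    is ``None`` when no k in range reaches full success.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    rows, systems = [], {}
    for k in k_range:
        res = fcm_fit(palette, k, fuzzifier=fuzzifier, restarts=restarts, seed=seed + k)
        ns = fcm_naming(res, mode=naming_mode)
        succ = bayesian_expected_success(ns, palette, threshold)
        cx = complexity(ns, palette)
        rows.append({"k": k, "complexity_bits": cx, "success": succ,
                     "fully_successful": succ >= 1.0 - success_tol})
        systems[k] = ns
    table = pd.DataFrame(rows)
    ok = table[table["fully_successful"]]
    best_ns = None
    if not ok.empty:
        best_k = int(ok.loc[ok["complexity_bits"].idxmin(), "k"])
        best_ns = systems[best_k]
    return best_ns, table
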
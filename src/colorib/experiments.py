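"""Sweep orchestration, aggregation and the statistical comparisons.

A sweep cell is (percentile, method, tau, capacity, seed).  Each cell
trains a pair of agents, evaluates argmax success exactly, extracts the
25-sample naming system and scores it on the information plane against a
precomputed theoretical-limit curve.  Only runs reaching the 95% success
threshold enter the "successful" aggregates; the trend and discreteness
comparisons use rank-based tests with Bonferroni correction, matching how
the underlying distributions are typically non-Gaussian and small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .agents import TrainConfig, train
from .extraction import effective_vocab, extract_naming
from .game import GameConfig
from .ib import IBCurve, IBPoint, MeaningModel, accuracy, build_meanings, \
    complexity, fit_beta, inefficiency
from .palette import Palette

__all__ = [
    "SweepSpec",
    "run_sweep",
    "complexity_trend_test",
    "discreteness_comparison",
    "information_plane_plot",
]

STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


@dataclass
class SweepSpec:
    """Grid over game and training settings; every cell is fully determined
    by the global seed and its index."""

    percentiles: tuple = (20, 30, 40, 50, 60, 70, 80)
    methods: tuple = ("gs",)
    taus: tuple = (1.0,)            # used by GS cells only
    n_seeds: int = 20
    vocab_size: int = 1024
    speaker_hidden: int = 1000
    speaker_depth: int = 3
    listener_dim: int = 5
    global_seed: int = 0
    n_extract_samples: int = 25
    sigma2: float = 64.0
    train_kwargs: dict = field(default_factory=dict)

    def cells(self):
        idx = 0
        for pct in self.percentiles:
            for method in self.methods:
                taus = self.taus if method == "gs" else (None,)
                for tau in taus:
                    for rep in range(self.n_seeds):
                        yield idx, pct, method, tau, rep
                        idx += 1


def _cell_seed(global_seed: int, idx: int) -> int:
    return int(np.random.default_rng([global_seed, idx]).integers(2 ** 31))


def run_sweep(spec: SweepSpec, palette: Palette, curve: IBCurve,
              meanings: MeaningModel | None = None,
              out_dir=None) -> pd.DataFrame:
    """Run every sweep cell; returns one row per run.

    With ``out_dir`` set, each finished run is persisted as a JSON file and
    already-present cells are loaded instead of re-run, making sweeps
    resumable; identical config + seed reproduces identical rows.  A run
    that raises is recorded with ``error`` set, never aborting the sweep.
    """
    meanings = meanings or build_meanings(palette, spec.sigma2)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, pct, method, tau, rep in spec.cells():
        cell_path = out_dir / f"run_{idx:05d}.json" if out_dir is not None else None
        if cell_path is not None and cell_path.exists():
            rows.append(json.loads(cell_path.read_text()))
            continue
        seed = _cell_seed(spec.global_seed, idx)
        row = {"cell": idx, "percentile": pct, "method": method,
               "tau": tau, "replicate": rep, "seed": seed}
        try:
            game = GameConfig(percentile=pct, vocab_size=spec.vocab_size, seed=seed)
            cfg = TrainConfig(method=method, tau=tau if tau is not None else 1.0,
                              speaker_hidden=spec.speaker_hidden,
                              speaker_depth=spec.speaker_depth,
                              listener_dim=spec.listener_dim, seed=seed,
                              **spec.train_kwargs)
            run = train(palette, game, cfg)
            rng = np.random.default_rng(seed + 1)
            ns = extract_naming(run.speaker, palette, spec.n_extract_samples, rng)
            cx = complexity(ns, palette)
            acc = accuracy(ns, meanings, palette)
            point = IBPoint(cx, acc)
            row.update(
                converged=run.converged, success=run.final_success,
                interactions=run.interactions, complexity_bits=cx,
                accuracy_bits=acc, inefficiency=inefficiency(point, curve),
                beta_fit=fit_beta(point, curve),
                effective_vocab=effective_vocab(ns), error=None,
            )
        except (FloatingPointError, ValueError, RuntimeError) as exc:
            row.update(converged=False, success=float("nan"), error=str(exc))
        if cell_path is not None:
            cell_path.write_text(json.dumps(row))
        rows.append(row)
    return pd.DataFrame(rows)


def successful_runs(table: pd.DataFrame, threshold: float = 0.95) -> pd.DataFrame:
    """The runs entering every aggregate: success >= threshold."""
    return table[(table["error"].isna()) & (table["success"] >= threshold)]


def _stars(p: float) -> str:
    for level, s in STAR_LEVELS:
        if p < level:
            return s
    return ""


def complexity_trend_test(table: pd.DataFrame, group_col: str = "percentile",
                          value_col: str = "complexity_bits",
                          success_threshold: float = 0.95) -> dict:
    """Kruskal-Wallis omnibus test across groups plus Bonferroni-corrected
    pairwise Mann-Whitney tests on the successful runs."""
    data = successful_runs(table, success_threshold)
    groups = {g: sub[value_col].to_numpy() for g, sub in data.groupby(group_col)}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 successful runs")
    keys = sorted(groups)
    H, p = stats.kruskal(*[groups[k] for k in keys])
    pairs = list(combinations(keys, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        stat, praw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pcorr = min(1.0, praw * m)
        pairwise.append({"a": a, "b": b, "U": float(stat), "p_raw": float(praw),
                         "p_bonferroni": pcorr, "stars": _stars(pcorr)})
    return {
        "groups": {k: {"n": len(groups[k]), "median": float(np.median(groups[k]))}
                   for k in keys},
        "kruskal_H": float(H), "kruskal_p": float(p), "pairwise": pairwise,
    }


def discreteness_comparison(table: pd.DataFrame,
                            success_threshold: float = 0.95) -> dict:
    """Per-method/tau complexity and inefficiency summaries with pairwise
    Bonferroni-corrected rank tests and star annotations."""
    data = successful_runs(table, success_threshold).copy()
    data["setting"] = [
        "rf" if m == "reinforce" else f"gs_tau{t:g}"
        for m, t in zip(data["method"], data["tau"])
    ]
    report = {"settings": {}, "pairwise": {}}
    for metric in ("complexity_bits", "inefficiency"):
        groups = {s: sub[metric].dropna().to_numpy()
                  for s, sub in data.groupby("setting")}
        groups = {s: v for s, v in groups.items() if len(v) >= 2}
        for s, v in groups.items():
            report["settings"].setdefault(s, {})[metric] = {
                "n": len(v), "median": float(np.median(v))}
        pairs = list(combinations(sorted(groups), 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            stat, praw = stats.mannwhitneyu(groups[a], groups[b],
                                            alternative="two-sided")
            pcorr = min(1.0, praw * m) if m else 1.0
            rows.append({"a": a, "b": b, "U": float(stat), "p_raw": float(praw),
                         "p_bonferroni": pcorr, "stars": _stars(pcorr)})
        report["pairwise"][metric] = rows
    return report


def information_plane_plot(points, curve: IBCurve, out,
                           labels=None) -> None:
    """Scatter scored systems over the theoretical-limit curve and save to
    ``out``.  Purely presentational."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(curve.complexity, curve.accuracy, "k-", lw=1.5, label="IB limit")
    pts = [(p.complexity, p.accuracy) for p in points]
    if pts:
        xs, ys = zip(*pts)
        ax.scatter(xs, ys, s=18, c="tab:orange", alpha=0.8,
                   label=labels or "naming systems")
    ax.set_xlabel("complexity, I(M;W) bits")
    ax.set_ylabel("accuracy, I(U;W) bits")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
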
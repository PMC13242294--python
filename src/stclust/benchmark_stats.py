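"""Nonparametric paired benchmark statistics across slides.

Friedman test (tie-corrected average ranks), exact one-sided paired
Wilcoxon signed-rank tests (full enumeration of the sign-pattern null for
n <= 25), Holm step-down correction and rank-biserial effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

logger = logging.getLogger("stclust")

MAX_EXACT_N = 25


@dataclass
class ScoreTable:
    """Per-method, per-slide scores (e.g. ARI), no missing cells."""

    methods: list
    slides: list
    scores: np.ndarray  # (n_methods, n_slides)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.methods), len(self.slides)):
            raise ValueError("score matrix shape does not match methods x slides")
        if len(self.slides) < 2:
            raise ValueError("at least 2 slides required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("missing or non-finite scores")

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            methods=[str(m) for m in df.index],
            slides=[str(s) for s in df.columns],
            scores=df.to_numpy(dtype=float),
        )

    def row(self, method: str) -> np.ndarray:
        if method not in self.methods:
            raise KeyError(f"unknown method {method!r}")
        return self.scores[self.methods.index(method)]

    def subset(self, methods: Sequence[str]) -> "ScoreTable":
        return ScoreTable(
            methods=list(methods),
            slides=list(self.slides),
            scores=np.vstack([self.row(m) for m in methods]),
        )


@dataclass
class PairwiseRecord:
    proposed: str
    baseline: str
    wins: int
    n_slides: int
    delta_mean: float
    p_raw: float
    p_holm: float
    rank_biserial: float


@dataclass
class ComparisonReport:
    friedman_chi2: float
    friedman_p: float
    pairwise: list = field(default_factory=list)


def friedman_test(table: ScoreTable, tie_correction: bool = True) -> Tuple[float, float]:
    """Tie-corrected Friedman chi-squared over within-slide average ranks."""
    k, n = table.scores.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 methods")
    ranks = np.apply_along_axis(rankdata, 0, table.scores)
    rank_sums = ranks.sum(axis=1)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    if tie_correction:
        ties = 0.0
        for j in range(n):
            _, counts = np.unique(table.scores[:, j], return_counts=True)
            ties += np.sum(counts**3 - counts)
        correction = 1.0 - ties / (n * (k**3 - k))
        if correction > 0:
            stat /= correction
    p = float(chi2_dist.sf(stat, k - 1))
    return float(stat), p


def _signed_ranks(a, b):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    return d, ranks


def wilcoxon_one_sided(a, b) -> Tuple[float, int, float]:
    """Exact one-sided signed-rank p-value for the alternative a > b.

    Zero differences are dropped, tied magnitudes receive average ranks,
    and the null distribution of W+ is enumerated exactly over all 2^n
    sign patterns (via subset-sum counting on doubled ranks).
    Returns (p_raw, wins, delta_mean).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d, ranks = _signed_ranks(a, b)
    n = d.size
    if n > MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to n <= {MAX_EXACT_N}")
    w_plus = ranks[d > 0].sum()
    # doubled ranks are integers (average ranks are multiples of 1/2)
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        counts[r:] = counts[r:] + counts[:-r]
    threshold = int(np.rint(2 * w_plus))
    ge = sum(counts[threshold:])
    p = float(ge / (2**n))
    wins = int(np.sum(a > b))
    return p, wins, float(a.mean() - b.mean())


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        value = min(1.0, (m - i) * p[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted


def rank_biserial(a, b) -> float:
    """(W+ - W-) / (W+ + W-) from signed ranks of nonzero differences."""
    d, ranks = _signed_ranks(a, b)
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    return float((w_plus - w_minus) / (w_plus + w_minus))


def compare_methods(
    table: ScoreTable, proposed: Sequence[str], baselines: Sequence[str]
) -> ComparisonReport:
    """Friedman over the table plus per-proposed Holm-corrected Wilcoxon tests.

    Holm correction is applied within each proposed method's family of
    baseline comparisons.
    """
    for name in list(proposed) + list(baselines):
        if name not in table.methods:
            raise KeyError(f"unknown method {name!r}")
    if len(table.methods) >= 3:
        chi2, p = friedman_test(table)
    else:
        logger.warning("fewer than 3 methods; skipping Friedman test")
        chi2, p = float("nan"), float("nan")
    report = ComparisonReport(friedman_chi2=chi2, friedman_p=p)
    for prop in proposed:
        rows = []
        for base in baselines:
            p_raw, wins, delta = wilcoxon_one_sided(table.row(prop), table.row(base))
            rrb = rank_biserial(table.row(prop), table.row(base))
            rows.append((base, p_raw, wins, delta, rrb))
        adjusted = holm_adjust([r[1] for r in rows])
        for (base, p_raw, wins, delta, rrb), p_holm in zip(rows, adjusted):
            report.pairwise.append(
                PairwiseRecord(
                    proposed=prop,
                    baseline=base,
                    wins=wins,
                    n_slides=len(table.slides),
                    delta_mean=delta,
                    p_raw=p_raw,
                    p_holm=float(p_holm),
                    rank_biserial=rrb,
                )
            )
    return report


# --- packaged benchmark fixture -------------------------------------------

DISTINCT_METHODS = (
    "conST",
    "DeepST",
    "SpaceFlow",
    "STAGATE",
    "SpaGCN",
    "GraphST",
    "Scatter",
    "ACT",
    "FACT",
    "Ensemble",
)
PROPOSED_METHODS = ("Scatter", "ACT", "FACT", "Ensemble")
BASELINE_METHODS = ("conST", "DeepST", "SpaceFlow", "SpaGCN")


def load_dlpfc_scores() -> ScoreTable:
    """Published per-slide ARI scores of 13 methods on the 12-slide DLPFC
    benchmark, shipped as a CSV fixture."""
    with resources.as_file(
        resources.files("stclust").joinpath("data/dlpfc_benchmark_ari.csv")
    ) as path:
        return ScoreTable.from_csv(path)
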
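"""Group comparisons and per-position delta-score aggregation.

Score distributions (binder vs nonbinder, allele vs allele) are compared with
the Mann-Whitney rank-sum test: exact by full enumeration of all
C(n_A + n_B, n_A) labelings for small groups, tie-corrected normal
approximation otherwise.  Per-position aggregation of delta-scores over
non-anchor lysine positions identifies "favorable" adduction sites — those
where multiple modeled peptides show no score increase.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .binder import PSSM
from .chem import Peptide
from .mhc import AlleleModel, ComplexModel
from .scoring import SurrogateParams, delta_score

__all__ = [
    "FavorableResult",
    "RankSumResult",
    "build_delta_table",
    "compare_groups",
    "favorable_positions",
    "per_position_delta",
    "read_delta_table_tsv",
    "write_delta_table_tsv",
]

EXACT_LIMIT = 8  # enumerate all labelings when both groups are this small


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U (count of A-over-B pairs, ties as 1/2) and p-values."""

    U: float
    p_two_sided: float
    method: str          # "exact" | "normal"
    p_greater: float     # P(U >= observed) under H0
    p_less: float        # P(U <= observed) under H0


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
) -> RankSumResult:
    """Rank-sum comparison of two score vectors.

    ``mode``: "auto" (exact when both groups <= 8), "exact", or "normal".
    Exact p-values come from full enumeration of rank assignments; two-sided
    p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    exact = mode == "exact" or (
        mode == "auto" and a.size <= EXACT_LIMIT and b.size <= EXACT_LIMIT)
    u_obs = _u_statistic(a, b)
    if exact:
        p_ge, p_le = _exact_tails(a, b, u_obs)
        method = "exact"
    else:
        p_ge, p_le = _normal_tails(a, b, u_obs)
        method = "normal"
    p_two = min(1.0, 2.0 * min(p_ge, p_le))
    return RankSumResult(U=u_obs, p_two_sided=p_two, method=method,
                         p_greater=p_ge, p_less=p_le)


def _exact_tails(a: np.ndarray, b: np.ndarray, u_obs: float) -> tuple[float, float]:
    n_a, n = a.size, a.size + b.size
    ranks = rankdata(np.concatenate([a, b]))
    offset = n_a * (n_a + 1) / 2.0
    total = comb(n, n_a)
    n_ge = n_le = 0
    for sel in combinations(range(n), n_a):
        u = ranks[list(sel)].sum() - offset
        if u >= u_obs - 1e-9:
            n_ge += 1
        if u <= u_obs + 1e-9:
            n_le += 1
    return n_ge / total, n_le / total


def _normal_tails(a: np.ndarray, b: np.ndarray, u_obs: float) -> tuple[float, float]:
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0, 1.0
    sd = sqrt(var)
    # 0.5 continuity correction toward the mean
    p_ge = float(norm.sf((u_obs - mu - 0.5) / sd))
    p_le = float(norm.cdf((u_obs - mu + 0.5) / sd))
    return p_ge, p_le


def build_delta_table(
    peptides: Iterable[tuple[str, Peptide]],
    allele: AlleleModel,
    species: str = "pyrrole",
    pssm: PSSM | None = None,
    params: SurrogateParams | None = None,
    backend: str = "surrogate",
    registry=None,
) -> pd.DataFrame:
    """Delta-scores for every non-anchor lysine of each (id, peptide) pair.

    Anchor positions are excluded here, upstream of any aggregation: adducts
    at pocket anchors abolish binding outright and are not informative about
    accommodation.  Columns: peptide_id, position, delta, allele.
    """
    rows = []
    for pid, pep in peptides:
        length = len(pep)
        anchors = allele.anchors.get(length, frozenset())
        model = ComplexModel(peptide=pep, backbone=None,
                             receptor_atoms=np.empty((0, 4)),
                             template_id="none", allele=allele.name)
        for pos in sorted(pep.lysine_positions() - set(anchors)):
            d = delta_score(model, pos, species, allele, pssm, params,
                            backend, registry)
            rows.append((pid, pos, d, allele.name))
    return pd.DataFrame(rows, columns=["peptide_id", "position", "delta", "allele"])


def per_position_delta(table: pd.DataFrame, tau: float = 0.0) -> pd.DataFrame:
    """Per-position summary: n, mean delta, and count of delta <= tau.

    Positions with no observations are absent, not zero-filled.
    """
    if table.empty:
        return pd.DataFrame(columns=["position", "n", "mean_delta", "n_favorable"])
    grouped = table.groupby("position")["delta"]
    out = pd.DataFrame({
        "n": grouped.size(),
        "mean_delta": grouped.mean(),
        "n_favorable": grouped.apply(lambda s: int((s <= tau).sum())),
    }).reset_index().sort_values("position", ignore_index=True)
    return out


class FavorableResult(NamedTuple):
    positions: list[int]          # count(delta <= tau) >= min_count, ascending
    ranking_by_mean: list[int]    # all observed positions, most favorable first


def favorable_positions(summary: pd.DataFrame, min_count: int = 2) -> FavorableResult:
    """Positions where at least ``min_count`` peptides show delta <= tau.

    ``summary`` comes from :func:`per_position_delta` (which fixes tau).
    Also reports the full position ranking by mean delta, ascending.
    """
    if summary.empty:
        return FavorableResult([], [])
    passing = summary.loc[summary["n_favorable"] >= min_count, "position"]
    ranking = summary.sort_values(["mean_delta", "position"])["position"]
    return FavorableResult(sorted(int(p) for p in passing),
                           [int(p) for p in ranking])


def write_delta_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_delta_table_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "position", "delta"}
    if not required <= set(df.columns):
        raise ValueError(f"delta table must have columns {sorted(required)}")
    return df
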
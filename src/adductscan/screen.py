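"""Candidate-selection pipeline and HLA allele panel selection.

The screening chain mirrors how adduct-carrying self-epitope candidates are
funneled from a tissue proteome: (1) keep proteins overexpressed in the
target tissue (default: kidney, fold change > 4 vs the maximum across other
tissues), (2) map them to the model organism via an ortholog table, (3)
enumerate 9-mers, (4) keep predicted strong binders (percentile rank against
a random background <= 0.5), (5) keep peptides with a lysine at a favorable
(adduct-accommodating) position, and (6) deduplicate sequences.  Every
emitted record carries per-filter pass flags so the funnel can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binder import PSSM, background_scores, is_strong_binder, percentile_rank
from .chem import read_fasta
from .mhc import AlleleModel

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "CANDIDATE_COLUMNS",
    "enumerate_kmers",
    "filter_overexpressed",
    "map_orthologs",
    "read_allele_frequencies_tsv",
    "read_expression_tsv",
    "read_orthologs_tsv",
    "screen_candidates",
    "select_hla_alleles",
    "write_candidates_tsv",
]

CANDIDATE_COLUMNS = [
    "protein", "start", "peptide", "lysine_positions", "fold_change",
    "binder_rank", "pass_expression", "pass_binder", "pass_lysine", "pass_all",
]

BG_STREAM = 7919  # sub-stream id for the background score sample


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the screening pipeline (defaults follow the screen design)."""

    target_tissue: str = "kidney"
    fold_threshold: float = 4.0
    denominator: str = "max"       # "max" (conservative) or "mean"
    rank_threshold: float = 0.5    # strong-binder percentile rank
    k: int = 9
    background_size: int = 100_000
    seed: int = 0


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_expression(df)
    return df


def _validate_expression(df: pd.DataFrame) -> None:
    required = {"protein", "tissue", "level"}
    if not required <= set(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if (df["level"] < 0).any():
        raise ValueError("expression levels must be >= 0")
    if df.duplicated(["protein", "tissue"]).any():
        dup = df[df.duplicated(["protein", "tissue"])].iloc[0]
        raise ValueError(
            f"duplicate (protein, tissue) pair: ({dup['protein']}, {dup['tissue']})")


def filter_overexpressed(
    expression: pd.DataFrame,
    target_tissue: str = "kidney",
    fold_threshold: float = 4.0,
    denominator: str = "max",
) -> tuple[set[str], dict[str, float]]:
    """Proteins overexpressed in ``target_tissue`` by strictly > ``fold_threshold``.

    Fold = level(target) / denominator over non-target tissues ("max" by
    default, the conservative tissue-enrichment convention; "mean" optional).
    A zero denominator with positive target level counts as infinite fold
    (pass).  Proteins missing the target-tissue row are excluded with a
    logged warning.  Returns (passing ids, fold for every evaluated protein).
    """
    _validate_expression(expression)
    if denominator not in ("max", "mean"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    passing: set[str] = set()
    folds: dict[str, float] = {}
    for protein, grp in expression.groupby("protein", sort=True):
        target_rows = grp.loc[grp["tissue"] == target_tissue, "level"]
        if target_rows.empty:
            logger.warning("protein %s has no %s row; excluded",
                           protein, target_tissue)
            continue
        target = float(target_rows.iloc[0])
        others = grp.loc[grp["tissue"] != target_tissue, "level"]
        denom = float(others.max() if denominator == "max" else others.mean()) \
            if not others.empty else 0.0
        if denom == 0.0:
            fold = np.inf if target > 0 else 0.0
        else:
            fold = target / denom
        folds[str(protein)] = fold
        if fold > fold_threshold:
            passing.add(str(protein))
    return passing, folds


def read_orthologs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"source", "target"} <= set(df.columns):
        raise ValueError("ortholog table needs columns source, target")
    return df


def map_orthologs(
    ids: Iterable[str],
    table: pd.DataFrame,
) -> tuple[set[str], set[str]]:
    """Map ids through an ortholog table; report unmapped ids, never drop
    them silently.  Many-to-one mappings are deduplicated.

    Returns (mapped target ids, dropped source ids).
    """
    mapping: dict[str, str] = dict(
        zip(table["source"].astype(str), table["target"].astype(str)))
    mapped: set[str] = set()
    dropped: set[str] = set()
    for i in ids:
        if i in mapping:
            mapped.add(mapping[i])
        else:
            dropped.add(i)
    if dropped:
        logger.warning("%d ids without orthologs: %s", len(dropped),
                       sorted(dropped))
    return mapped, dropped


def enumerate_kmers(sequence: str, k: int = 9) -> list[tuple[int, str]]:
    """All k-mer windows with 1-based start offsets, in order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [(i + 1, sequence[i:i + k])
            for i in range(len(sequence) - k + 1)]


def _source_folds(mouse_id: str, ortho: pd.DataFrame,
                  folds: Mapping[str, float]) -> float:
    sources = ortho.loc[ortho["target"].astype(str) == mouse_id, "source"]
    vals = [folds[s] for s in sources.astype(str) if s in folds]
    return max(vals) if vals else float("nan")


def screen_candidates(
    proteome: Mapping[str, str] | str | Path,
    expression: pd.DataFrame | str | Path,
    orthologs: pd.DataFrame | str | Path,
    allele: AlleleModel,
    pssm: PSSM,
    favorable: Iterable[int],
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the full candidate funnel; returns the candidate table.

    Emits one record per k-mer of every ortholog-mapped overexpressed protein
    present in the proteome, with per-filter flags; fully-passing records
    satisfy the binder-rank and favorable-lysine filters too.  Duplicate
    peptide sequences keep the first occurrence ordered by (protein, start).
    Deterministic given config (the seed only drives the background sample).
    """
    config = config or ScreenConfig()
    if isinstance(proteome, (str, Path)):
        proteome = read_fasta(proteome)
    if not proteome:
        raise ValueError("proteome is empty")
    if isinstance(expression, (str, Path)):
        expression = read_expression_tsv(expression)
    if isinstance(orthologs, (str, Path)):
        orthologs = read_orthologs_tsv(orthologs)
    favorable = set(int(x) for x in favorable)
    if not favorable:
        raise ValueError("favorable position set must be non-empty")
    if config.k not in allele.supported_lengths:
        raise ValueError(
            f"k={config.k} unsupported by allele {allele.name}")
    if pssm.length != config.k:
        raise ValueError(
            f"PSSM length {pssm.length} does not match k={config.k}")

    passing, folds = filter_overexpressed(
        expression, config.target_tissue, config.fold_threshold,
        config.denominator)
    logger.info("expression filter: %d/%d proteins pass",
                len(passing), len(folds))
    mapped, dropped = map_orthologs(sorted(passing), orthologs)
    logger.info("ortholog mapping: %d mapped, %d dropped", len(mapped),
                len(dropped))

    rng = np.random.default_rng([config.seed, BG_STREAM])
    bg = background_scores(pssm, n=config.background_size, rng=rng)

    from .binder import score_peptide

    rows = []
    for mouse_id in sorted(mapped & set(proteome)):
        fold = _source_folds(mouse_id, orthologs, folds)
        pass_expr = True  # emitted proteins already passed the funnel head
        for start, pep in enumerate_kmers(proteome[mouse_id], config.k):
            lys = {i for i, aa in enumerate(pep, start=1) if aa == "K"}
            rank = percentile_rank(score_peptide(pep, pssm), bg)
            pass_binder = is_strong_binder(rank, config.rank_threshold)
            pass_lys = bool(lys & favorable)
            rows.append((
                mouse_id, start, pep,
                ",".join(str(i) for i in sorted(lys)),
                fold, rank, pass_expr, pass_binder, pass_lys,
                pass_expr and pass_binder and pass_lys,
            ))
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df = df.sort_values(["protein", "start"], ignore_index=True)
    df = df.drop_duplicates("peptide", keep="first", ignore_index=True)
    logger.info("screen: %d records, %d fully passing", len(df),
                int(df["pass_all"].sum()))
    return df


def write_candidates_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic, byte-stable TSV writer for candidate tables."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_allele_frequencies_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"population", "allele", "frequency"}
    if not required <= set(df.columns):
        raise ValueError(f"frequency table needs columns {sorted(required)}")
    if ((df["frequency"] < 0) | (df["frequency"] > 1)).any():
        raise ValueError("phenotype frequencies must lie in [0, 1]")
    if df.duplicated(["population", "allele"]).any():
        raise ValueError("duplicate (population, allele) pair")
    return df


def select_hla_alleles(
    frequencies: pd.DataFrame,
    min_freq: float = 0.05,
    top_n: int = 10,
) -> tuple[list[str], dict[str, list[str]]]:
    """Per population: top ``top_n`` alleles with phenotype frequency
    strictly above ``min_freq``; union across populations, duplicates
    collapsed.  Ties break by allele name (lexicographic).

    Returns (sorted allele panel, allele -> contributing populations).
    """
    if frequencies.empty:
        raise ValueError("need at least one population")
    provenance: dict[str, list[str]] = {}
    for pop, grp in frequencies.groupby("population", sort=True):
        eligible = grp[grp["frequency"] > min_freq]
        ranked = eligible.sort_values(
            ["frequency", "allele"], ascending=[False, True])
        for allele in ranked["allele"].head(top_n):
            provenance.setdefault(str(allele), []).append(str(pop))
    return sorted(provenance), provenance
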
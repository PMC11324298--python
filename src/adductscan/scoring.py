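"""Surrogate scoring of peptide-MHC complexes and the delta-score statistic.

The all-atom refinement energy used in structure-based screening is replaced
here by a transparent surrogate whose only structural free parameter is the
allele's groove-exposure profile:

    per_position[i] = -pssm(i, aa_i) + penalty(i)
    penalty(i)      = kappa * bulk_weight * (1 - exposure[i])   (+ clash term)

Lower is more favourable, matching the convention that binders score lower.
An adduct at a fully exposed position (exposure = 1) costs nothing; at a
buried position it costs the full bulk penalty.  The optional clash term adds
``clash_weight`` per receptor pseudo-atom within ``clash_radius`` of the
position's backbone coordinate (off by default so results are closed-form).

Delta-score = score(adducted) - score(unadducted); under the surrogate this
equals the adduct penalty at the modified position exactly.  External
all-atom backends can be registered by name and plug into the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .binder import PSSM
from .chem import AdductRegistry, AdductSpecies, apply_adduct, default_registry
from .mhc import AlleleModel, ComplexModel

__all__ = [
    "ScoreReport",
    "SurrogateParams",
    "adduct_penalty",
    "delta_score",
    "register_backend",
    "registered_backends",
    "score_complex",
    "write_score_report_tsv",
]


@dataclass(frozen=True)
class SurrogateParams:
    """Tunable knobs of the surrogate scorer.

    kappa (``penalty_scale``) sets the cost, in score units, of placing an
    adduct of unit bulk at a fully buried position.
    """

    penalty_scale: float = 10.0
    clash_radius: float = 2.5
    clash_weight: float = 1.0
    clash_term_enabled: bool = False

    def __post_init__(self) -> None:
        if self.penalty_scale < 0:
            raise ValueError("penalty_scale must be >= 0")
        if self.clash_radius <= 0:
            raise ValueError("clash_radius must be > 0")
        if self.clash_weight < 0:
            raise ValueError("clash_weight must be >= 0")


@dataclass(frozen=True)
class ScoreReport:
    """Total surrogate score with its per-position decomposition."""

    total: float
    per_position: np.ndarray
    backend: str
    adducted: bool
    adduct_position: int | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        per = np.asarray(self.per_position, dtype=float)
        per.setflags(write=False)
        object.__setattr__(self, "per_position", per)
        if abs(self.total - per.sum()) > 1e-9:
            raise ValueError("total must equal the sum of per_position entries")


Backend = Callable[
    [ComplexModel, AlleleModel, "PSSM | None", SurrogateParams, AdductRegistry],
    ScoreReport,
]

_BACKENDS: dict[str, Backend] = {}


def register_backend(name: str, fn: Backend) -> None:
    """Register a scoring backend under a unique name."""
    if name in _BACKENDS:
        raise ValueError(f"backend {name!r} already registered")
    _BACKENDS[name] = fn


def registered_backends() -> list[str]:
    return sorted(_BACKENDS)


def _clash_count(position: int, model: ComplexModel,
                 params: SurrogateParams) -> int:
    if model.backbone is None:
        raise ValueError("clash term requires a backbone; model has none")
    if model.receptor_atoms.size == 0:
        return 0
    d = np.linalg.norm(
        model.receptor_atoms[:, :3] - model.backbone[position - 1], axis=1)
    return int(np.count_nonzero(d <= params.clash_radius))


def adduct_penalty(
    position: int,
    species: AdductSpecies,
    allele: AlleleModel,
    params: SurrogateParams | None = None,
    model: ComplexModel | None = None,
    length: int | None = None,
) -> float:
    """Accommodation penalty for an adduct at 1-based ``position``.

    penalty = kappa * bulk_weight * (1 - exposure[position]), plus the clash
    term when enabled (requires ``model`` with a backbone).
    """
    params = params or SurrogateParams()
    if length is None:
        if model is None:
            raise ValueError("need model or explicit peptide length")
        length = len(model.peptide)
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside [1, {length}]")
    exposure = allele.exposure_at(length, position)
    penalty = params.penalty_scale * species.bulk_weight * (1.0 - exposure)
    if params.clash_term_enabled:
        penalty += params.clash_weight * _clash_count(position, model, params)
    return penalty


def _surrogate_backend(
    model: ComplexModel,
    allele: AlleleModel,
    pssm: PSSM | None,
    params: SurrogateParams,
    registry: AdductRegistry,
) -> ScoreReport:
    pep = model.peptide
    length = len(pep)
    per = np.zeros(length)
    for i, aa in enumerate(pep.sequence, start=1):
        binding = -pssm.entry(i, aa) if pssm is not None else 0.0
        pen = 0.0
        if i in pep.modifications:
            species = registry.get(pep.modifications[i])
            pen = adduct_penalty(i, species, allele, params, model=model,
                                 length=length)
        per[i - 1] = binding + pen
    mods = sorted(pep.modifications)
    return ScoreReport(
        total=float(per.sum()),
        per_position=per,
        backend="surrogate",
        adducted=bool(mods),
        adduct_position=mods[0] if mods else None,
        species=pep.modifications[mods[0]] if mods else None,
    )


register_backend("surrogate", _surrogate_backend)


def score_complex(
    model: ComplexModel,
    allele: AlleleModel,
    pssm: PSSM | None = None,
    params: SurrogateParams | None = None,
    backend: str = "surrogate",
    registry: AdductRegistry | None = None,
    n_models: int | None = None,
    top_k: int | None = None,
) -> ScoreReport:
    """Score one peptide-MHC complex with the named backend.

    ``n_models``/``top_k`` mirror ensemble-and-average protocols of external
    all-atom backends; the surrogate is deterministic, so they are accepted
    and ignored (results are identical for any setting).
    """
    if len(model.peptide) not in allele.supported_lengths:
        raise ValueError(
            f"peptide length {len(model.peptide)} unsupported by allele "
            f"{allele.name} (supports {sorted(allele.supported_lengths)})")
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown backend {backend!r}; registered: {registered_backends()}"
        ) from None
    params = params or SurrogateParams()
    registry = registry or default_registry()
    return fn(model, allele, pssm, params, registry)


def delta_score(
    model: ComplexModel,
    position: int,
    species: AdductSpecies | str,
    allele: AlleleModel,
    pssm: PSSM | None = None,
    params: SurrogateParams | None = None,
    backend: str = "surrogate",
    registry: AdductRegistry | None = None,
) -> float:
    """Score change on in-silico adduction at lysine ``position``.

    delta = score(adducted).total - score(unadducted).total.  Nonnegative
    under the surrogate; zero iff the position is fully exposed (and
    clash-free when the clash term is on).
    """
    registry = registry or default_registry()
    name = species.name if isinstance(species, AdductSpecies) else species
    adducted = apply_adduct(model.peptide, position, registry.get(name))
    model_ad = replace(model, peptide=adducted)
    before = score_complex(model, allele, pssm, params, backend, registry)
    after = score_complex(model_ad, allele, pssm, params, backend, registry)
    return after.total - before.total


def write_score_report_tsv(report: ScoreReport, path: str | Path) -> None:
    """One row per position plus a totals row."""
    with open(path, "w") as fh:
        fh.write("position\tscore\n")
        for i, x in enumerate(report.per_position, start=1):
            fh.write(f"{i}\t{x:.10g}\n")
        fh.write(f"total\t{report.total:.10g}\n")
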
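"""MHC-I allele models, peptide-MHC structure templates, and threading.

An :class:`AlleleModel` abstracts one class I molecule: which peptide lengths
it binds, which positions are pocket anchors, and a per-position groove
exposure profile in [0, 1] (1 = fully solvent-exposed / TCR-facing, 0 = fully
buried).  Exposure is the structural driver of adduct accommodation in the
surrogate scorer.

Templates are solved peptide-MHC complexes read from a minimal PDB dialect
(ATOM records only; the peptide chain selected by chain id, default "C").
Threading copies a template's peptide backbone and swaps in the query
sequence, mirroring template-based peptide modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import AMINO_ACIDS, Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleModel",
    "ComplexModel",
    "TemplateEntry",
    "TemplateLibrary",
    "alignment_score",
    "blosum62",
    "default_h2db",
    "default_h2kb",
    "load_template_library",
    "read_alleles_tsv",
    "select_template",
    "thread_peptide",
    "write_alleles_tsv",
]


@dataclass(frozen=True)
class AlleleModel:
    """One MHC-I variant.

    ``anchors`` and ``exposure`` are keyed by peptide length; exposure vectors
    have one entry per position, each in [0, 1].  ``pssm_id`` names the
    position-specific scoring matrix used for binding prediction.
    """

    name: str
    supported_lengths: frozenset[int]
    anchors: Mapping[int, frozenset[int]]
    exposure: Mapping[int, tuple[float, ...]]
    pssm_id: str | None = None

    def __post_init__(self) -> None:
        lengths = frozenset(int(x) for x in self.supported_lengths)
        if not lengths or not all(8 <= l <= 10 for l in lengths):
            raise ValueError(f"supported lengths must lie in [8, 10], got {lengths}")
        anchors = {int(l): frozenset(int(a) for a in v)
                   for l, v in self.anchors.items()}
        exposure = {int(l): tuple(float(e) for e in v)
                    for l, v in self.exposure.items()}
        for l in lengths:
            if l not in exposure:
                raise ValueError(f"missing exposure profile for length {l}")
            if len(exposure[l]) != l:
                raise ValueError(
                    f"exposure profile for length {l} has {len(exposure[l])} entries")
            if not all(0.0 <= e <= 1.0 for e in exposure[l]):
                raise ValueError(f"exposure values must lie in [0, 1] for length {l}")
            if not anchors.get(l, frozenset()) <= set(range(1, l + 1)):
                raise ValueError(f"anchors for length {l} outside [1, {l}]")
        object.__setattr__(self, "supported_lengths", lengths)
        object.__setattr__(self, "anchors", anchors)
        object.__setattr__(self, "exposure", exposure)

    def exposure_at(self, length: int, pos: int) -> float:
        """Exposure at 1-based ``pos`` for a peptide of ``length``."""
        return self.exposure[length][pos - 1]


def _profile(length: int, anchors: set[int], exposed: set[int],
             anchor_exp: float = 0.1, exposed_exp: float = 1.0,
             other_exp: float = 0.5) -> tuple[float, ...]:
    out = []
    for i in range(1, length + 1):
        if i in anchors:
            out.append(anchor_exp)
        elif i in exposed:
            out.append(exposed_exp)
        else:
            out.append(other_exp)
    return tuple(out)


def default_h2db() -> AlleleModel:
    """Default H-2Db model: 9-mers, anchors P5/P9, TCR-exposed P4/P6/P7.

    These profiles are configuration defaults, not measured accessibilities;
    override via :func:`read_alleles_tsv` for real work.
    """
    return AlleleModel(
        name="H-2Db",
        supported_lengths=frozenset({9}),
        anchors={9: frozenset({5, 9})},
        exposure={9: _profile(9, {5, 9}, {4, 6, 7})},
        pssm_id="H-2Db",
    )


def default_h2kb() -> AlleleModel:
    """Default H-2Kb model: 8-mers, anchors P5/P8, restrictive groove."""
    return AlleleModel(
        name="H-2Kb",
        supported_lengths=frozenset({8}),
        anchors={8: frozenset({5, 8})},
        exposure={8: _profile(8, {5, 8}, set(), other_exp=0.4)},
        pssm_id="H-2Kb",
    )


def read_alleles_tsv(path: str | Path) -> dict[str, AlleleModel]:
    """Read allele definitions (name, length, anchors, exposure) from TSV.

    Columns: ``name`` ``length`` ``anchors`` (comma-separated 1-based)
    ``exposure`` (comma-separated floats, one per position).  Multiple rows
    with the same name define profiles for multiple lengths.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, AlleleModel] = {}
    for name, grp in df.groupby("name", sort=False):
        lengths, anchors, exposure = set(), {}, {}
        for _, row in grp.iterrows():
            l = int(row["length"])
            lengths.add(l)
            anchors[l] = frozenset(
                int(a) for a in str(row["anchors"]).split(",") if a.strip())
            exposure[l] = tuple(float(e) for e in str(row["exposure"]).split(","))
        out[str(name)] = AlleleModel(str(name), frozenset(lengths), anchors, exposure)
    return out


def write_alleles_tsv(alleles: Iterable[AlleleModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tlength\tanchors\texposure\n")
        for a in alleles:
            for l in sorted(a.supported_lengths):
                anch = ",".join(str(x) for x in sorted(a.anchors.get(l, ())))
                expo = ",".join(f"{e:.6g}" for e in a.exposure[l])
                fh.write(f"{a.name}\t{l}\t{anch}\t{expo}\n")


@dataclass(frozen=True)
class TemplateEntry:
    """One solved peptide-MHC complex usable as a threading template."""

    template_id: str
    peptide_sequence: str
    backbone: np.ndarray          # (L, 3) peptide CA coordinates, Angstrom
    receptor_atoms: np.ndarray    # (M, 4) pseudo-atom x, y, z, radius

    def __post_init__(self) -> None:
        bb = np.asarray(self.backbone, dtype=float)
        ra = np.asarray(self.receptor_atoms, dtype=float).reshape(-1, 4)
        if bb.shape != (len(self.peptide_sequence), 3):
            raise ValueError(
                f"template {self.template_id}: backbone shape {bb.shape} does not "
                f"match peptide length {len(self.peptide_sequence)}")
        bb.setflags(write=False)
        ra.setflags(write=False)
        object.__setattr__(self, "backbone", bb)
        object.__setattr__(self, "receptor_atoms", ra)


class TemplateLibrary:
    """Templates keyed by unique id."""

    def __init__(self, entries: Iterable[TemplateEntry] = ()) -> None:
        self._entries: dict[str, TemplateEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: TemplateEntry) -> None:
        if entry.template_id in self._entries:
            raise ValueError(f"duplicate template id {entry.template_id!r}")
        self._entries[entry.template_id] = entry

    def entries(self) -> list[TemplateEntry]:
        return [self._entries[k] for k in sorted(self._entries)]

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, template_id: str) -> TemplateEntry:
        return self._entries[template_id]


def _one_letter(resname: str) -> str | None:
    import gemmi

    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in AMINO_ACIDS else None


def load_template_library(
    paths: Iterable[str | Path],
    peptide_chain: str = "C",
    receptor_radius: float = 2.0,
) -> TemplateLibrary:
    """Build a template library from minimal-dialect PDB files.

    Only ATOM records are honoured.  Per entry, the peptide chain is the one
    matching ``peptide_chain``; every peptide residue must have a CA record
    and no altloc or insertion code.  Receptor pseudo-atoms are the CA centres
    of all other chains with a uniform ``receptor_radius``.  Entries failing
    validation are skipped with a logged reason; zero valid entries is an
    error, as is a duplicate template id (the file stem).
    """
    import gemmi

    lib = TemplateLibrary()
    n_seen = 0
    for path in paths:
        path = Path(path)
        n_seen += 1
        template_id = path.stem
        try:
            entry = _parse_template(path, template_id, peptide_chain,
                                    receptor_radius)
        except ValueError as exc:
            logger.warning("skipping template %s: %s", path, exc)
            continue
        lib.add(entry)
    if n_seen == 0 or len(lib) == 0:
        raise ValueError("no valid template entries loaded")
    return lib


def _parse_template(path: Path, template_id: str, peptide_chain: str,
                    receptor_radius: float) -> TemplateEntry:
    import gemmi

    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise ValueError("no models in file")
    model = structure[0]
    pep_seq: list[str] = []
    pep_xyz: list[tuple[float, float, float]] = []
    receptor: list[tuple[float, float, float, float]] = []
    found_pep = False
    for chain in model:
        is_pep = chain.name == peptide_chain
        if is_pep:
            found_pep = True
        for res in chain:
            if res.het_flag != "A":  # minimal dialect: ATOM records only
                continue
            if res.seqid.icode not in ("", " "):
                raise ValueError(
                    f"insertion code on residue {res.seqid.num} ({chain.name})")
            ca = None
            for atom in res:
                if atom.altloc not in ("", "\0", " "):
                    raise ValueError(
                        f"altloc on atom {atom.name} of residue {res.seqid.num}")
                if atom.name == "CA":
                    ca = atom
            if ca is None:
                if is_pep:
                    raise ValueError(
                        f"peptide residue {res.seqid.num} lacks a CA record")
                continue
            if is_pep:
                code = _one_letter(res.name)
                if code is None:
                    raise ValueError(f"non-canonical peptide residue {res.name}")
                pep_seq.append(code)
                pep_xyz.append((ca.pos.x, ca.pos.y, ca.pos.z))
            else:
                receptor.append((ca.pos.x, ca.pos.y, ca.pos.z, receptor_radius))
    if not found_pep or not pep_seq:
        raise ValueError(f"no peptide chain {peptide_chain!r} with residues")
    return TemplateEntry(
        template_id=template_id,
        peptide_sequence="".join(pep_seq),
        backbone=np.array(pep_xyz, dtype=float),
        receptor_atoms=np.array(receptor, dtype=float).reshape(-1, 4),
    )


_BLOSUM62 = None


def blosum62():
    """The published BLOSUM62 substitution matrix (via Biopython's copy)."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def alignment_score(a: str, b: str, matrix=None) -> float:
    """Ungapped position-wise substitution score of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    matrix = matrix if matrix is not None else blosum62()
    return float(sum(matrix[x, y] for x, y in zip(a, b)))


def select_template(
    query: str | Peptide,
    lib: TemplateLibrary,
    matrix=None,
) -> tuple[TemplateEntry, float]:
    """Best same-length template by ungapped substitution score.

    Length-mismatched templates are excluded; ties broken by lexicographically
    smallest template id.  MHC-I peptides of equal length sit end-to-end in
    the closed groove, so scoring is gapless by design.
    """
    seq = query.sequence if isinstance(query, Peptide) else query
    if len(lib) == 0:
        raise ValueError("template library is empty")
    matrix = matrix if matrix is not None else blosum62()
    best: tuple[float, str] | None = None
    best_entry: TemplateEntry | None = None
    for entry in lib.entries():  # sorted by id: first max wins ties
        if len(entry.peptide_sequence) != len(seq):
            continue
        score = alignment_score(seq, entry.peptide_sequence, matrix)
        if best is None or score > best[0]:
            best = (score, entry.template_id)
            best_entry = entry
    if best_entry is None:
        raise ValueError(f"no template of length {len(seq)} in library")
    return best_entry, best[0]


@dataclass(frozen=True)
class ComplexModel:
    """A peptide threaded onto a template backbone inside an MHC groove.

    ``backbone`` may be None for structure-free surrogate scoring (the clash
    term then cannot be evaluated).
    """

    peptide: Peptide
    backbone: np.ndarray | None
    receptor_atoms: np.ndarray
    template_id: str
    allele: str | None = None

    def __post_init__(self) -> None:
        ra = np.asarray(self.receptor_atoms, dtype=float).reshape(-1, 4)
        ra.setflags(write=False)
        object.__setattr__(self, "receptor_atoms", ra)
        if self.backbone is not None:
            bb = np.asarray(self.backbone, dtype=float)
            if bb.shape != (len(self.peptide), 3):
                raise ValueError(
                    f"backbone shape {bb.shape} does not match peptide length "
                    f"{len(self.peptide)}")
            bb.setflags(write=False)
            object.__setattr__(self, "backbone", bb)


def thread_peptide(template: TemplateEntry, query: Peptide | str,
                   allele: str | None = None) -> ComplexModel:
    """Thread ``query`` onto ``template``: copy the backbone, swap residues."""
    pep = query if isinstance(query, Peptide) else Peptide(query)
    if len(pep) != len(template.peptide_sequence):
        raise ValueError(
            f"query length {len(pep)} does not match template "
            f"{template.template_id} length {len(template.peptide_sequence)}")
    return ComplexModel(
        peptide=pep,
        backbone=template.backbone.copy(),
        receptor_atoms=template.receptor_atoms.copy(),
        template_id=template.template_id,
        allele=allele,
    )
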
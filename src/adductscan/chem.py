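"""Peptide sequences, lysine-adduct chemistry, and monoisotopic mass / m/z.

Positions are 1-based throughout (immunology P1..P9 convention).

Isolevuglandins (IsoLGs, C20H32O4) are lipid-peroxidation electrophiles that
condense with lysine epsilon-amines to form a family of covalent adducts
(pyrrole and oxidized-pyrrole species).  The shipped adduct registry carries
placeholder elemental deltas derived from that condensation series; the real
chemotype compositions are a user-editable chemistry config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "AMINO_ACIDS",
    "AdductRegistry",
    "AdductSpecies",
    "ElementTable",
    "Peptide",
    "apply_adduct",
    "default_registry",
    "format_peptide",
    "load_chemistry",
    "monoisotopic_mass",
    "parse_peptide",
    "precursor_mz",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Standard residue (amino acid minus water) elemental compositions.
RESIDUE_FORMULAS: Mapping[str, Mapping[str, int]] = MappingProxyType({
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
})

WATER = {"H": 2, "O": 1}
ACETYL = {"C": 2, "H": 2, "O": 1}  # N-terminal acetylation delta


@dataclass(frozen=True)
class ElementTable:
    """Monoisotopic element masses (Da) plus the proton mass."""

    masses: Mapping[str, float]
    proton: float = 1.00727646688

    def __post_init__(self) -> None:
        for sym, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"element {sym!r} has non-positive mass {m}")
        if self.proton <= 0:
            raise ValueError("proton mass must be positive")

    @classmethod
    def default(cls) -> "ElementTable":
        return cls(masses=MappingProxyType({
            "H": 1.00782503207,
            "C": 12.0,
            "N": 14.0030740048,
            "O": 15.9949146196,
            "S": 31.97207100,
        }))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ElementTable":
        data = yaml.safe_load(Path(path).read_text())
        proton = float(data.pop("proton", 1.00727646688))
        return cls(masses={str(k): float(v) for k, v in data.items()}, proton=proton)

    def formula_mass(self, formula: Mapping[str, int | float]) -> float:
        """Mass of a (possibly signed) element->count composition."""
        total = 0.0
        for sym, count in formula.items():
            try:
                total += self.masses[sym] * count
            except KeyError:
                raise KeyError(f"element {sym!r} not in element table") from None
        return total


@dataclass(frozen=True)
class AdductSpecies:
    """A named lysine-adduct chemotype.

    ``elemental_delta`` is the signed element->count change of the modified
    residue relative to unmodified lysine; ``bulk_weight`` is a unitless
    accommodation-penalty weight used by the surrogate scorer.
    """

    name: str
    elemental_delta: Mapping[str, int]
    bulk_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.bulk_weight < 0:
            raise ValueError(f"bulk_weight must be >= 0, got {self.bulk_weight}")
        object.__setattr__(self, "elemental_delta",
                           MappingProxyType(dict(self.elemental_delta)))


class AdductRegistry:
    """Registry of adduct species with unique names."""

    def __init__(self, species: Iterable[AdductSpecies] = ()) -> None:
        self._species: dict[str, AdductSpecies] = {}
        for s in species:
            self.add(s)

    def add(self, species: AdductSpecies) -> None:
        if species.name in self._species:
            raise ValueError(f"adduct species {species.name!r} already registered")
        self._species[species.name] = species

    def get(self, name: str) -> AdductSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise KeyError(
                f"unknown adduct species {name!r}; registered: {sorted(self._species)}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self._species)

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def __iter__(self) -> Iterator[AdductSpecies]:
        return iter(self._species.values())


def default_registry() -> AdductRegistry:
    """The four IsoLG-lysine chemotypes with placeholder compositions.

    Deltas follow the IsoLG (C20H32O4) + lysine condensation series: the
    Paal-Knorr pyrrole loses two waters (C20H28O2); the lactam is the oxidized
    pyrrole (+O); the anhydro species each lose a further water.  These are
    documented placeholders, not literature ground truth; override via
    :func:`load_chemistry`.
    """
    return AdductRegistry([
        AdductSpecies("pyrrole", {"C": 20, "H": 28, "O": 2}),
        AdductSpecies("lactam", {"C": 20, "H": 28, "O": 3}),
        AdductSpecies("anhydropyrrole", {"C": 20, "H": 26, "O": 1}),
        AdductSpecies("anhydrolactam", {"C": 20, "H": 26, "O": 2}),
    ])


def load_chemistry(path: str | Path) -> AdductRegistry:
    """Load an adduct registry from a YAML chemistry config.

    Format::

        pyrrole:
          delta: {C: 20, H: 28, O: 2}
          bulk_weight: 1.0
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or not data:
        raise ValueError(f"chemistry config {path} is empty or malformed")
    species = []
    for name, entry in data.items():
        delta = {str(k): int(v) for k, v in entry["delta"].items()}
        species.append(AdductSpecies(str(name), delta,
                                     float(entry.get("bulk_weight", 1.0))))
    return AdductRegistry(species)


@dataclass(frozen=True)
class Peptide:
    """A validated peptide with optional per-position lysine modifications.

    ``modifications`` maps 1-based position -> adduct species name; every
    modified position must hold a lysine.  N-terminal acetylation is a
    peptide-level flag (it is applied uniformly during synthesis, not at a
    residue position).
    """

    sequence: str
    n_terminal_acetyl: bool = False
    modifications: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i}")
        for pos in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside [1, {len(self.sequence)}]")
            if self.sequence[pos - 1] != "K":
                raise ValueError(
                    f"modification at position {pos} addresses "
                    f"{self.sequence[pos - 1]!r}, not lysine")
        object.__setattr__(self, "modifications",
                           MappingProxyType(dict(self.modifications)))

    def __len__(self) -> int:
        return len(self.sequence)

    def lysine_positions(self) -> set[int]:
        """1-based positions of every lysine in the sequence."""
        return {i for i, aa in enumerate(self.sequence, start=1) if aa == "K"}

    def modification_at(self, pos: int) -> str | None:
        return self.modifications.get(pos)

    def to_string(self) -> str:
        return format_peptide(self)


_ANNOT_RE = re.compile(r"\[([^\]]*)\]")


def parse_peptide(text: str, acetylated: bool = False) -> Peptide:
    """Parse plain or annotated peptide text into a :class:`Peptide`.

    Accepts a bare sequence (``LAGKNLTHI``) or the annotated form produced by
    :func:`format_peptide` (``Ac-LAGK[pyrrole]NLTHI``).  ``acetylated`` forces
    the N-terminal acetyl flag on; an ``Ac-`` prefix does the same.
    """
    if not text:
        raise ValueError("peptide text must be non-empty")
    if text.startswith("Ac-"):
        acetylated = True
        text = text[3:]
    seq_chars: list[str] = []
    mods: dict[int, str] = {}
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            m = _ANNOT_RE.match(text, i)
            if m is None:
                raise ValueError(f"unterminated modification annotation at index {i}")
            if not seq_chars:
                raise ValueError("modification annotation before any residue")
            pos = len(seq_chars)
            if pos in mods:
                raise ValueError(f"multiple modifications at position {pos}")
            mods[pos] = m.group(1)
            i = m.end()
            continue
        seq_chars.append(ch)
        i += 1
    return Peptide("".join(seq_chars), n_terminal_acetyl=acetylated,
                   modifications=mods)


def format_peptide(p: Peptide) -> str:
    """Serialize a peptide so that parse(format(p)) round-trips exactly."""
    out = ["Ac-"] if p.n_terminal_acetyl else []
    for i, aa in enumerate(p.sequence, start=1):
        out.append(aa)
        if i in p.modifications:
            out.append(f"[{p.modifications[i]}]")
    return "".join(out)


def apply_adduct(p: Peptide, pos: int, species: AdductSpecies | str) -> Peptide:
    """Return a copy of ``p`` with ``species`` recorded at lysine ``pos``.

    Raises if the target residue is not lysine or is already modified.
    """
    name = species.name if isinstance(species, AdductSpecies) else species
    if not 1 <= pos <= len(p):
        raise ValueError(f"position {pos} outside [1, {len(p)}]")
    if p.sequence[pos - 1] != "K":
        raise ValueError(
            f"cannot adduct {p.sequence[pos - 1]!r} at position {pos}: "
            "adduction targets lysine")
    if pos in p.modifications:
        raise ValueError(f"position {pos} already carries {p.modifications[pos]!r}")
    mods = dict(p.modifications)
    mods[pos] = name
    return replace(p, modifications=mods)


def monoisotopic_mass(
    p: Peptide,
    table: ElementTable | None = None,
    registry: AdductRegistry | None = None,
) -> float:
    """Monoisotopic mass in Da.

    mass = sum(residue masses) + water + acetyl delta (if flagged)
         + sum of the elemental deltas of all recorded modifications.
    """
    table = table or ElementTable.default()
    registry = registry or default_registry()
    mass = table.formula_mass(WATER)
    for aa in p.sequence:
        mass += table.formula_mass(RESIDUE_FORMULAS[aa])
    if p.n_terminal_acetyl:
        mass += table.formula_mass(ACETYL)
    for name in p.modifications.values():
        mass += table.formula_mass(registry.get(name).elemental_delta)
    return mass


def precursor_mz(
    p: Peptide,
    z: int,
    table: ElementTable | None = None,
    registry: AdductRegistry | None = None,
) -> float:
    """Precursor m/z at charge ``z``: (M + z * proton) / z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    table = table or ElementTable.default()
    return (monoisotopic_mass(p, table, registry) + z * table.proton) / z


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write id -> sequence pairs as FASTA (fixed line width, stable order)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
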
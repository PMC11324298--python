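import numpy as np
import pytest

from adductscan.chem import ElementTable, default_registry

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _atom_line(serial, name, resname, chain, resseq, x, y, z,
               altloc=" ", icode=" "):
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {name.strip()[0]:>2s}\n")


def write_template_pdb(path, peptide_seq, chain="C", receptor_coords=(),
                       altloc_at=None, skip_ca_at=None, icode_at=None):
    """Write a minimal peptide-MHC PDB: CA trace for the peptide chain plus
    optional receptor CA pseudo-atoms on chain A.  The *_at knobs inject
    validation defects at a 1-based peptide residue."""
    lines = []
    serial = 1
    for i, aa in enumerate(peptide_seq, start=1):
        if skip_ca_at == i:
            lines.append(_atom_line(serial, "N", AA3[aa], chain, i,
                                    float(i), 0.0, 0.0))
            serial += 1
            continue
        altloc = "A" if altloc_at == i else " "
        icode = "A" if icode_at == i else " "
        lines.append(_atom_line(serial, "CA", AA3[aa], chain, i,
                                float(i), 0.0, 0.0, altloc=altloc, icode=icode))
        serial += 1
    for j, (x, y, z) in enumerate(receptor_coords, start=1):
        lines.append(_atom_line(serial, "CA", "GLY", "A", j, x, y, z))
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def element_table():
    return ElementTable.default()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
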
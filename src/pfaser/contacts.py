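"""Ligand-residue contact analysis on receptor-ligand complexes.

A residue is "in contact" when any of its atoms lies within a distance
cutoff (5 Å by default, the conventional binding-site radius in docking
analysis) of any ligand atom; all atoms participate, hydrogens included
when present.  Contact sets across a panel of complexes aggregate into
per-residue-type frequencies, and interacting residues export to FASTA
(one record per complex, one-letter codes in residue-number order).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.SeqUtils import seq1
from scipy.spatial.distance import cdist

__all__ = [
    "WATER_NAMES",
    "ResidueContact",
    "ComplexStructure",
    "ContactProfile",
    "parse_complex",
    "write_pdb",
    "find_contacts",
    "atom_pair_counts",
    "aggregate_frequencies",
    "export_fasta",
]

#: Residue names treated as solvent, never as the ligand.
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

_ATOM_COLUMNS = [
    "atom_name",
    "element",
    "x",
    "y",
    "z",
    "resname",
    "resseq",
    "chain",
    "is_ligand",
]


class ResidueContact(NamedTuple):
    chain: str
    resseq: int
    resname: str


@dataclass
class ComplexStructure:
    """Atom table of one receptor-ligand complex.

    ``atoms`` columns: atom_name, element, x, y, z (Å), resname, resseq,
    chain, is_ligand.  Must contain at least one ligand atom and one
    receptor atom to support contact analysis.
    """

    atoms: pd.DataFrame
    complex_id: str = "complex"

    def __post_init__(self) -> None:
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite atom coordinates")

    @property
    def ligand_atoms(self) -> pd.DataFrame:
        return self.atoms[self.atoms["is_ligand"]]

    @property
    def receptor_atoms(self) -> pd.DataFrame:
        return self.atoms[~self.atoms["is_ligand"]]


def _flag_ligand(
    df: pd.DataFrame,
    ligand_resname: str | None = None,
    ligand_chain: str | None = None,
    hetero: pd.Series | None = None,
) -> pd.Series:
    if ligand_resname is not None:
        return df["resname"] == ligand_resname
    if ligand_chain is not None:
        return df["chain"] == ligand_chain
    if hetero is None:
        raise ValueError("no ligand selector and no HETATM information")
    return hetero & ~df["resname"].isin(WATER_NAMES)


def parse_complex(
    pdb: str,
    complex_id: str = "complex",
    ligand_resname: str | None = None,
    ligand_chain: str | None = None,
) -> ComplexStructure:
    """Parse PDB text (or a path to a .pdb/.pdbqt file) into an atom table.

    The ligand is identified as the HETATM records that are not solvent,
    unless a residue name or chain is given explicitly.  PDBQT content is
    tolerated: only the fixed PDB columns are read.  Malformed coordinate
    fields raise with the offending line number.
    """
    text = pdb
    if "\n" not in pdb and (pdb.endswith(".pdb") or pdb.endswith(".pdbqt")):
        with open(pdb) as fh:
            text = fh.read()
    # pre-scan for coordinate validity so errors carry a line number
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError):
                raise ValueError(
                    f"malformed coordinates on line {lineno}: {line!r}"
                ) from None
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(complex_id, io.StringIO(text))
    rows, het = [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                hetfield = residue.id[0]
                for atom in residue:
                    x, y, z = atom.coord
                    rows.append(
                        {
                            "atom_name": atom.get_name(),
                            "element": (atom.element or "").strip() or atom.get_name()[0],
                            "x": float(x),
                            "y": float(y),
                            "z": float(z),
                            "resname": residue.get_resname().strip(),
                            "resseq": int(residue.id[1]),
                            "chain": chain.id,
                            "is_ligand": False,
                        }
                    )
                    het.append(hetfield != " " and not hetfield.startswith("W"))
        break  # first model only
    if not rows:
        raise ValueError("no ATOM/HETATM records found")
    df = pd.DataFrame(rows)
    df["is_ligand"] = _flag_ligand(
        df, ligand_resname, ligand_chain, hetero=pd.Series(het)
    )
    if not df["is_ligand"].any():
        raise ValueError(
            "no ligand atoms found (no non-solvent HETATM records and no "
            "ligand selector given)"
        )
    return ComplexStructure(df, complex_id)


def write_pdb(complex_: ComplexStructure) -> str:
    """Serialize an atom table back to PDB text (ligand as HETATM)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(complex_.complex_id)
    builder.init_model(0)
    serial = 1
    current_chain = None
    current_res = None
    for _, row in complex_.atoms.iterrows():
        if row["chain"] != current_chain:
            builder.init_chain(row["chain"])
            builder.init_seg("    ")
            current_chain = row["chain"]
            current_res = None
        hetfield = "H_" + row["resname"] if row["is_ligand"] else " "
        res_key = (hetfield, int(row["resseq"]), row["resname"])
        if res_key != current_res:
            builder.init_residue(row["resname"], hetfield, int(row["resseq"]), " ")
            current_res = res_key
        builder.init_atom(
            row["atom_name"],
            np.array([row["x"], row["y"], row["z"]], dtype=float),
            0.0,
            1.0,
            " ",
            row["atom_name"].ljust(4)[:4],
            serial,
            element=row["element"],
        )
        serial += 1
    out = io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    pdbio.save(out)
    return out.getvalue()


def _contact_distances(complex_: ComplexStructure) -> pd.DataFrame:
    lig = complex_.ligand_atoms
    rec = complex_.receptor_atoms
    if lig.empty:
        raise ValueError("complex has no ligand atoms")
    if rec.empty:
        raise ValueError("complex has no receptor atoms")
    d = cdist(
        rec[["x", "y", "z"]].to_numpy(dtype=float),
        lig[["x", "y", "z"]].to_numpy(dtype=float),
    )
    out = rec[["chain", "resseq", "resname"]].copy()
    out["min_dist"] = d.min(axis=1)
    return out, d


def find_contacts(
    complex_: ComplexStructure, cutoff: float = 5.0
) -> list[ResidueContact]:
    """Residues with any atom within ``cutoff`` Å of any ligand atom.

    The boundary is inclusive (distance == cutoff counts as contact).
    Returns residue instances sorted by (chain, residue number).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    per_atom, _ = _contact_distances(complex_)
    near = per_atom[per_atom["min_dist"] <= cutoff]
    residues = {
        ResidueContact(str(c), int(r), str(n))
        for c, r, n in zip(near["chain"], near["resseq"], near["resname"])
    }
    return sorted(residues, key=lambda rc: (rc.chain, rc.resseq))


def atom_pair_counts(
    complex_: ComplexStructure, cutoff: float = 5.0
) -> pd.Series:
    """Per-residue-type count of (ligand atom, residue atom) pairs within
    the cutoff — the finest-grained contact-counting convention."""
    per_atom, d = _contact_distances(complex_)
    within = (d <= cutoff).sum(axis=1)
    per_atom = per_atom.assign(pairs=within)
    counts = per_atom.groupby("resname")["pairs"].sum()
    return counts[counts > 0].astype(int).sort_values(ascending=False)


@dataclass
class ContactProfile:
    """Residue-type contact counts and percentages across complexes."""

    counts: pd.Series
    percentages: pd.Series

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def aggregate_frequencies(
    contact_sets: Sequence[Iterable[ResidueContact]],
    mode: str = "instances",
) -> ContactProfile:
    """Aggregate per-complex contact sets into residue-type frequencies.

    ``mode="instances"`` counts each contacted residue instance once per
    complex (a type contacted via two residues in one complex counts 2);
    ``mode="presence"`` counts a type at most once per complex.  With no
    contacts anywhere the profile is empty and percentages are omitted.
    """
    if len(contact_sets) < 1:
        raise ValueError("need at least one complex")
    counter: Counter[str] = Counter()
    for contacts in contact_sets:
        names = [rc.resname for rc in contacts]
        if mode == "presence":
            names = sorted(set(names))
        elif mode != "instances":
            raise ValueError("mode must be 'instances' or 'presence'")
        counter.update(names)
    counts = pd.Series(counter, dtype=int).sort_values(ascending=False)
    if counts.empty:
        return ContactProfile(
            pd.Series(dtype=int), pd.Series(dtype=float)
        )
    pct = counts / counts.sum() * 100.0
    return ContactProfile(counts, pct)


def export_fasta(
    contacts_per_complex: Mapping[str, Iterable[ResidueContact]]
) -> str:
    """FASTA text with one record per complex.

    The sequence is the one-letter codes of the interacting residues in
    (chain, residue number) order; non-standard residues become ``X``.
    An empty contact set yields an empty-sequence record.
    """
    lines = []
    for cid, contacts in contacts_per_complex.items():
        ordered = sorted(contacts, key=lambda rc: (rc.chain, rc.resseq))
        seq = "".join(seq1(rc.resname, undef_code="X") for rc in ordered)
        lines.append(f">{cid}")
        lines.append(seq)
    return "\n".join(lines) + "\n"
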
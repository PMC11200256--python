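"""Structural data model and PDB I/O.

Microbial rhodopsin structures arrive as predicted models (e.g. AlphaFold2
through ColabFold, five ranked models per sequence) in PDB format, with the
per-residue confidence (pLDDT, 0-100) stored in the B-factor column.  This
module parses them into a minimal heavy-atom data model, selects the best
of several ranked models by mean pLDDT, and writes structures back out.

Conventions
-----------
* Only ATOM records of the 20 standard amino acids are kept; HETATM groups
  (retinal among them) are skipped with a logged count — the model is
  trained on opsin structures without the chromophore.
* Hydrogens are dropped: predicted structures are heavy-atom only, and the
  representation must be consistent across inputs.
* Only the first chain is used; rhodopsins are modelled as monomers.
* Alternate locations: only blank or 'A' altloc codes are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

logger = logging.getLogger(__name__)

#: 3-letter -> 1-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {one: three for three, one in STANDARD_RESIDUES.items()}


class PDBParseError(ValueError):
    """Raised for malformed or unsupported PDB content."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a standard residue.

    ``confidence`` carries the per-atom pLDDT read from the B-factor column.
    """

    name: str
    element: str
    res_name: str
    res_index: int
    chain: str
    coord: np.ndarray
    confidence: float

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)
        if self.res_name not in STANDARD_RESIDUES:
            raise ValueError(f"non-standard residue {self.res_name!r}")


@dataclass
class Structure:
    """An ordered heavy-atom model of one protein chain."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"structure {self.source_id!r} has no atoms")
        prev_chain, prev_idx = None, None
        for atom in self.atoms:
            if atom.chain != prev_chain:
                prev_chain, prev_idx = atom.chain, atom.res_index
            elif atom.res_index < prev_idx:
                raise ValueError(
                    f"structure {self.source_id!r}: residue indices not "
                    f"increasing in chain {atom.chain!r}"
                )
            else:
                prev_idx = atom.res_index

    @property
    def model_rank_score(self) -> float:
        """Mean per-atom confidence (mean pLDDT for predicted models)."""
        return float(np.mean([a.confidence for a in self.atoms]))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å, file order."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def residue_indices(self) -> list[int]:
        """Distinct residue indices in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.res_index, None)
        return list(seen)

    def sequence(self) -> str:
        """One-letter sequence over distinct residues, in order."""
        letters, seen = [], set()
        for a in self.atoms:
            if a.res_index not in seen:
                seen.add(a.res_index)
                letters.append(STANDARD_RESIDUES[a.res_name])
        return "".join(letters)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly transformed copy: ``x -> R x + t``."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = [
            Atom(a.name, a.element, a.res_name, a.res_index, a.chain,
                 rotation @ a.coord + translation, a.confidence)
            for a in self.atoms
        ]
        return Structure(atoms, source_id=self.source_id)


def _prescan(lines: list[str], path: str) -> None:
    """Cheap line-level diagnostics before handing the file to the parser."""
    n_atom_records = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if rec == "ATOM  ":
            n_atom_records += 1
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"{path}:{lineno}: truncated {rec.strip()} record")
        try:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError:
            raise PDBParseError(
                f"{path}:{lineno}: malformed coordinate field in {rec.strip()} record"
            ) from None
        if rec == "ATOM  ":
            res = line[17:20].strip()
            if res not in STANDARD_RESIDUES:
                raise PDBParseError(
                    f"{path}:{lineno}: non-standard residue {res!r} in ATOM record"
                )
    if n_atom_records == 0:
        raise PDBParseError(f"{path}: no standard-residue heavy atoms found")


def read_pdb(path: str | Path, source_id: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    HETATM groups are skipped (count logged), hydrogens and non-first
    chains are dropped, and only blank/'A' altlocs are kept.  A file whose
    ATOM records contain a non-standard residue, or a malformed record,
    raises :class:`PDBParseError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    _prescan(text.splitlines(), str(path))

    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(
            model=1, altloc="all", extra_fields=["b_factor"]
        )
    except Exception as exc:  # biotite raises various types on bad input
        raise PDBParseError(f"{path}: failed to parse PDB: {exc}") from exc

    n_het = int(np.count_nonzero(arr.hetero))
    if n_het:
        logger.info("%s: skipped %d HETATM atoms", path.name, n_het)
    mask = ~arr.hetero
    if hasattr(arr, "altloc_id"):
        mask &= np.isin(arr.altloc_id, ["", " ", ".", "A"])
    mask &= ~np.isin(arr.element, ["H", "D"])
    arr = arr[mask]
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no standard-residue heavy atoms found")

    first_chain = arr.chain_id[0]
    if not np.all(arr.chain_id == first_chain):
        n_drop = int(np.count_nonzero(arr.chain_id != first_chain))
        logger.info("%s: using chain %s only (%d atoms dropped)",
                    path.name, first_chain, n_drop)
        arr = arr[arr.chain_id == first_chain]

    atoms = [
        Atom(
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            res_name=str(arr.res_name[i]),
            res_index=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]),
            coord=arr.coord[i],
            confidence=float(arr.b_factor[i]),
        )
        for i in range(arr.array_length())
    ]
    return Structure(atoms, source_id=source_id or path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write standard 80-column ATOM records (confidence in the B column)."""
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords()
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.res_id = np.array([a.res_index for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.set_annotation("b_factor", np.array([a.confidence for a in structure.atoms]))
    arr.set_annotation("occupancy", np.ones(n))
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(Path(path)))


def select_best_model(structures: list[Structure]) -> Structure:
    """Pick the model with highest mean per-atom confidence (first wins ties).

    This mirrors ColabFold's default monomer ranking (mean pLDDT) over the
    five predicted models per sequence.
    """
    if not structures:
        raise ValueError("select_best_model: empty model list")
    scores = np.array([s.model_rank_score for s in structures])
    return structures[int(np.argmax(scores))]
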
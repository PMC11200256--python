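"""Locating and extracting the retinal binding pocket.

The absorption maximum of a microbial rhodopsin is tuned almost entirely by
the 24 residues lining the retinal chromophore.  Given an annotated
reference (sequence plus the 24 pocket positions, including the conserved
Schiff-base lysine), the pocket of an arbitrary query rhodopsin is located
by global sequence alignment and the corresponding residues are cut out of
its 3D structure.

The alignment is pairwise Needleman–Wunsch with BLOSUM62 and affine gaps
(open 10, extend 0.5 — EMBOSS defaults), which is deterministic and
self-contained; alternatively a pre-computed multiple sequence alignment
(Clustal or aligned FASTA) containing both sequences can be supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

from .structure import STANDARD_RESIDUES, Structure

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Number of residues lining the retinal pocket.
POCKET_SIZE = 24


class IncompletePocketError(ValueError):
    """A pocket position has no aligned residue in the query."""

    def __init__(self, missing: list[int]):
        self.missing = missing
        super().__init__(
            "incomplete pocket: reference position(s) "
            f"{missing} aligned to gaps in the query"
        )


@dataclass(frozen=True)
class PocketSpec:
    """Reference sequence with its annotated pocket positions (1-based)."""

    ref_id: str
    ref_sequence: str
    pocket_positions: tuple[int, ...]

    def __post_init__(self):
        pos = tuple(int(p) for p in self.pocket_positions)
        object.__setattr__(self, "pocket_positions", pos)
        if len(pos) != POCKET_SIZE:
            raise ValueError(f"pocket spec must list {POCKET_SIZE} positions, got {len(pos)}")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("pocket positions must be strictly increasing")
        if pos[-1] > len(self.ref_sequence) or pos[0] < 1:
            raise ValueError("pocket position outside reference sequence")
        if not any(self.ref_sequence[p - 1] == "K" for p in pos):
            raise ValueError(
                "pocket spec must include the conserved retinal-binding lysine"
            )


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment as two equal-length gapped strings."""

    query_aln: str
    ref_aln: str
    score: float

    def __post_init__(self):
        if len(self.query_aln) != len(self.ref_aln):
            raise ValueError("aligned strings must have equal length")

    @property
    def query(self) -> str:
        return self.query_aln.replace("-", "")

    @property
    def reference(self) -> str:
        return self.ref_aln.replace("-", "")


def _check_alphabet(seq: str, label: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in AA_ALPHABET:
            raise ValueError(
                f"{label}: non-amino-acid character {ch!r} at position {i + 1}"
            )


def global_align(
    query: str,
    reference: str,
    subst_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Optimal global alignment with affine gap penalties.

    Scoring: substitution matrix (default BLOSUM62) minus an affine gap
    cost of ``gap_open + gap_extend * (L - 1)`` for a gap of length L.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(query, "query")
    _check_alphabet(reference, "reference")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        subst_matrix if subst_matrix is not None
        else substitution_matrices.load("BLOSUM62")
    )
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    result = aligner.align(query, reference)
    best = result[0]
    query_aln, ref_aln = str(best[0]), str(best[1])
    return Alignment(query_aln=query_aln, ref_aln=ref_aln, score=float(result.score))


def _map_from_columns(
    query_aln: str,
    ref_aln: str,
    spec: PocketSpec,
    allow_partial: bool,
) -> list[int]:
    wanted = set(spec.pocket_positions)
    mapping: dict[int, int] = {}
    q_pos = r_pos = 0
    for q_ch, r_ch in zip(query_aln, ref_aln):
        if q_ch != "-":
            q_pos += 1
        if r_ch != "-":
            r_pos += 1
            if r_pos in wanted and q_ch != "-":
                mapping[r_pos] = q_pos
    missing = [p for p in spec.pocket_positions if p not in mapping]
    if missing and not allow_partial:
        raise IncompletePocketError(missing)
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "pocket incomplete: %d of %d positions missing (%s)",
            len(missing), POCKET_SIZE, missing,
        )
    return [mapping[p] for p in spec.pocket_positions if p in mapping]


def map_pocket_positions(
    aln: Alignment, spec: PocketSpec, allow_partial: bool = False
) -> list[int]:
    """Transfer pocket positions from the reference to the query (1-based).

    Raises :class:`IncompletePocketError` if any pocket column is aligned
    to a gap in the query, unless ``allow_partial`` downgrades that to a
    warning (the result then has fewer than 24 indices).
    """
    if aln.reference != spec.ref_sequence:
        raise ValueError("alignment reference does not match the pocket spec sequence")
    return _map_from_columns(aln.query_aln, aln.ref_aln, spec, allow_partial)


def map_positions_from_msa(
    msa_path: str | Path,
    ref_id: str,
    query_id: str,
    spec: PocketSpec,
    allow_partial: bool = False,
) -> list[int]:
    """Like :func:`map_pocket_positions`, but columns come from an MSA file.

    The file may be Clustal or aligned FASTA and must contain both ids; the
    ungapped reference row must equal the spec's reference sequence.
    """
    msa_path = Path(msa_path)
    msa = None
    errors = []
    for fmt in ("fasta", "clustal"):
        try:
            msa = AlignIO.read(str(msa_path), fmt)
            break
        except Exception as exc:
            errors.append(f"{fmt}: {exc}")
    if msa is None:
        raise ValueError(f"{msa_path}: not a readable alignment ({'; '.join(errors)})")
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    for needed in (ref_id, query_id):
        if needed not in rows:
            raise ValueError(f"{msa_path}: id {needed!r} not present in MSA")
    ref_row, query_row = rows[ref_id], rows[query_id]
    if ref_row.replace("-", "") != spec.ref_sequence:
        raise ValueError(
            f"{msa_path}: ungapped row {ref_id!r} does not match the "
            "pocket spec reference sequence"
        )
    return _map_from_columns(query_row, ref_row, spec, allow_partial)


def extract_pocket(structure: Structure, indices: list[int]) -> Structure:
    """Substructure with all heavy atoms of exactly the listed residues.

    ``indices`` are residue sequence positions (1-based, matching the
    structure's residue numbering); atom order is preserved.
    """
    if not indices:
        raise ValueError("extract_pocket: empty residue index list")
    present = set(a.res_index for a in structure.atoms)
    absent = [i for i in indices if i not in present]
    if absent:
        raise ValueError(f"extract_pocket: residue indices {absent} not in structure")
    keep = set(indices)
    atoms = [a for a in structure.atoms if a.res_index in keep]
    return Structure(atoms, source_id=f"{structure.source_id}:pocket")


def load_default_pocket_spec() -> PocketSpec:
    """The packaged bacteriorhodopsin reference with 24 pocket positions.

    The positions approximate the retinal-contact shell of
    bacteriorhodopsin (including the Schiff-base lysine K216) and are
    shipped as replaceable configuration.
    """
    with resources.files("rhopocket.data").joinpath("pocket_spec.json").open() as fh:
        payload = json.load(fh)
    return PocketSpec(
        ref_id=payload["ref_id"],
        ref_sequence=payload["ref_sequence"],
        pocket_positions=tuple(payload["pocket_positions"]),
    )


def pocket_indices_for_sequence(
    query: str, spec: PocketSpec, allow_partial: bool = False
) -> list[int]:
    """Convenience: align ``query`` to the spec reference and map positions."""
    aln = global_align(query, spec.ref_sequence)
    return map_pocket_positions(aln, spec, allow_partial=allow_partial)
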
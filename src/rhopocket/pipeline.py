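"""High-level glue: structure → pocket → features → graph.

These helpers wire the modules into the standard workflow (used by the
command-line interface and the example scripts): solvent accessibility is
computed on the full-length structure, the pocket residues are located by
alignment to the reference, and the pocket atoms are featurized and
connected into a molecular graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    FeatureMatrix,
    FeatureTables,
    NormalizationStats,
    apply_normalizer,
    build_feature_matrix,
    compute_sasa,
    fit_normalizer,
)
from .graphs import MolecularGraph, build_graph
from .pocket import PocketSpec, extract_pocket, global_align, map_pocket_positions
from .structure import Structure


@dataclass
class FeaturizedPocket:
    """A pocket substructure with its raw (un-normalized) 36-column features."""

    pocket: Structure
    features: FeatureMatrix
    indices: list[int]


def featurize_structure(
    structure: Structure,
    spec: PocketSpec | None = None,
    sequence: str | None = None,
    tables: FeatureTables | None = None,
    allow_partial: bool = False,
    pocket_indices: list[int] | None = None,
) -> FeaturizedPocket:
    """Locate, extract and featurize the binding pocket of one structure.

    If ``pocket_indices`` is given the alignment step is skipped (used
    when indices come from a user-supplied MSA or when the structure *is*
    the pocket).  Otherwise the structure's sequence (or ``sequence``)
    is globally aligned to ``spec``'s reference and the 24 positions are
    mapped across.  SASA is computed on the full structure, then rows are
    subset to the pocket atoms.
    """
    tables = tables or FeatureTables.load()
    if pocket_indices is None:
        if spec is None:
            raise ValueError("need either pocket_indices or a PocketSpec")
        seq = sequence or structure.sequence()
        aln = global_align(seq, spec.ref_sequence)
        mapped = map_pocket_positions(aln, spec, allow_partial=allow_partial)
        # map sequence positions (1-based over residues) to residue indices
        res_ids = structure.residue_indices()
        pocket_indices = [res_ids[p - 1] for p in mapped]
    sasa_full = compute_sasa(structure, tables=tables)
    pocket = extract_pocket(structure, pocket_indices)
    keep = set(pocket_indices)
    mask = np.array([a.res_index in keep for a in structure.atoms])
    features = build_feature_matrix(
        pocket, tables=tables, sasa=sasa_full[mask],
        atom_index=np.flatnonzero(mask),
    )
    return FeaturizedPocket(pocket=pocket, features=features, indices=pocket_indices)


def graphs_from_featurized(
    items: list[FeaturizedPocket],
    stats: NormalizationStats,
    labels: np.ndarray | None = None,
    cutoff: float = 2.0,
) -> list[MolecularGraph]:
    """Build graphs with normalized node features."""
    out = []
    for i, fp in enumerate(items):
        out.append(
            build_graph(
                fp.pocket,
                apply_normalizer(fp.features, stats),
                cutoff=cutoff,
                label=None if labels is None else float(labels[i]),
                graph_id=fp.pocket.source_id,
            )
        )
    return out


def raw_graph(fp: FeaturizedPocket, cutoff: float = 2.0,
              label: float | None = None) -> MolecularGraph:
    """Graph carrying the raw 36-column features (pre-normalization
    interchange format written by the featurize command)."""
    return build_graph(
        fp.pocket, fp.features.values, cutoff=cutoff, label=label,
        graph_id=fp.pocket.source_id,
    )
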
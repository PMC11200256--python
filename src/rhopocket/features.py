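"""Per-atom featurization of binding-pocket structures.

Every heavy atom is described by a 36-dimensional vector:

* 18 residue-level physicochemical descriptors of the amino acid the atom
  belongs to (acid/base class, neutral 5-class and 2-class encodings,
  hydropathy, isoelectric point, log(P), molecular weight, organic and
  inorganic value, polarity index, residue volume),
* a 15-way one-hot encoding of the tripos 5.2 force-field atom type,
* three atom-level values: CHARMM22 partial charge, per-atom
  solvent-accessible surface area (Shrake–Rupley, 1.4 Å probe) and the
  atomic (van der Waals) radius.

Descriptor values, atom types, charges and radii are shipped as plain TSV
tables and can be overridden by the user; the column-to-group mapping used
by the ablation protocols is part of the schema.

Feature columns that are constant over the training set are removed and
the remaining columns are z-scored with train-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure

#: The fixed 15-type tripos 5.2 vocabulary used for one-hot encoding.
TRIPOS_VOCAB: tuple[str, ...] = (
    "C.3", "C.2", "C.ar", "C.cat", "N.3", "N.2", "N.4",
    "N.am", "N.ar", "N.pl3", "O.2", "O.3", "O.co2", "S.3", "other",
)

#: Feature-group labels used by the ablation protocols.
GROUP_RESIDUE = {
    "acid_base_acidic": "acid base property",
    "acid_base_basic": "acid base property",
    "acid_base_neutral": "acid base property",
    "neutral5_aliphatic": "neutral (5-class)",
    "neutral5_aromatic": "neutral (5-class)",
    "neutral5_polar": "neutral (5-class)",
    "neutral5_cysteine": "neutral (5-class)",
    "neutral5_progly": "neutral (5-class)",
    "neutral2_polar": "neutral (2-class)",
    "hydropathy": "hydropathy",
    "hydrophobic": "hydropathy",
    "isoelectric_point": "isoelectric point",
    "logp": "log(P)",
    "mol_weight": "molecular weight",
    "organic_value": "organic/inorganic value",
    "inorganic_value": "organic/inorganic value",
    "polarity_index": "polarity index",
    "residue_volume": "atomic volume",
}


def _data_path(name: str):
    return resources.files("rhopocket.data").joinpath(name)


@dataclass(frozen=True)
class FeatureTables:
    """The packaged (or user-supplied) lookup tables."""

    residue: pd.DataFrame          # index res_name, 18 descriptor columns
    tripos: dict[tuple[str, str], str]
    charges: dict[tuple[str, str], float]
    radii: dict[str, float]

    @classmethod
    def load(
        cls,
        residue_path: str | Path | None = None,
        tripos_path: str | Path | None = None,
        charges_path: str | Path | None = None,
        radii_path: str | Path | None = None,
    ) -> "FeatureTables":
        def _read(path, default):
            src = Path(path) if path is not None else _data_path(default)
            return pd.read_csv(src, sep="\t")

        res = _read(residue_path, "residue_features.tsv").set_index("res")
        if res.shape[1] != 18:
            raise ValueError(f"residue feature table must have 18 columns, got {res.shape[1]}")
        tripos_df = _read(tripos_path, "tripos_types.tsv")
        tripos = {(r.res, r.atom): r.type for r in tripos_df.itertuples()}
        charges_df = _read(charges_path, "charmm22_charges.tsv")
        charges = {(r.res, r.atom): float(r.charge) for r in charges_df.itertuples()}
        radii_df = _read(radii_path, "radii.tsv")
        radii = {r.element: float(r.radius) for r in radii_df.itertuples()}
        return cls(residue=res, tripos=tripos, charges=charges, radii=radii)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 36-column schema with the group label of every column."""

    column_names: tuple[str, ...]
    group_of_column: dict[str, str]

    def __post_init__(self):
        if len(self.column_names) != 36:
            raise ValueError(f"schema must have 36 columns, got {len(self.column_names)}")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.column_names:
            seen.setdefault(self.group_of_column[c], None)
        return tuple(seen)

    def columns_of_group(self, group: str) -> list[int]:
        if group not in self.groups:
            raise KeyError(f"unknown feature group {group!r}; known: {list(self.groups)}")
        return [
            i for i, c in enumerate(self.column_names)
            if self.group_of_column[c] == group
        ]


def default_schema(tables: FeatureTables) -> FeatureSchema:
    residue_cols = tuple(tables.residue.columns)
    tripos_cols = tuple(f"tripos_{t}" for t in TRIPOS_VOCAB)
    tail = ("partial_charge", "surface_area", "atomic_radius")
    names = residue_cols + tripos_cols + tail
    groups = dict(GROUP_RESIDUE)
    groups.update({c: "tripos 5.2 atom type" for c in tripos_cols})
    groups["partial_charge"] = "partial atom charge"
    groups["surface_area"] = "surface area"
    groups["atomic_radius"] = "atomic radius"
    return FeatureSchema(column_names=names, group_of_column=groups)


@dataclass
class FeatureMatrix:
    """N_atoms x 36 feature table aligned to a pocket structure."""

    values: np.ndarray
    schema: FeatureSchema
    atom_index: np.ndarray  # indices of the atoms in the source structure

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.schema.column_names):
            raise ValueError("feature matrix shape does not match schema")
        onehot = self.values[:, [self.schema.column_names.index(f"tripos_{t}")
                                 for t in TRIPOS_VOCAB]]
        if not np.allclose(onehot.sum(axis=1), 1.0):
            raise ValueError("tripos one-hot rows must sum to 1")


# --------------------------------------------------------------------------
# tripos atom typing
# --------------------------------------------------------------------------

def assign_tripos_types(pocket: Structure, tables: FeatureTables | None = None) -> list[str]:
    """Map each heavy atom to its tripos 5.2 type via the packaged table.

    Lookup order: exact (residue, atom name), then backbone wildcard
    ('*', atom name).  An atom absent from both raises KeyError.
    """
    tables = tables or FeatureTables.load()
    out = []
    for atom in pocket.atoms:
        t = tables.tripos.get((atom.res_name, atom.name))
        if t is None:
            t = tables.tripos.get(("*", atom.name))
        if t is None:
            raise KeyError(
                f"no tripos type for atom {atom.name!r} of residue {atom.res_name!r}"
            )
        out.append(t)
    return out


def _lookup_charge(tables: FeatureTables, res: str, atom: str) -> float:
    c = tables.charges.get((res, atom))
    if c is None:
        c = tables.charges.get(("*", atom))
    if c is None:
        raise KeyError(f"no partial charge for atom {atom!r} of residue {res!r}")
    return c


# --------------------------------------------------------------------------
# solvent-accessible surface area
# --------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (deterministic)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate a centred point cloud into its PCA frame with fixed signs.

    Makes the quadrature rigid-motion invariant: the sphere points are
    effectively attached to the molecule, not to the world frame.
    """
    if len(coords) < 2:
        return coords
    cov = np.cov(coords.T)
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    proj = coords @ vecs
    for k in range(3):
        col = proj[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            proj[:, k] = -col
    return proj


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    tables: FeatureTables | None = None,
    canonicalize: bool = True,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    For each atom, a deterministic golden-spiral quadrature of
    ``n_sphere_points`` points is placed on the expanded sphere of radius
    ``r_atom + probe_radius``; the accessible fraction (points not buried
    in any neighbour's expanded sphere) times the expanded-sphere area is
    the atom's SASA.  Coordinates are first moved into a canonical
    molecular frame so the result is rigid-motion invariant.

    Call this on the full-length structure (burial context matters) and
    subset the rows to pocket atoms afterwards.
    """
    tables = tables or FeatureTables.load()
    try:
        radii = np.array([tables.radii[a.element] for a in structure.atoms])
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius for element {exc.args[0]!r}") from None

    coords = structure.coords()
    if canonicalize:
        coords = _canonical_frame(coords - coords.mean(axis=0))
    expanded = radii + probe_radius
    sphere = _golden_spiral(n_sphere_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


# --------------------------------------------------------------------------
# feature matrix assembly and normalization
# --------------------------------------------------------------------------

def build_feature_matrix(
    pocket: Structure,
    tables: FeatureTables | None = None,
    sasa: np.ndarray | None = None,
    atom_index: np.ndarray | None = None,
) -> FeatureMatrix:
    """Assemble the N x 36 feature matrix for a pocket structure.

    ``sasa`` should hold the per-atom areas of exactly the pocket's atoms
    (typically computed on the full structure and subset); if omitted it
    is computed on the pocket alone.
    """
    tables = tables or FeatureTables.load()
    schema = default_schema(tables)
    if sasa is None:
        sasa = compute_sasa(pocket, tables=tables)
    sasa = np.asarray(sasa, dtype=float)
    if sasa.shape != (pocket.n_atoms,):
        raise ValueError("sasa length does not match pocket atom count")

    types = assign_tripos_types(pocket, tables)
    type_index = {t: k for k, t in enumerate(TRIPOS_VOCAB)}
    n = pocket.n_atoms
    values = np.zeros((n, 36))
    for i, atom in enumerate(pocket.atoms):
        try:
            values[i, :18] = tables.residue.loc[atom.res_name].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"residue {atom.res_name!r} missing from residue table") from None
        values[i, 18 + type_index[types[i]]] = 1.0
        values[i, 33] = _lookup_charge(tables, atom.res_name, atom.name)
        values[i, 34] = sasa[i]
        values[i, 35] = tables.radii[atom.element]
    if atom_index is None:
        atom_index = np.arange(n)
    return FeatureMatrix(values=values, schema=schema, atom_index=np.asarray(atom_index))


@dataclass(frozen=True)
class NormalizationStats:
    """Train-set column statistics: mask of retained (non-constant) columns
    plus their means and standard deviations."""

    mean: np.ndarray
    std: np.ndarray
    retained_mask: np.ndarray

    def __post_init__(self):
        if np.any(self.std <= 0):
            raise ValueError("retained columns must have positive std")
        if len(self.mean) != int(self.retained_mask.sum()):
            raise ValueError("mean/std length must equal number of retained columns")


def fit_normalizer(
    train_matrices: list[FeatureMatrix], var_tol: float = 1e-12
) -> NormalizationStats:
    """Pool all atoms of all training pockets; mask constant columns,
    record mean/std of the rest."""
    if not train_matrices:
        raise ValueError("fit_normalizer: empty training set")
    pooled = np.vstack([m.values for m in train_matrices])
    var = pooled.var(axis=0)
    retained = var >= var_tol
    return NormalizationStats(
        mean=pooled.mean(axis=0)[retained],
        std=pooled.std(axis=0)[retained],
        retained_mask=retained,
    )


def apply_normalizer(m: FeatureMatrix, stats: NormalizationStats) -> np.ndarray:
    """(x - mean) / std on the retained columns; returns (N, n_retained)."""
    if m.values.shape[1] != len(stats.retained_mask):
        raise ValueError(
            f"feature matrix has {m.values.shape[1]} columns but stats expect "
            f"{len(stats.retained_mask)}"
        )
    return (m.values[:, stats.retained_mask] - stats.mean) / stats.std
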
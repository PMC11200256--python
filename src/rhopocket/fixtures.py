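"""Synthetic desk-scale inputs for exercising the whole pipeline.

Generates geometrically valid toy pocket structures (idealized tree
geometry: every covalent neighbour pair ~1.5 Å apart, all non-bonded
pairs > 2 Å), mutant families that differ from their parent by one or
two substitutions, and labels planted as an affine function of the mean
node feature vector plus Gaussian noise.  The emitted PDB/FASTA/CSV
files use exactly the formats the real pipeline consumes.

The structures are chemically implausible (uniform bond lengths, no ring
closure, residues spaced far apart on a coarse helix) but satisfy every
geometric contract the pipeline relies on, which is all a fixture needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import ONE_TO_THREE, STANDARD_RESIDUES, Atom, Structure

# Heavy-atom tree topology per residue: (atom_name, parent_name) in build
# order.  The backbone is shared; side chains hang off CA.  Rings are left
# open — fixtures need bonds, not aromatic chemistry.
_BACKBONE = [("N", None), ("CA", "N"), ("C", "CA"), ("O", "C")]
_SIDE_CHAINS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CB", "CA")],
    "SER": [("CB", "CA"), ("OG", "CB")],
    "CYS": [("CB", "CA"), ("SG", "CB")],
    "THR": [("CB", "CA"), ("OG1", "CB"), ("CG2", "CB")],
    "VAL": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB")],
    "LEU": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "ILE": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
    "MET": [("CB", "CA"), ("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "PRO": [("CB", "CA"), ("CG", "CB"), ("CD", "CG")],
    "PHE": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
            ("CE1", "CD1"), ("CE2", "CD2"), ("CZ", "CE1")],
    "TYR": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
            ("CE1", "CD1"), ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ")],
    "TRP": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
            ("NE1", "CD1"), ("CE2", "CD2"), ("CE3", "CD2"),
            ("CZ2", "CE2"), ("CZ3", "CE3"), ("CH2", "CZ2")],
    "ASP": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "GLU": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
    "ASN": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
    "GLN": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")],
    "HIS": [("CB", "CA"), ("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"),
            ("CE1", "ND1"), ("NE2", "CE1")],
    "LYS": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")],
    "ARG": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("NE", "CD"),
            ("CZ", "NE"), ("NH1", "CZ"), ("NH2", "CZ")],
}

BOND_LENGTH = 1.5          # uniform synthetic bond length, Å
_TET = np.deg2rad(180.0 - 109.47)  # deviation from straight continuation

HELIX_RADIUS = 36.0
HELIX_STEP_DEG = 36.0
HELIX_RISE = 5.0


def residue_topology(res_name: str) -> list[tuple[str, str | None]]:
    """Heavy-atom (name, parent) list for one residue, backbone first."""
    return _BACKBONE + _SIDE_CHAINS[res_name]


def heavy_atom_count(res_name: str) -> int:
    return len(residue_topology(res_name))


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - np.cos(angle))
    )


def _build_residue(res_name: str, origin: np.ndarray) -> dict[str, np.ndarray]:
    """Place one residue's atoms by deterministic ideal tree geometry.

    The first child of every atom continues in an anti (all-trans zigzag)
    direction so chains extend instead of curling back; further children
    are spread by ±120° azimuth about the incoming bond.
    """
    topo = residue_topology(res_name)
    children: dict[str, list[str]] = {}
    for a, p in topo:
        if p is not None:
            children.setdefault(p, []).append(a)
    coords: dict[str, np.ndarray] = {"N": origin.astype(float)}
    incoming: dict[str, np.ndarray] = {"N": np.array([1.0, 0.0, 0.0])}
    lateral: dict[str, np.ndarray] = {"N": np.array([0.0, 0.0, 1.0])}
    stack = ["N"]
    while stack:
        parent = stack.pop()
        kids = children.get(parent, [])
        if not kids:
            continue
        u = incoming[parent]
        # zigzag: children tilt toward the opposite side of the parent's
        # own lateral displacement, orthogonalized against u
        base = -lateral[parent] + np.dot(lateral[parent], u) * u
        nb = np.linalg.norm(base)
        base = base / nb if nb > 1e-9 else _perp_basis(u)[0]
        for k, child in enumerate(kids):
            m = base if k == 0 else _rotate_about(base, u, 2.0 * np.pi * k / 3.0)
            m = m - np.dot(m, u) * u
            m /= np.linalg.norm(m)
            d = np.cos(_TET) * u + np.sin(_TET) * m
            d /= np.linalg.norm(d)
            coords[child] = coords[parent] + BOND_LENGTH * d
            incoming[child] = d
            lateral[child] = m
            stack.append(child)
    return coords


def _helix_anchor(i: int) -> np.ndarray:
    ang = np.deg2rad(HELIX_STEP_DEG) * i
    return np.array(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i]
    )


def _element(atom_name: str) -> str:
    return atom_name[0]


@dataclass
class FixtureConfig:
    """Study conditions for a synthetic dataset."""

    n_wt_groups: int = 75
    mutants_per_wt: int = 4
    n_residues: int = 24
    noise_sigma: float = 2.0   # nm
    seed: int = 0
    planted_coeffs: "PlantedCoeffs | None" = None

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_residues < 2:
            raise ValueError("n_residues must be at least 2")


def make_toy_pocket(
    seed: int,
    n_residues: int = 24,
    out_pdb: str | Path | None = None,
    sequence: str | None = None,
    source_id: str | None = None,
) -> tuple[Structure, str]:
    """A toy multi-residue pocket structure on a coarse helical path.

    Residue types are drawn uniformly from the 20 standard amino acids
    (one position is forced to lysine so toy pocket specs can include the
    conserved retinal-binding lysine).  Per-residue synthetic pLDDT-like
    confidences fill the B-factor column.  Deterministic per seed; the
    same seed yields a byte-identical PDB.
    """
    rng = np.random.default_rng(seed)
    three = sorted(STANDARD_RESIDUES)
    if sequence is None:
        seq = [three[i] for i in rng.integers(0, 20, size=n_residues)]
        seq[n_residues // 2] = "LYS"
    else:
        if len(sequence) != n_residues:
            raise ValueError("sequence length must equal n_residues")
        seq = [ONE_TO_THREE[ch] for ch in sequence]
    plddt = rng.uniform(60.0, 95.0, size=n_residues)

    atoms: list[Atom] = []
    for i, res in enumerate(seq):
        coords = _build_residue(res, _helix_anchor(i))
        for name, _parent in residue_topology(res):
            atoms.append(
                Atom(
                    name=name,
                    element=_element(name),
                    res_name=res,
                    res_index=i + 1,
                    chain="A",
                    coord=coords[name],
                    confidence=round(float(plddt[i]), 2),
                )
            )
    structure = Structure(atoms, source_id=source_id or f"toy-{seed}")
    if out_pdb is not None:
        from .structure import write_pdb

        write_pdb(structure, out_pdb)
    return structure, "".join(STANDARD_RESIDUES[r] for r in seq)


def make_mutant_family(
    wt: Structure,
    wt_sequence: str,
    n_mutants: int,
    seed: int,
    protected_positions: set[int] | None = None,
) -> list[tuple[str, Structure]]:
    """Mutants differing from the parent by 1–2 substitutions.

    Side-chain atoms of mutated residues are rebuilt from the idealized
    templates at the residue's original anchor; every unchanged residue
    keeps its coordinates bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    three = sorted(STANDARD_RESIDUES)
    n_res = len(wt_sequence)
    protected = protected_positions or set()
    candidates = [p for p in range(1, n_res + 1) if p not in protected]
    by_res: dict[int, list[Atom]] = {}
    for a in wt.atoms:
        by_res.setdefault(a.res_index, []).append(a)

    out = []
    for m in range(n_mutants):
        k = int(rng.integers(1, 3))
        pos = sorted(rng.choice(candidates, size=min(k, len(candidates)), replace=False))
        muts: dict[int, str] = {}
        for p in pos:
            old = ONE_TO_THREE[wt_sequence[p - 1]]
            new = three[int(rng.integers(0, 20))]
            while new == old:
                new = three[int(rng.integers(0, 20))]
            muts[int(p)] = new
        atoms: list[Atom] = []
        for res_idx in sorted(by_res):
            originals = by_res[res_idx]
            if res_idx not in muts:
                atoms.extend(originals)
                continue
            new_res = muts[res_idx]
            anchor = next(a.coord for a in originals if a.name == "N")
            conf = originals[0].confidence
            coords = _build_residue(new_res, anchor)
            for name, _parent in residue_topology(new_res):
                atoms.append(
                    Atom(name, _element(name), new_res, res_idx, "A",
                         coords[name], conf)
                )
        seq = list(wt_sequence)
        for p, res in muts.items():
            seq[p - 1] = STANDARD_RESIDUES[res]
        out.append(("".join(seq), Structure(atoms, source_id=f"{wt.source_id}-m{m}")))
    return out


@dataclass(frozen=True)
class PlantedCoeffs:
    """Affine map from the mean node feature vector to a label in nm."""

    intercept: float
    weights: np.ndarray


def random_planted_coeffs(
    feature_means: np.ndarray, seed: int, center_nm: float = 550.0,
    spread_nm: float = 50.0,
) -> PlantedCoeffs:
    """Coefficients scaled so labels spread ~``spread_nm`` around the center.

    ``feature_means`` is the (n_graphs, F) matrix of per-graph mean node
    features used to calibrate the output scale.
    """
    rng = np.random.default_rng(seed)
    fm = np.asarray(feature_means, dtype=float)
    w = rng.normal(size=fm.shape[1])
    raw = fm @ w
    scale = raw.std()
    if scale == 0:
        scale = 1.0
    w *= spread_nm / scale
    intercept = center_nm - float(np.mean(fm @ w))
    return PlantedCoeffs(intercept=intercept, weights=w)


def plant_labels(
    graphs,
    coeffs: PlantedCoeffs,
    noise_sigma: float,
    seed: int,
) -> np.ndarray:
    """label = clip(affine(mean node features), 400, 700) + N(0, σ²) per graph."""
    rng = np.random.default_rng(seed)
    means = np.vstack([g.node_features.mean(axis=0) for g in graphs])
    core = np.clip(coeffs.intercept + means @ coeffs.weights, 400.0, 700.0)
    return core + rng.normal(0.0, noise_sigma, size=len(graphs))


def make_dataset(
    config: FixtureConfig, out_dir: str | Path | None = None
) -> tuple[list[dict], dict[str, Structure]]:
    """A full synthetic dataset: wild-type groups with mutant families.

    Returns (records, structures); records are dicts with seq_id,
    wt_group, sequence (labels are planted later, on featurized graphs).
    If ``out_dir`` is given, writes <seq_id>.pdb files, a sequences.fasta
    and a dataset.csv skeleton there.
    """
    rng = np.random.default_rng(config.seed)
    records: list[dict] = []
    structures: dict[str, Structure] = {}
    for g in range(config.n_wt_groups):
        wt_seed = int(rng.integers(0, 2**31 - 1))
        wt_id = f"wt{g:03d}"
        wt_struct, wt_seq = make_toy_pocket(
            wt_seed, config.n_residues, source_id=wt_id
        )
        records.append({"seq_id": wt_id, "wt_group": wt_id, "sequence": wt_seq})
        structures[wt_id] = wt_struct
        fam = make_mutant_family(
            wt_struct, wt_seq, config.mutants_per_wt,
            seed=int(rng.integers(0, 2**31 - 1)),
            protected_positions={config.n_residues // 2 + 1},
        )
        for mi, (mseq, mstruct) in enumerate(fam):
            mid = f"{wt_id}m{mi}"
            records.append({"seq_id": mid, "wt_group": wt_id, "sequence": mseq})
            structures[mid] = mstruct
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .structure import write_pdb

        with open(out_dir / "sequences.fasta", "w") as fa:
            for rec in records:
                fa.write(f">{rec['seq_id']}\n{rec['sequence']}\n")
                write_pdb(structures[rec["seq_id"]], out_dir / f"{rec['seq_id']}.pdb")
    return records, structures


def write_dataset_csv(records: list[dict], labels_nm: np.ndarray, path: str | Path) -> None:
    """Write the dataset CSV the training CLI consumes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seq_id", "wt_group", "sequence", "lambda_max_nm", "method"])
        for rec, y in zip(records, labels_nm):
            writer.writerow(
                [rec["seq_id"], rec["wt_group"], rec["sequence"],
                 f"{float(y):.3f}", "synthetic"]
            )
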
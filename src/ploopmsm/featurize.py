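"""Geometric featurization of loop structures and trajectories.

Converts structures into the features the pipeline consumes: the 36
backbone N(i)/O(j) pairwise distances of a 6-residue P-loop (nm), optimal
superposition RMSD (Å), carbonyl bond-vector angles (degrees), per-residue
side-chain solvent-accessible surface area (nm²), and contact fractions.

Unit convention: coordinates are stored in Å (the PDB convention); internal
distance features are reported in nm and RMSD in Å, with the conversions
centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

ANGSTROM_PER_NM = 10.0

#: Bondi-style van der Waals radii (Å) by element symbol.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31, "ZN": 1.39,
    "FE": 1.94, "MN": 2.05, "SE": 1.90,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Structure:
    """A minimal structure: parallel per-atom arrays plus coordinates (Å)."""

    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=str)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=str)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.residue_ids) == len(self.residue_names) == self.coords.shape[0] == n):
            raise ValueError("per-atom arrays must have equal length")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, residue_id: int, atom_name: str) -> int:
        mask = (self.residue_ids == residue_id) & (self.atom_names == atom_name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"residue {residue_id} has no atom {atom_name!r}")
        return int(idx[0])

    def atom_coord(self, residue_id: int, atom_name: str) -> np.ndarray:
        return self.coords[self.atom_index(residue_id, atom_name)]

    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_names, BACKBONE_ATOMS)

    def select_residues(self, residue_ids) -> "Structure":
        mask = np.isin(self.residue_ids, residue_ids)
        return Structure(self.atom_names[mask], self.residue_ids[mask],
                         self.residue_names[mask], self.coords[mask], self.chain_id)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Rigidly transformed copy (x -> R x + t)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return Structure(self.atom_names.copy(), self.residue_ids.copy(),
                         self.residue_names.copy(), coords, self.chain_id)


@dataclass
class FeatureMatrix:
    """frame x d feature values with per-column labels and a unit string."""

    values: np.ndarray
    feature_labels: list
    units: str

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_labels):
            raise ValueError("number of labels must match feature dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no missing values)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def find_ploop(structure: Structure, motif: str = "GESGAG") -> np.ndarray:
    """Locate the P-loop by scanning the residue sequence for ``motif``.

    Returns the residue ids of the first match (first match wins).
    """
    ids = []
    seen = set()
    for rid, rname in zip(structure.residue_ids, structure.residue_names):
        if rid not in seen:
            seen.add(rid)
            ids.append((int(rid), _AA3.get(str(rname).upper(), "X")))
    seq = "".join(code for _, code in ids)
    pos = seq.find(motif)
    if pos < 0:
        raise ValueError(f"motif {motif!r} not found in residue sequence {seq!r}")
    return np.array([ids[pos + k][0] for k in range(len(motif))])


def _ploop_atom_indices(structure: Structure, ploop_residues) -> tuple[np.ndarray, np.ndarray]:
    ploop_residues = np.asarray(ploop_residues, dtype=int)
    if len(ploop_residues) != 6:
        raise ValueError("ploop_residues must list exactly 6 consecutive residue ids")
    n_idx = np.array([structure.atom_index(r, "N") for r in ploop_residues])
    o_idx = np.array([structure.atom_index(r, "O") for r in ploop_residues])
    return n_idx, o_idx


def ploop_distances(structure: Structure, ploop_residues=None,
                    trajectory: np.ndarray | None = None) -> FeatureMatrix:
    """All 36 ordered backbone N(i)–O(j) distances of a 6-residue loop, in nm.

    ``structure`` provides the topology (atom naming); coordinates come from
    the structure itself or, if ``trajectory`` is given, from a
    (frames, n_atoms, 3) coordinate array in Å sharing the structure's atom
    order.  The features are internal distances, hence invariant to global
    rotation and translation.
    """
    if ploop_residues is None:
        ploop_residues = find_ploop(structure)
    n_idx, o_idx = _ploop_atom_indices(structure, ploop_residues)
    coords = structure.coords[None] if trajectory is None else np.asarray(trajectory, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("trajectory must be (frames, n_atoms, 3)")
    n_xyz = coords[:, n_idx]            # (frames, 6, 3)
    o_xyz = coords[:, o_idx]
    diff = n_xyz[:, :, None, :] - o_xyz[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1) / ANGSTROM_PER_NM
    values = dist.reshape(coords.shape[0], 36)
    labels = [(f"N:{int(ri)}", f"O:{int(rj)}")
              for ri in ploop_residues for rj in ploop_residues]
    return FeatureMatrix(values=values, feature_labels=labels, units="nm")


def superpose_rmsd(mobile: Structure | np.ndarray, reference: Structure | np.ndarray,
                   atom_selection: np.ndarray | None = None) -> float:
    """Minimum RMSD (Å) over all rigid transforms (Kabsch superposition).

    ``atom_selection`` is a boolean mask or index array applied to both
    structures; selections must map to equal atom counts >= 3 in consistent
    order.
    """
    def _coords(s):
        return s.coords if isinstance(s, Structure) else np.asarray(s, dtype=float)

    a = _coords(mobile)
    b = _coords(reference)
    if atom_selection is not None:
        a = a[atom_selection]
        b = b[atom_selection]
    if a.shape != b.shape:
        raise ValueError(f"selection sizes differ: {a.shape[0]} vs {b.shape[0]} atoms")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # Kabsch via scipy's rotational alignment; rssd is sqrt of the residual
    # sum of squares at the optimal rotation.
    _, rssd = Rotation.align_vectors(b, a)
    return float(rssd / np.sqrt(a.shape[0]))


def carbonyl_angle(structure: Structure, res_i: int, res_j: int) -> float:
    """Angle (degrees, in [0, 180]) between the C→O carbonyl bond vectors of
    two residues — the coordinate that separates the serine-carbonyl-flipped
    loop states."""
    v1 = structure.atom_coord(res_i, "O") - structure.atom_coord(res_i, "C")
    v2 = structure.atom_coord(res_j, "O") - structure.atom_coord(res_j, "C")
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _element_of(atom_name: str) -> str:
    name = atom_name.strip().upper()
    if name in VDW_RADII and len(name) == 2 and not name[0] in "CNOSHP":
        return name
    # PDB-style heuristics: CA/CB/CG... are carbons, OXT oxygen, etc.
    if name[:1] in ("C", "N", "O", "S", "H", "P"):
        return name[:1]
    if name in VDW_RADII:
        return name
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def shrake_rupley_scsasa(structure: Structure, probe_radius: float = 1.4,
                         n_sphere_points: int = 960,
                         radii: dict | None = None) -> FeatureMatrix:
    """Per-residue side-chain solvent-accessible surface area (nm²).

    Accessible area per atom comes from the sphere-point sampling
    construction (points on an inflated sphere of radius r_vdw + probe,
    counted accessible if outside every neighbor's inflated sphere).
    Backbone atoms (N, CA, C, O) occlude but are excluded from the
    per-residue sums.  Radii come from a fixed element table; unknown
    elements raise unless a radius is supplied via ``radii``.
    """
    from biotite.structure import AtomArray, sasa

    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    vdw = np.empty(structure.n_atoms)
    for i, name in enumerate(structure.atom_names):
        if radii and name.upper() in {k.upper() for k in radii}:
            vdw[i] = table[name.upper()]
            continue
        element = _element_of(name)
        if element not in table:
            raise ValueError(f"no van der Waals radius for element {element!r}; "
                             f"supply one via the radii argument")
        vdw[i] = table[element]

    arr = AtomArray(structure.n_atoms)
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.atom_names
    arr.res_id = structure.residue_ids
    arr.res_name = structure.residue_names
    arr.chain_id = np.full(structure.n_atoms, structure.chain_id)

    def _element_or_placeholder(name):
        try:
            return _element_of(name)
        except ValueError:
            return "X"  # radius already supplied explicitly; element unused

    arr.element = np.array([_element_or_placeholder(n) for n in structure.atom_names])

    sidechain = ~structure.backbone_mask()
    per_atom = sasa(arr, probe_radius=probe_radius, atom_filter=sidechain,
                    point_number=n_sphere_points, vdw_radii=vdw,
                    ignore_ions=False)
    per_atom = np.nan_to_num(per_atom, nan=0.0)

    resids = np.unique(structure.residue_ids)
    values = np.array([
        per_atom[(structure.residue_ids == rid) & sidechain].sum() for rid in resids
    ]) / (ANGSTROM_PER_NM ** 2)
    return FeatureMatrix(values=values[None, :], feature_labels=list(map(int, resids)),
                         units="nm^2")


def contact_fraction(distances: np.ndarray, cutoff: float = 0.35) -> float:
    """Fraction of frames in which a distance (nm) is strictly below ``cutoff``
    — the direct-interaction criterion used for side-chain contact analysis."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distance trajectory")
    if np.any(distances < 0):
        raise ValueError("distances must be non-negative")
    return float(np.mean(distances < cutoff))
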
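"""File I/O for every pipeline artifact.

Structures are standard PDB (read through biotite; single model, first
altloc).  Trajectories are one whitespace-delimited numeric matrix per
trajectory plus a JSON manifest; assignments are one integer per line per
trajectory; models are JSON with matrices row-major; feature matrices and
tabular outputs are CSV.  All writers are deterministic for fixed inputs so
reruns with equal seeds produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .cluster import Clustering, MacroMapping
from .featurize import FeatureMatrix, Structure
from .msm import MicrostateModel, PloopStateModel


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read the polymer atoms of a PDB file (first model, first altloc)."""
    import biotite.structure.io.pdb as pdb

    try:
        f = pdb.PDBFile.read(str(path))
        arr = f.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    poly = arr[~arr.hetero]
    if poly.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records")
    chain = str(poly.chain_id[0])
    poly = poly[poly.chain_id == chain]
    return Structure(atom_names=poly.atom_name, residue_ids=poly.res_id,
                     residue_names=poly.res_name, coords=poly.coord,
                     chain_id=chain)


def read_pdb_ligands(path) -> list[str]:
    """Residue names of all HETATM records (for nucleotide classification)."""
    import biotite.structure.io.pdb as pdb

    try:
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    het = arr[arr.hetero]
    seen, names = set(), []
    for n in het.res_name:
        if n not in seen:
            seen.add(n)
            names.append(str(n))
    return names


def write_pdb(structure: Structure, path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.atom_names
    arr.res_id = structure.residue_ids
    arr.res_name = structure.residue_names
    arr.chain_id = np.full(structure.n_atoms, structure.chain_id)
    arr.element = np.array([n[0] for n in structure.atom_names])
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


# ---------------------------------------------------------------------------
# matrices, assignments, features
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.17g")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def write_assignments(assignments: list[np.ndarray], directory, prefix: str = "assignments") -> list[Path]:
    """One file per trajectory, one integer per line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, seq in enumerate(assignments):
        p = directory / f"{prefix}_{i:04d}.txt"
        np.savetxt(p, np.asarray(seq, dtype=np.int64), fmt="%d")
        paths.append(p)
    return paths


def read_assignments(paths) -> list[np.ndarray]:
    return [np.loadtxt(p, dtype=np.int64, ndmin=1) for p in sorted(map(str, paths))]


def write_features_csv(fm: FeatureMatrix, path) -> None:
    header = ",".join("|".join(map(str, lab)) if isinstance(lab, tuple) else str(lab)
                      for lab in fm.feature_labels)
    np.savetxt(path, fm.values, fmt="%.17g", delimiter=",",
               header=header + f"\n# units: {fm.units}", comments="")


def write_ensemble(ensemble, directory) -> Path:
    """Trajectory matrices + JSON manifest (frame_interval, seed, truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, feats in enumerate(ensemble.features):
        p = directory / f"traj_{i:04d}.txt"
        write_matrix(feats, p)
        files.append(p.name)
    truth = ensemble.truth
    manifest = {
        "frame_interval_ns": truth.frame_interval,
        "seed": truth.seed,
        "n_trajectories": len(files),
        "trajectory_files": files,
        "truth": {
            "T_true": truth.T_true.tolist(),
            "centers": truth.centers.tolist(),
            "emission_sd": truth.emission_sd,
        },
    }
    mpath = directory / "manifest.json"
    _dump_json(manifest, mpath)
    return mpath


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_microstate_model(model: MicrostateModel, path, seed=None, provenance=None) -> None:
    _dump_json({
        "kind": "microstate_model",
        "n_states": model.n_states,
        "stride": model.stride,
        "lag_ns": model.lag_ns,
        "C": model.C.tolist(),
        "T": model.T.tolist(),
        "pi": model.pi.tolist(),
        "eigenvalues_real": model.eigenvalues.real.tolist(),
        "eigenvalues_imag": model.eigenvalues.imag.tolist(),
        "timescales_ns": [None if not np.isfinite(t) else t for t in model.timescales_ns],
        "seed": seed,
        "provenance": provenance,
    }, path)


def read_microstate_model(path) -> MicrostateModel:
    with open(path) as fh:
        d = json.load(fh)
    return MicrostateModel(
        n_states=d["n_states"], stride=d["stride"], lag_ns=d["lag_ns"],
        C=np.array(d["C"]), T=np.array(d["T"]), pi=np.array(d["pi"]),
        eigenvalues=np.array(d["eigenvalues_real"]) + 1j * np.array(d["eigenvalues_imag"]),
        timescales_ns=np.array([np.nan if t is None else t for t in d["timescales_ns"]]),
    )


def write_ploop_model(model: PloopStateModel, path, seed=None, provenance=None) -> None:
    _dump_json({
        "kind": "ploop_state_model",
        "labels": list(model.labels),
        "micro_to_macro": [str(x) for x in model.mapping.micro_to_macro],
        "stride": model.stride,
        "lag_ns": model.lag_ns,
        "C5": model.C5.tolist(),
        "T5": model.T5.tolist(),
        "pi5": model.pi5.tolist(),
        "p_ab": model.p_ab,
        "dg_ab": model.dg_ab,
        "seed": seed,
        "provenance": provenance,
    }, path)


def read_ploop_model(path) -> PloopStateModel:
    with open(path) as fh:
        d = json.load(fh)
    mapping = MacroMapping(micro_to_macro=np.array(d["micro_to_macro"]),
                           labels=tuple(d["labels"]))
    return PloopStateModel(mapping=mapping, stride=d["stride"], lag_ns=d["lag_ns"],
                           C5=np.array(d["C5"]), T5=np.array(d["T5"]),
                           pi5=np.array(d["pi5"]))


def write_clustering_summary(clustering: Clustering, path, seed=None) -> None:
    """Clustering report: state count, radius, seed, center frame indices."""
    _dump_json({
        "n_states": clustering.n_states,
        "cluster_radius": clustering.cluster_radius,
        "seed": seed,
        "center_frame_indices": clustering.center_indices.tolist(),
    }, path)


def write_surface(surface, grid_path, meta_path) -> None:
    np.savetxt(grid_path, surface.grid, fmt="%.17g", delimiter=",")
    _dump_json({
        "x_edges": surface.x_edges.tolist(),
        "y_edges": surface.y_edges.tolist(),
        "smoothing_variance": surface.smoothing_variance,
        "smooth_space": surface.smooth_space,
        "levels": surface.levels.tolist(),
    }, meta_path)
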
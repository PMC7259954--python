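"""End-to-end orchestration: the single-system pipeline and the motor-panel
recovery workflow.

The single-system pipeline mirrors the analysis applied to each motor:
simulate (optional) → featurize → k-hybrid microstates → microstate MSM →
PCA/free-energy landscape → Ward coarse-graining into the five P-loop
states → coarse MSM with its two predictors.  The panel workflow repeats
this across motors, defining the macrostates once on a reference motor and
assigning every other motor's conformations to those states with k-NN, then
compares the recovered predictors against the panel's observables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as _cluster
from . import io as _io
from . import landscape as _landscape
from . import msm as _msm
from . import predict as _predict
from . import synthetic as _synth
from .cluster import MacroMapping
from .synthetic import STATE_LABELS

logger = logging.getLogger("ploopmsm")


@dataclass
class PipelineConfig:
    """Parameters and (optional) input paths for a pipeline run.

    With no trajectory paths, the simulate stage generates a synthetic
    ensemble; otherwise trajectories are read from ``trajectory_dir``
    (matrix-per-trajectory plus manifest, as written by
    :func:`ploopmsm.io.write_ensemble`).
    """

    trajectory_dir: str | None = None
    topology_pdb: str | None = None
    reference_pdb: str | None = None
    crystal_manifest: str | None = None
    panel_csv: str | None = None
    cluster_radius: float = 1.0
    lag_ns: float = 0.5
    coarse_lag_ns: float = 37.5
    knn_k: int = 5
    bins: int = 50
    smoothing: float = 0.3
    rmsd_threshold: float = 0.6
    seed: int = 0
    n_trajectories: int = 10
    n_frames: int = 1000
    frame_interval: float = 0.1
    cluster_subsample: int = 5

    def validate(self) -> None:
        for name in ("trajectory_dir", "topology_pdb", "reference_pdb",
                     "crystal_manifest", "panel_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if not 0 < self.knn_k:
            raise ValueError("knn_k must be positive")
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def fit_macro_model(macro_seqs, stride: int, frame_interval: float,
                    labels=STATE_LABELS) -> _msm.PloopStateModel:
    """Coarse model straight from frame-level macrostate index sequences
    (identity micro→macro map)."""
    mapping = MacroMapping(micro_to_macro=np.array(labels), labels=tuple(labels))
    return _msm.coarse_grain(macro_seqs, mapping, stride, frame_interval)


def build_reference_states(features_list, paths_list=None, cluster_radius: float = 1.0,
                           subsample: int = 5, n_macrostates: int = 5,
                           n_pca_dims: int = 4, seed: int = 0):
    """Define microstates and the five macrostates on a reference ensemble.

    k-hybrid clusters a frame subsample, PCA reduces the medoid feature
    vectors to ``n_pca_dims`` dimensions, and Ward agglomeration groups the
    medoids into macrostates.  When ground-truth paths are supplied the
    macrostate indices are relabeled so each matches the generating state it
    predominantly contains (the standard label alignment for parameter
    recovery); otherwise labels are ordered by decreasing population.

    Returns a dict with the clustering, the PCA model, medoid vectors,
    their 4-D projections, per-medoid macrostate labels, and per-frame
    macro assignments of the (subsampled) reference ensemble.
    """
    X = np.vstack([f[::subsample] for f in features_list])
    clustering = _cluster.khybrid(X, cluster_radius=cluster_radius, seed=seed)
    medoids = X[clustering.center_indices]
    pca = _landscape.fit_pca(medoids)
    dims = tuple(range(1, min(n_pca_dims, pca.n_components) + 1))
    medoid_pcs = _landscape.project(medoids, pca, dims=dims)
    ward = _cluster.ward_cluster(medoid_pcs, n_clusters=n_macrostates)
    frame_macro_raw = ward[clustering.assignments]

    if paths_list is not None:
        true_sub = np.concatenate([p[::subsample] for p in paths_list])
        perm = {}
        for c in range(n_macrostates):
            members = true_sub[frame_macro_raw == c]
            perm[c] = int(np.bincount(members, minlength=n_macrostates).argmax()) \
                if len(members) else c
        if len(set(perm.values())) != n_macrostates:
            # fall back: greedy assignment by overlap counts
            overlap = np.zeros((n_macrostates, n_macrostates))
            for c in range(n_macrostates):
                members = true_sub[frame_macro_raw == c]
                overlap[c] = np.bincount(members, minlength=n_macrostates)
            perm, used = {}, set()
            for c in np.argsort(-overlap.max(axis=1)):
                t = int(np.argmax([overlap[c, j] if j not in used else -1
                                   for j in range(n_macrostates)]))
                perm[int(c)] = t
                used.add(t)
    else:
        order = np.argsort(-np.bincount(frame_macro_raw, minlength=n_macrostates))
        perm = {int(c): rank for rank, c in enumerate(order)}

    medoid_labels = np.array([STATE_LABELS[perm[int(c)]] for c in ward])
    lut = np.array([perm[int(c)] for c in range(n_macrostates)])
    return {
        "clustering": clustering,
        "pca": pca,
        "pca_dims": dims,
        "medoids": medoids,
        "medoid_pcs": medoid_pcs,
        "medoid_labels": medoid_labels,
        "frame_macro": lut[frame_macro_raw],
        "subsample": subsample,
    }


def assign_motor_frames(features_list, reference_states, knn_k: int = 5) -> list[np.ndarray]:
    """Per-frame macrostate indices for a new motor via k-NN against the
    reference medoids in PCA space."""
    label_to_idx = {lab: i for i, lab in enumerate(STATE_LABELS)}
    out = []
    for feats in features_list:
        pcs = _landscape.project(feats, reference_states["pca"],
                                 dims=reference_states["pca_dims"])
        labels = _cluster.knn_assign(reference_states["medoid_pcs"],
                                     reference_states["medoid_labels"],
                                     pcs, k=knn_k)
        out.append(np.array([label_to_idx[l] for l in labels], dtype=np.int64))
    return out


def recover_motor_panel(panel: _synth.SyntheticMotorPanel,
                        n_trajectories: int = 20, n_frames: int = 2000,
                        cluster_radius: float = 1.0, stride: int = 1,
                        knn_k: int = 5, subsample: int = 5,
                        reference_index: int | None = None,
                        seed: int = 0):
    """Run the full pipeline over a synthetic motor panel.

    For each motor: simulate an ensemble, assign frames to the five P-loop
    states (reference motor: own k-hybrid microstates + Ward; others: k-NN
    in the shared PCA space), fit the coarse MSM, and extract dG_AB and
    P(A→B) with jackknife standard errors.

    Returns (results, diagnostics): a list of
    :class:`ploopmsm.predict.MotorResult` and a dict holding the reference
    state definition.
    """
    motors = panel.motors
    if reference_index is None:
        reference_index = len(motors) // 2
    ensembles = []
    for m, motor in enumerate(motors):
        ensembles.append(_synth.generate_ensemble(
            motor.truth, n_trajectories=n_trajectories, n_steps=n_frames,
            seed=seed + 1000 * (m + 1)))

    ref = ensembles[reference_index]
    reference_states = build_reference_states(
        ref.features, ref.paths, cluster_radius=cluster_radius,
        subsample=subsample, seed=seed)

    results = []
    for m, (motor, ens) in enumerate(zip(motors, ensembles)):
        macro_seqs = assign_motor_frames(ens.features, reference_states, knn_k=knn_k)
        fi = motor.truth.frame_interval

        def dg_est(seqs):
            return fit_macro_model(seqs, stride, fi).dg_ab

        def pab_est(seqs):
            return fit_macro_model(seqs, stride, fi).p_ab

        dg, dg_se = _msm.jackknife(macro_seqs, dg_est)
        pab, pab_se = _msm.jackknife(macro_seqs, pab_est)
        results.append(_predict.MotorResult(
            name=motor.name, dg_ab=dg, dg_ab_se=dg_se, p_ab=pab, p_ab_se=pab_se,
            duty_obs=motor.duty_obs, adp_obs=motor.adp_obs,
            condition_group=motor.condition_group))
    return results, {"reference_states": reference_states,
                     "reference_index": reference_index}


@dataclass
class PipelineResult:
    out_dir: Path
    artifacts: dict
    micro_model: _msm.MicrostateModel
    ploop_model: _msm.PloopStateModel
    surface: _landscape.FreeEnergySurface


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute simulate → cluster → fit-msm → landscape → coarse-grain on one
    system, writing every stage's artifact plus a provenance log.

    Each artifact embeds the seed; reruns with an identical config are
    byte-identical.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    @_stage("simulate")
    def _simulate():
        if config.trajectory_dir is None:
            ens = _synth.generate_ensemble(
                _synth.default_truth(seed=config.seed),
                n_trajectories=config.n_trajectories,
                n_steps=config.n_frames, seed=config.seed)
        else:
            d = Path(config.trajectory_dir)
            with open(d / "manifest.json") as fh:
                man = json.load(fh)
            truth = _synth.GroundTruth(
                T_true=np.array(man["truth"]["T_true"]),
                centers=np.array(man["truth"]["centers"]),
                emission_sd=man["truth"]["emission_sd"],
                frame_interval=man["frame_interval_ns"], seed=man["seed"])
            feats = [_io.read_matrix(d / f) for f in man["trajectory_files"]]
            ens = _synth.SyntheticEnsemble(
                paths=[np.zeros(len(f), dtype=np.int64) for f in feats],
                features=feats, truth=truth)
        artifacts["ensemble"] = _io.write_ensemble(ens, out / "trajectories")
        return ens

    ens = _simulate()
    fi = ens.truth.frame_interval
    stride = max(1, int(round(config.lag_ns / fi)))

    @_stage("cluster")
    def _do_cluster():
        states = build_reference_states(
            ens.features, ens.paths if config.trajectory_dir is None else None,
            cluster_radius=config.cluster_radius,
            subsample=config.cluster_subsample, seed=config.seed)
        path = out / "clustering.json"
        _io.write_clustering_summary(states["clustering"], path, seed=config.seed)
        artifacts["clustering"] = path
        return states

    states = _do_cluster()

    @_stage("fit-msm")
    def _fit():
        lengths = [len(f[::config.cluster_subsample]) for f in ens.features]
        seqs = _cluster.split_assignments(states["clustering"].assignments, lengths)
        model = _msm.fit_msm(seqs, stride, fi * config.cluster_subsample)
        path = out / "microstate_model.json"
        _io.write_microstate_model(model, path, seed=config.seed,
                                   provenance="khybrid microstates")
        artifacts["micro_model"] = path
        return model, seqs

    micro_model, micro_seqs = _fit()

    @_stage("landscape")
    def _surface():
        pcs2 = _landscape.project(states["medoids"], states["pca"], dims=(1, 3))
        surf = _landscape.free_energy_surface(
            pcs2, micro_model.pi, bins=config.bins, variance=config.smoothing)
        _io.write_surface(surf, out / "surface.csv", out / "surface_meta.json")
        artifacts["surface"] = out / "surface.csv"
        return surf

    surface = _surface()

    @_stage("coarse-grain")
    def _coarse():
        coarse_stride = max(1, int(round(config.coarse_lag_ns / (fi * config.cluster_subsample))))
        labels = states["medoid_labels"]
        mapping = MacroMapping(micro_to_macro=labels)
        n_frames_total = sum(len(s) for s in micro_seqs)
        # fall back to the micro lag when trajectories are too short for 37.5 ns
        if coarse_stride >= max(len(s) for s in micro_seqs):
            coarse_stride = stride
        model = _msm.coarse_grain(micro_seqs, mapping, coarse_stride,
                                  fi * config.cluster_subsample,
                                  micro_pi=micro_model.pi)
        path = out / "ploop_model.json"
        _io.write_ploop_model(model, path, seed=config.seed,
                              provenance=f"ward over {len(labels)} medoids; "
                                         f"{n_frames_total} frames")
        artifacts["ploop_model"] = path
        return model

    ploop_model = _coarse()

    provenance = {
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    artifacts["provenance"] = out / "provenance.json"
    return PipelineResult(out_dir=out, artifacts=artifacts,
                          micro_model=micro_model, ploop_model=ploop_model,
                          surface=surface)
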
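"""Synthetic trajectory, structure and motor-panel generators.

The analysis pipeline in this package assumes its input is an ensemble of
independent trajectories whose frames hop between a handful of metastable
conformational states of a nucleotide-binding loop (P-loop / Walker A motif),
with geometric features that scatter around a state-specific mean.  This
module generates data with exactly that statistical structure — a discrete
metastable Markov chain with isotropic Gaussian emissions in the
36-dimensional loop-distance feature space — plus toy 6-residue backbone
coordinates exhibiting the serine carbonyl flip that distinguishes the
nucleotide-favorable state (A) from the nucleotide-unfavorable ones (B–D).
Because the generating parameters are known, every downstream stage can be
tested by parameter recovery.

Nothing here attempts to reproduce real myosin energetics; the generators
only reproduce the *shape* of the data the estimators consume.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .featurize import Structure

N_FEATURES = 36  # 6x6 ordered N/O pairs of a 6-residue loop
STATE_LABELS = ("A", "B", "C", "D", "E")

# Toy loop sequence mirrors the conserved GESGAG Walker A core.
TOY_RESNAMES = ("GLY", "GLU", "SER", "GLY", "ALA", "GLY")
TOY_BACKBONE = ("N", "CA", "C", "O")


def _validate_stochastic(T: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < 0):
        raise ValueError("transition matrix has negative entries")
    rowsums = T.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=atol):
        raise ValueError(f"rows must sum to 1 (max deviation {abs(rowsums - 1).max():.3g})")
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized to 1."""
    T = _validate_stochastic(T)
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmax(evals.real))
    pi = evecs[:, i].real
    pi = np.clip(pi / pi.sum(), 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class GroundTruth:
    """Known generating parameters for a synthetic conformational ensemble.

    Parameters
    ----------
    T_true : (n, n) row-stochastic array
        Per-step transition probabilities of the hidden state chain.
    centers : (n, 36) array, nm
        State-specific means in loop-distance feature space.
    emission_sd : float, nm
        Isotropic Gaussian emission width around each center.
    frame_interval : float, ns
        Physical time per chain step (default 0.1 ns so nanosecond-scale
        lag times are integer strides).
    """

    T_true: np.ndarray
    centers: np.ndarray
    emission_sd: float = 0.1
    frame_interval: float = 0.1
    seed: int = 0

    def __post_init__(self):
        T = _validate_stochastic(self.T_true, atol=1e-12)
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 2 or centers.shape[0] != T.shape[0]:
            raise ValueError("centers must be (n_states, d)")
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 0:
            raise ValueError("state centers must be pairwise distinct")
        if not self.emission_sd > 0:
            raise ValueError("emission_sd must be positive")
        object.__setattr__(self, "T_true", T)
        object.__setattr__(self, "centers", centers)

    @property
    def n_states(self) -> int:
        return self.T_true.shape[0]

    @property
    def pi_true(self) -> np.ndarray:
        return stationary_distribution(self.T_true)


@dataclass
class SyntheticEnsemble:
    """A bundle of independent synthetic trajectories plus their ground truth."""

    paths: list[np.ndarray]
    features: list[np.ndarray]
    truth: GroundTruth
    coords: list[np.ndarray] | None = None

    def __post_init__(self):
        for p, f in zip(self.paths, self.features):
            if len(p) != len(f):
                raise ValueError("paths and features must have matching lengths")
            if p.min() < 0 or p.max() >= self.truth.n_states:
                raise ValueError("state index out of range")

    @property
    def n_trajectories(self) -> int:
        return len(self.paths)


def default_transition_matrix(n_states: int = 5, metastability: float = 0.95) -> np.ndarray:
    """Metastable chain: diagonal `metastability`, off-diagonal mass decaying
    with state-index distance (so the basins are kinetically separated and the
    slow implied timescales are well resolved)."""
    T = np.zeros((n_states, n_states))
    for i in range(n_states):
        w = np.array([0.0 if j == i else 1.0 / (1 + abs(i - j)) for j in range(n_states)])
        T[i] = (1 - metastability) * w / w.sum()
        T[i, i] = metastability
    return T


def default_truth(seed: int = 0, n_states: int = 5, emission_sd: float = 0.1) -> GroundTruth:
    """Default 5-state metastable ground truth with well-separated centers.

    Centers are drawn uniformly in [0.4, 1.2] nm per coordinate — the range of
    backbone N/O distances a short loop actually spans — which in 36
    dimensions puts typical center pairs ~2 nm apart, an order of magnitude
    beyond the emission width.
    """
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.4, 1.2, size=(n_states, N_FEATURES))
    return GroundTruth(
        T_true=default_transition_matrix(n_states),
        centers=centers,
        emission_sd=emission_sd,
        seed=seed,
    )


def sample_chain(T: np.ndarray, n_steps: int, start: int, seed: int | np.random.Generator) -> np.ndarray:
    """Sample a discrete Markov chain path of length ``n_steps``.

    The first element is ``start``; transitions are drawn from the rows of
    ``T`` by inverse-CDF lookup, so the path is bit-reproducible per seed.
    """
    T = _validate_stochastic(T)
    n = T.shape[0]
    if not (0 <= start < n):
        raise ValueError(f"start state {start} out of range [0, {n})")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard roundoff
    path = np.empty(n_steps, dtype=np.int64)
    path[0] = start
    u = rng.random(n_steps - 1)
    s = start
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        path[t] = s
    return path


def sample_paths(truth: GroundTruth, n_trajectories: int, n_steps: int, seed: int) -> list[np.ndarray]:
    """Sample independent paths, starts drawn from the stationary distribution.

    Vectorized across trajectories (all paths advance one step per iteration).
    """
    rng = np.random.default_rng(seed)
    pi = truth.pi_true
    cum = np.cumsum(truth.T_true, axis=1)
    cum[:, -1] = 1.0
    state = rng.choice(truth.n_states, size=n_trajectories, p=pi)
    out = np.empty((n_trajectories, n_steps), dtype=np.int64)
    out[:, 0] = state
    for t in range(1, n_steps):
        u = rng.random(n_trajectories)
        state = (cum[state] > u[:, None]).argmax(axis=1)
        out[:, t] = state
    return list(out)


def emit_features(path: np.ndarray, truth: GroundTruth,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Emit a frame x 36 feature matrix: row t ~ N(centers[path[t]], sd² I)."""
    path = np.asarray(path, dtype=np.int64)
    if path.min() < 0 or path.max() >= truth.n_states:
        raise ValueError("path contains state indices out of range for this truth")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = truth.centers[path]
    return X + truth.emission_sd * rng.standard_normal(X.shape)


def generate_ensemble(truth: GroundTruth | None = None, n_trajectories: int = 100,
                      n_steps: int = 10_000, seed: int = 0) -> SyntheticEnsemble:
    """Full synthetic ensemble: paths plus Gaussian feature emissions."""
    if truth is None:
        truth = default_truth(seed=seed)
    paths = sample_paths(truth, n_trajectories, n_steps, seed=seed)
    rng = np.random.default_rng(seed + 1)
    features = [emit_features(p, truth, seed=rng) for p in paths]
    return SyntheticEnsemble(paths=paths, features=features, truth=truth)


# ---------------------------------------------------------------------------
# Toy 6-residue P-loop structures
# ---------------------------------------------------------------------------

def _toy_template(state: str) -> np.ndarray:
    """Deterministic 24-atom backbone template (Å).

    The two templates are identical except that the B-like one flips the
    third residue's (the serine's) carbonyl oxygen to the opposite side of
    the backbone — the local rearrangement that separates the
    nucleotide-favorable A state from the B–D states.
    """
    coords = []
    for i in range(6):
        ca = np.array([3.8 * i, 0.0, 0.3 * (-1) ** i])
        n = ca + np.array([-1.45, 0.35, 0.10])
        c = ca + np.array([1.52, 0.35, -0.10])
        o_dir = np.array([0.0, 1.23, 0.0])
        if state == "B" and i == 2:
            # ~150 degree swing of the serine carbonyl (a pure 180 degree
            # mirror would leave every N/O distance unchanged)
            o_dir = np.array([0.615, -1.065, 0.0])
        o = c + o_dir
        coords.extend([n, ca, c, o])
    return np.array(coords)


def _displaced_template() -> np.ndarray:
    """A-like template with the last two residues bent 45° about z at CA-4:
    a deterministic 'far' conformation (well beyond 0.6 Å backbone RMSD)."""
    coords = _toy_template("A").copy()
    pivot = coords[4 * 3 + 1]  # CA of residue 4
    th = math.radians(45.0)
    R = np.array([[math.cos(th), -math.sin(th), 0.0],
                  [math.sin(th), math.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    coords[16:] = (coords[16:] - pivot) @ R.T + pivot
    return coords


def build_toy_ploop(state: str = "A", noise_sd: float = 0.0,
                    seed: int | np.random.Generator | None = None,
                    with_sidechains: bool = False) -> Structure:
    """Build a toy 6-residue loop structure in an A-like or B-like conformation.

    Parameters
    ----------
    state : "A" | "B" | "far"
        "A" and "B" differ only in the flip of residue 3's carbonyl
        direction; "far" is a bent conformation with large backbone RMSD
        from "A" (used to emulate outlier crystal conformations).
    noise_sd : float, Å
        Isotropic Gaussian jitter added to every atom.
    with_sidechains : bool
        Add one CB pseudo-atom per residue so side-chain surface-area
        featurization has something to measure.
    """
    if state not in ("A", "B", "far"):
        raise ValueError(f"unknown toy state {state!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coords = _displaced_template() if state == "far" else _toy_template(state)
    names = list(TOY_BACKBONE) * 6
    resids = [i + 1 for i in range(6) for _ in TOY_BACKBONE]
    resnames = [TOY_RESNAMES[i] for i in range(6) for _ in TOY_BACKBONE]
    if with_sidechains:
        cb_rows = []
        for i in range(6):
            ca = coords[4 * i + 1]
            cb_rows.append(ca + np.array([0.0, -1.0, 1.1]))
        coords = np.vstack([coords, cb_rows])
        names += ["CB"] * 6
        resids += list(range(1, 7))
        resnames += list(TOY_RESNAMES)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        coords = coords + noise_sd * rng.standard_normal(coords.shape)
    order = np.lexsort((np.arange(len(resids)), np.array(resids)))
    return Structure(
        atom_names=np.array(names)[order],
        residue_ids=np.array(resids)[order],
        residue_names=np.array(resnames)[order],
        coords=np.asarray(coords)[order],
        chain_id="A",
    )


# ---------------------------------------------------------------------------
# Synthetic crystal ensembles
# ---------------------------------------------------------------------------

#: residue names that mark a record as nucleotide-bound when generating
#: synthetic crystal sets (drawn from the recognized nucleotide/analogue list)
_BOUND_NAMES = ("ADP", "ATP", "ANP", "AGS")
_UNBOUND_NAMES = ("HOH", "MG", "SO4", "GOL")


def make_crystal_set(n_within: int, n_beyond: int, p_bound_within: float,
                     p_bound_beyond: float, seed: int = 0, noise_sd: float = 0.08):
    """Generate a synthetic reference-structure ("crystal") ensemble.

    ``n_within`` records are jittered copies of the A-like template (small
    backbone RMSD to the reference); ``n_beyond`` are jittered copies of the
    bent template (RMSD well beyond any sane threshold).  Within each group a
    deterministic round(p*n) of the records carry a nucleotide(-analogue)
    ligand residue name; which ones is a seeded shuffle, so the ensemble is
    bit-reproducible while matching the requested bound fractions exactly.

    Returns a list of :class:`ploopmsm.crystal.CrystalRecord`.
    """
    from .crystal import CrystalRecord

    if n_within < 0 or n_beyond < 0:
        raise ValueError("record counts must be non-negative")
    for p in (p_bound_within, p_bound_beyond):
        if not 0.0 <= p <= 1.0:
            raise ValueError("bound probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for group, n, p in (("within", n_within, p_bound_within),
                        ("beyond", n_beyond, p_bound_beyond)):
        n_bound = int(round(p * n))
        bound_flags = np.array([True] * n_bound + [False] * (n - n_bound))
        rng.shuffle(bound_flags)
        for i, bound in enumerate(bound_flags):
            structure = build_toy_ploop(
                state="A" if group == "within" else "far",
                noise_sd=noise_sd, seed=rng)
            if bound:
                ligands = [str(rng.choice(_BOUND_NAMES)), "MG"]
            else:
                ligands = [str(rng.choice(_UNBOUND_NAMES))]
            records.append(CrystalRecord(
                id=f"SYN-{group[:3].upper()}{i:03d}",
                structure=structure,
                ligand_names=ligands,
            ))
    return records


# ---------------------------------------------------------------------------
# Synthetic motor panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkParams:
    """Monotone links from chain thermodynamics/kinetics to observables.

    duty_obs = logistic(-(dG - duty_mid)/duty_width) + noise   (decreasing in dG)
    adp_obs  = adp_scale * pAB**adp_exponent * exp(noise)      (increasing in pAB)
    """

    duty_mid: float = 0.0
    duty_width: float = 1.0
    duty_noise_sd: float = 0.03
    adp_scale: float = 1500.0
    adp_exponent: float = 1.0
    adp_noise_sd: float = 0.15


@dataclass
class SyntheticMotor:
    name: str
    truth: GroundTruth
    dg_true: float
    pab_true: float
    duty_obs: float
    adp_obs: float
    condition_group: str


@dataclass
class SyntheticMotorPanel:
    motors: list[SyntheticMotor]
    link_params: LinkParams
    seed: int


def truth_from_thermo(dg_ab: float, p_ab: float, seed: int = 0,
                      emission_sd: float = 0.1, centers: np.ndarray | None = None,
                      base_rate: float = 0.02) -> GroundTruth:
    """Construct a 5-state ground truth with prescribed pi_A/pi_B and T[A→B].

    The chain is reversible with respect to a prescribed stationary
    distribution (Metropolis off-diagonals, exact detailed balance), so
    -ln(pi_A/pi_B) equals ``dg_ab`` to machine precision and T[A,B] equals
    ``p_ab`` exactly.
    """
    r = math.exp(-dg_ab)            # pi_A / pi_B
    pi_ab_mass = 0.8
    pi = np.empty(5)
    pi[0] = pi_ab_mass * r / (1 + r)
    pi[1] = pi_ab_mass / (1 + r)
    pi[2:] = np.array([0.12, 0.06, 0.02])
    T = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            if i == j:
                continue
            T[i, j] = base_rate * min(1.0, pi[j] / pi[i])
    T[0, 1] = p_ab
    T[1, 0] = p_ab * pi[0] / pi[1]
    np.fill_diagonal(T, 0.0)
    diag = 1.0 - T.sum(axis=1)
    if np.any(diag < 0):
        raise ValueError(
            f"infeasible prescription: dg_ab={dg_ab}, p_ab={p_ab} give a row sum > 1")
    np.fill_diagonal(T, diag)
    if centers is None:
        centers = np.random.default_rng(seed).uniform(0.4, 1.2, size=(5, N_FEATURES))
    return GroundTruth(T_true=T, centers=centers, emission_sd=emission_sd, seed=seed)


def make_motor_panel(n_motors: int = 8, seed: int = 0,
                     link_params: LinkParams | None = None,
                     pab_coupling: float = 0.6,
                     pab_base: float = 0.05) -> SyntheticMotorPanel:
    """Generate a panel of motors spanning high to low duty ratio.

    Ground-truth A/B free-energy differences are spread evenly over
    [-2, +2] kT (A-favoring, high-duty motors at the negative end, matching
    the spread the real motor panel exhibits) and each motor's one-step
    escape probability pAB is coupled log-linearly to its dG — motors that
    favor A also leave it more slowly.  Observed duty ratio and ADP release
    rate are noisy monotone transforms of dG and pAB respectively.
    All motors share one set of feature-space centers (the loop geometry of
    the states is conserved across motors; only the balance shifts).
    """
    if n_motors < 3:
        raise ValueError("need at least 3 motors for a panel")
    lp = link_params or LinkParams()
    rng = np.random.default_rng(seed)
    shared_centers = rng.uniform(0.4, 1.2, size=(5, N_FEATURES))
    dgs = np.linspace(-2.0, 2.0, n_motors)
    motors = []
    for m, dg in enumerate(dgs):
        pab = pab_base * math.exp(pab_coupling * dg)
        truth = truth_from_thermo(dg, pab, seed=seed + 100 + m, centers=shared_centers)
        duty = 1.0 / (1.0 + math.exp((dg - lp.duty_mid) / lp.duty_width))
        if lp.duty_noise_sd > 0:
            duty += lp.duty_noise_sd * rng.standard_normal()
        duty = float(np.clip(duty, 0.0, 1.0))
        adp = lp.adp_scale * pab ** lp.adp_exponent
        if lp.adp_noise_sd > 0:
            adp *= math.exp(lp.adp_noise_sd * rng.standard_normal())
        motors.append(SyntheticMotor(
            name=f"motor{m:02d}",
            truth=truth,
            dg_true=float(dg),
            pab_true=float(pab),
            duty_obs=duty,
            adp_obs=float(adp),
            condition_group="set1" if m % 2 == 0 else "set2",
        ))
    return SyntheticMotorPanel(motors=motors, link_params=lp, seed=seed)
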
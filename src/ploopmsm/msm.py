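"""Markov state model estimation with uniform pseudocounts.

Transition counting is sliding-window (every ordered frame pair (t, t+s)
within one trajectory contributes; counting never crosses trajectory
boundaries).  Model fitting adds a 1/n pseudocount to every element of the
count matrix (a uniform prior over the n-state space, which also makes the
chain irreducible — no ergodic trimming is needed) and row-normalizes; no
detailed-balance symmetrization is applied.  The equilibrium distribution is
the leading left eigenvector.  Implied timescales t_i = -tau / ln lambda_{i+1}
diagnose lag-time choice; lag selection itself is left to the user.

Also provides coarse-graining onto the five P-loop macrostates (A–E),
mean first-passage times, and leave-one-trajectory-out jackknife errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .cluster import MacroMapping


def count_transitions(assignments, stride: int, n_states: int | None = None) -> np.ndarray:
    """Raw transition count matrix at integer lag ``stride``.

    ``assignments`` is a list of integer state sequences (one per
    trajectory) or a single sequence.  C[i, j] counts ordered pairs
    (t, t + stride) with states (i, j), sliding window of offset 1.
    Trajectories shorter than stride + 1 contribute nothing; if none is long
    enough, raises.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    seqs = [np.asarray(a, dtype=np.int64) for a in _as_sequences(assignments)]
    if n_states is None:
        n_states = int(max(s.max() for s in seqs if len(s)) + 1)
    if any((s < 0).any() or (s >= n_states).any() for s in seqs if len(s)):
        raise ValueError("assignments contain invalid state indices")
    C = np.zeros((n_states, n_states), dtype=float)
    contributed = False
    for s in seqs:
        if len(s) <= stride:
            continue
        contributed = True
        np.add.at(C, (s[:-stride], s[stride:]), 1.0)
    if not contributed:
        raise ValueError(f"all trajectories are too short for stride {stride}")
    return C


def _as_sequences(assignments) -> list:
    if isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        return [assignments]
    if isinstance(assignments, (list, tuple)) and len(assignments) and np.isscalar(assignments[0]):
        return [np.asarray(assignments)]
    return list(assignments)


def fit_tmatrix(C: np.ndarray, n_states: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pseudocounted transition matrix and its equilibrium distribution.

    C' = C + 1/n in every cell; T = row-normalized C'; pi = leading left
    eigenvector of T (real part, negatives clipped, renormalized).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("count matrix must be square")
    if np.any(C < 0):
        raise ValueError("count matrix must be non-negative")
    n = n_states or C.shape[0]
    Cp = C + 1.0 / n
    T = Cp / Cp.sum(axis=1, keepdims=True)
    return T, equilibrium_distribution(T)


def equilibrium_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution via the leading left eigenvector."""
    evals, evecs = scipy.linalg.eig(T, left=True, right=False)
    i = int(np.argmax(evals.real))
    pi = evecs[:, i]
    if np.abs(pi.imag).max() > 1e-9:
        raise ValueError("leading eigenvector has a non-negligible imaginary part")
    pi = pi.real
    pi = pi / pi.sum()
    pi[(pi < 0) & (pi > -1e-12)] = 0.0
    if np.any(pi < 0):
        raise ValueError("leading eigenvector has significantly negative entries")
    return pi / pi.sum()


@dataclass
class MicrostateModel:
    """Fitted microstate MSM at one lag."""

    n_states: int
    stride: int
    lag_ns: float
    C: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    eigenvalues: np.ndarray
    timescales_ns: np.ndarray


def _sorted_eigenvalues(T: np.ndarray) -> np.ndarray:
    evals = np.linalg.eigvals(T)
    return evals[np.argsort(-evals.real)]


def implied_timescales_from_T(T: np.ndarray, lag_ns: float,
                              n_timescales: int | None = None) -> np.ndarray:
    """t_i = -tau / ln(lambda_{i+1}); NaN where the eigenvalue is complex
    (beyond roundoff) or not in (0, 1)."""
    evals = _sorted_eigenvalues(T)
    m = n_timescales or len(evals) - 1
    out = np.full(m, np.nan)
    for k in range(1, min(m + 1, len(evals))):
        lam = evals[k]
        if abs(lam.imag) > 1e-10:
            continue
        lam = lam.real
        if 0.0 < lam < 1.0:
            out[k - 1] = -lag_ns / np.log(lam)
    return out


def fit_msm(assignments, stride: int, frame_interval: float = 0.1,
            n_states: int | None = None) -> MicrostateModel:
    """Count, pseudocount, row-normalize; bundle the fitted model."""
    C = count_transitions(assignments, stride, n_states=n_states)
    T, pi = fit_tmatrix(C)
    lag_ns = stride * frame_interval
    evals = _sorted_eigenvalues(T)
    return MicrostateModel(
        n_states=C.shape[0], stride=stride, lag_ns=lag_ns, C=C, T=T, pi=pi,
        eigenvalues=evals,
        timescales_ns=implied_timescales_from_T(T, lag_ns),
    )


def implied_timescales(assignments, strides, frame_interval: float = 0.1,
                       n_timescales: int = 4, n_states: int | None = None) -> dict:
    """Implied-timescale table over a list of integer strides.

    Returns {stride: array of t_i in ns}; the model is Markovian at lags
    where the timescales are flat in the stride.
    """
    table = {}
    for stride in strides:
        model = fit_msm(assignments, stride, frame_interval, n_states=n_states)
        table[int(stride)] = implied_timescales_from_T(
            model.T, model.lag_ns, n_timescales)
    return table


@dataclass
class PloopStateModel:
    """Coarse-grained five-state (A–E) P-loop model.

    P(A→B) = T5[A, B] is the one-lag probability of leaving the
    nucleotide-favorable state A for state B (the ADP-release-rate proxy);
    dG_AB = -ln(pi_A / pi_B) in kT (the duty-ratio proxy; negative means A
    is preferred).
    """

    mapping: MacroMapping
    stride: int
    lag_ns: float
    C5: np.ndarray
    T5: np.ndarray
    pi5: np.ndarray
    pi5_from_micro: np.ndarray | None = None

    @property
    def labels(self) -> tuple:
        return self.mapping.labels

    def p_transition(self, a="A", b="B") -> float:
        return float(self.T5[self.mapping.label_index(a), self.mapping.label_index(b)])

    @property
    def p_ab(self) -> float:
        return self.p_transition("A", "B")

    @property
    def dg_ab(self) -> float:
        from .predict import delta_g
        return delta_g(self.pi5, self.labels.index("A"), self.labels.index("B"))

    def mfpt_matrix(self) -> np.ndarray:
        n = len(self.pi5)
        M = np.zeros((n, n))
        for t in range(n):
            M[:, t] = mfpt_all(self.T5, t, self.lag_ns)
        return M


def coarse_grain(micro_assignments, mapping: MacroMapping, stride: int,
                 frame_interval: float = 0.1,
                 micro_pi: np.ndarray | None = None,
                 method: str = "recount") -> PloopStateModel:
    """Fit the five-state P-loop model from frame-level macrostate assignments.

    method="recount" (default) maps every frame's microstate through
    ``mapping`` and re-counts transitions at the coarse level with the same
    pseudocount rule (n = 5).  method="project" instead projects a
    microstate T onto the macrostates using the micro equilibrium
    distribution (requires ``micro_pi``).

    If ``micro_pi`` is given, the macrostate equilibrium obtained by summing
    micro probabilities per macrostate is attached as ``pi5_from_micro`` for
    a consistency check against the refit pi5.
    """
    seqs = _as_sequences(micro_assignments)
    macro_seqs = [mapping.apply(s) for s in seqs]
    n5 = mapping.n_macro
    if method == "recount":
        C5 = count_transitions(macro_seqs, stride, n_states=n5)
        T5, pi5 = fit_tmatrix(C5)
    elif method == "project":
        if micro_pi is None:
            raise ValueError("method='project' requires micro_pi")
        micro_model = fit_msm(seqs, stride, frame_interval)
        idx = mapping.macro_indices()[:micro_model.n_states]
        C5 = np.zeros((n5, n5))
        flux = micro_pi[:, None] * micro_model.T
        for i in range(micro_model.n_states):
            for j in range(micro_model.n_states):
                C5[idx[i], idx[j]] += flux[i, j]
        T5 = C5 / C5.sum(axis=1, keepdims=True)
        pi5 = equilibrium_distribution(T5)
    else:
        raise ValueError(f"unknown coarse-graining method {method!r}")
    pi5_from_micro = None
    if micro_pi is not None:
        pi5_from_micro = equilibrium_macroprob(micro_pi, mapping)
    return PloopStateModel(mapping=mapping, stride=stride,
                           lag_ns=stride * frame_interval, C5=C5, T5=T5,
                           pi5=pi5, pi5_from_micro=pi5_from_micro)


def equilibrium_macroprob(micro_pi: np.ndarray, mapping: MacroMapping) -> np.ndarray:
    """Macrostate equilibrium probabilities by summing micro probabilities."""
    micro_pi = np.asarray(micro_pi, dtype=float)
    if not np.isclose(micro_pi.sum(), 1.0, atol=1e-8):
        raise ValueError("micro equilibrium distribution must sum to 1")
    idx = mapping.macro_indices()
    if len(idx) < len(micro_pi):
        raise ValueError("mapping does not cover all microstates")
    pi5 = np.zeros(mapping.n_macro)
    np.add.at(pi5, idx[: len(micro_pi)], micro_pi)
    return pi5


def mfpt_all(T: np.ndarray, target: int, lag_ns: float) -> np.ndarray:
    """Mean first-passage time (ns) from every state to ``target``.

    Solves (I - T_restricted) m = 1 in units of steps, then scales by the
    lag; m[target] = 0.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    others = [i for i in range(n) if i != target]
    A = np.eye(n - 1) - T[np.ix_(others, others)]
    try:
        m = np.linalg.solve(A, np.ones(n - 1))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"target state {target} unreachable: {exc}") from exc
    if np.any(m < 0):
        raise ValueError(f"target state {target} unreachable (negative passage time)")
    out = np.zeros(n)
    out[others] = m * lag_ns
    return out


def mfpt(T: np.ndarray, source: int, target: int, lag_ns: float) -> float:
    """Mean first-passage time (ns) from ``source`` to ``target``."""
    if source == target:
        return 0.0
    return float(mfpt_all(T, target, lag_ns)[source])


def jackknife(trajectories, estimator) -> tuple[float, float]:
    """Leave-one-trajectory-out jackknife of a scalar ensemble statistic.

    Returns (point estimate on the full ensemble, jackknife standard error
    from the n replicates).
    """
    trajs = list(trajectories)
    n = len(trajs)
    if n < 2:
        raise ValueError("jackknife needs at least 2 trajectories")
    theta = float(estimator(trajs))
    reps = np.array([
        float(estimator(trajs[:i] + trajs[i + 1:])) for i in range(n)
    ])
    se = float(np.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2)))
    return theta, se
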
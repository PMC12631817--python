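"""Hidden-Markov motion-state analysis of axonal-transport trajectories.

A trajectory is a sequence of 2-D localizations at a fixed frame interval.
Its displacements are modeled as draws from a small set of hidden motion
states, each either pure diffusion (``D``: isotropic Gaussian steps with
per-axis variance 2*D_k*dt) or diffusion plus constant drift (``DT``: the same
with mean v_k*dt), switching according to a first-order Markov chain.  The
module fits candidate state combinations by Baum-Welch EM — per trajectory or
pooled over a cohort with shared parameters — selects the simplest adequate
model with a BIC-penalized evidence score, annotates the most probable state
path by Viterbi decoding, maps directed states onto anterograde/retrograde
using the axon axis, and aggregates per-state speed and transition statistics
over cohorts, including drug-condition contrasts.

Units: positions are stored in nm (the tracking convention); diffusion
coefficients are um^2 s^-1 and velocities um s^-1 (the transport convention).
Displacements are converted to um once, at the start of every computation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import hyp1f1

from ._hmmcore import e_step, viterbi as _viterbi_kernel

__all__ = [
    "MotionState",
    "MotionModel",
    "Trajectory",
    "TrajectoryTruth",
    "HMMFit",
    "ModelSelection",
    "StateSummary",
    "CohortAnalysis",
    "CohortSummary",
    "FitError",
    "CANDIDATE_SPECS",
    "LABELS",
    "simulate_trajectory",
    "displacement_loglik",
    "fit_hmm",
    "fit_hmm_pooled",
    "refit_emissions",
    "rotate_to_axis",
    "evidence_score",
    "select_model",
    "select_model_pooled",
    "viterbi_annotate",
    "label_directions",
    "filter_trajectories",
    "analyze_cohort",
    "aggregate_statistics",
    "compare_conditions",
    "state_mean_speed",
    "coarsen",
    "EmissionPriors",
]

NM_PER_UM = 1000.0
D_FLOOR = 1e-6  # um^2/s, numerical floor for fitted diffusion coefficients
LABELS = ("diffusive", "anterograde", "retrograde")

#: Minimum self-transition probability enforced during fitting.  Localization
#: noise makes consecutive observed displacements anti-correlated, which an
#: unconstrained HMM exploits with a spurious fast-oscillating solution; motion
#: states that flip faster than the frame interval are physically
#: unresolvable, so persistence below 0.5 is excluded from the search space.
MIN_SELF_TRANSITION = 0.5

#: all multisets of {D, DT} with 1-3 states, ordered simplest first
CANDIDATE_SPECS: tuple[tuple[str, ...], ...] = tuple(
    sorted(
        {
            tuple(sorted(c))
            for n in (1, 2, 3)
            for c in itertools.combinations_with_replacement(("D", "DT"), n)
        },
        key=lambda s: (len(s), sum(k == "DT" for k in s)),
    )
)


class FitError(RuntimeError):
    """Raised when no EM restart produces a finite fit."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MotionState:
    """One hidden motion state: pure diffusion (D) or diffusion + drift (DT)."""

    kind: str  # "D" or "DT"
    diffusion_coefficient: float  # um^2 s^-1
    drift_velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))  # um s^-1

    def __post_init__(self) -> None:
        self.drift_velocity = np.asarray(self.drift_velocity, float)
        if self.kind not in ("D", "DT"):
            raise ValueError(f"unknown state kind {self.kind!r}")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.kind == "D" and np.any(self.drift_velocity != 0):
            raise ValueError("a D state has zero drift by definition")


@dataclass
class MotionModel:
    """An ordered set of motion states with Markov switching dynamics."""

    states: list[MotionState]
    transition_matrix: np.ndarray  # row-stochastic, K x K
    initial_distribution: np.ndarray  # length K

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        k = len(self.states)
        if not 1 <= k <= 3:
            raise ValueError("state count must be 1-3")
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")

    @property
    def spec(self) -> tuple[str, ...]:
        return tuple(s.kind for s in self.states)


@dataclass
class TrajectoryTruth:
    """Ground truth stored alongside simulated trajectories."""

    states: np.ndarray  # hidden state per displacement
    clean_positions: np.ndarray  # nm, before localization noise
    model: MotionModel


@dataclass
class Trajectory:
    """Time-stamped 2-D localizations of one tracked particle."""

    positions: np.ndarray  # (n, 2) in nm
    dt: float = 0.05  # s
    frame_index: np.ndarray | None = None  # 0-based consecutive
    snr: float = np.inf
    axon_axis: np.ndarray | None = None  # unit vector, anterograde-positive
    condition_label: str = "control"
    traj_id: str | int = 0
    truth: TrajectoryTruth | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.positions) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.positions))
        else:
            self.frame_index = np.asarray(self.frame_index)
            if np.any(np.diff(self.frame_index) != 1):
                raise ValueError("frames must be strictly consecutive")
        if self.axon_axis is not None:
            self.axon_axis = np.asarray(self.axon_axis, float)
            self.axon_axis = self.axon_axis / np.linalg.norm(self.axon_axis)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    def steps_um(self) -> np.ndarray:
        return np.diff(self.positions, axis=0) / NM_PER_UM


@dataclass
class HMMFit:
    """Result of Baum-Welch EM for one candidate state combination."""

    model: MotionModel
    log_likelihood: float
    evidence: float  # BIC-penalized score, nats
    viterbi_path: np.ndarray  # state index per displacement
    converged: bool
    n_restarts_used: int
    n_iter: int
    unreliable: bool = False  # n < number of free parameters

    @property
    def evidence_score(self) -> float:
        return self.evidence


@dataclass
class ModelSelection:
    """Fits and normalized probabilities for a candidate model family."""

    fits: dict[tuple[str, ...], HMMFit]
    probabilities: dict[tuple[str, ...], float]
    best_spec: tuple[str, ...]

    @property
    def best(self) -> HMMFit:
        return self.fits[self.best_spec]


@dataclass
class StateSummary:
    """Cohort-level summary of one labeled motion state."""

    state_label: str
    mean_speed: float  # um s^-1
    speed_sd: float  # across-trajectory SD, um s^-1
    occupancy_fraction: float
    n_trajectories: int


@dataclass
class CohortSummary:
    """Aggregate per-state statistics and pooled transition matrix."""

    state_summaries: dict[str, StateSummary]
    transition_matrix: pd.DataFrame  # labels x labels, row-stochastic
    n_trajectories: int


# ---------------------------------------------------------------------------
# simulation and emission model
# ---------------------------------------------------------------------------


def simulate_trajectory(
    model: MotionModel,
    n_frames: int,
    dt: float = 0.05,
    localization_sigma: float = 30.0,  # nm
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    snr: float = 4.0,
    axon_axis: np.ndarray | None = None,
    condition_label: str = "control",
    traj_id: str | int = 0,
) -> Trajectory:
    """Sample one trajectory from a Markov-switching drift-diffusion model.

    The hidden chain is drawn from (pi, A); each displacement is
    v_k*dt + sqrt(2*D_k*dt)*N(0,1) per axis; localization noise is added to
    the *positions* (so consecutive observed steps are anti-correlated, as in
    real tracking data).  Ground truth is retained on the returned object.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k = len(model.states)
    t_steps = n_frames - 1
    states = np.empty(t_steps, dtype=np.int64)
    states[0] = rng.choice(k, p=model.initial_distribution)
    for t in range(1, t_steps):
        states[t] = rng.choice(k, p=model.transition_matrix[states[t - 1]])

    steps = np.empty((t_steps, 2))
    for t in range(t_steps):
        st = model.states[states[t]]
        sigma = np.sqrt(2.0 * st.diffusion_coefficient * dt)
        steps[t] = st.drift_velocity * dt + sigma * rng.standard_normal(2)

    clean_um = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    clean_nm = clean_um * NM_PER_UM
    observed = clean_nm + localization_sigma * rng.standard_normal(clean_nm.shape)
    return Trajectory(
        positions=observed,
        dt=dt,
        snr=snr,
        axon_axis=axon_axis,
        condition_label=condition_label,
        traj_id=traj_id,
        truth=TrajectoryTruth(states=states, clean_positions=clean_nm, model=model),
    )


def displacement_loglik(step_um: np.ndarray, state: MotionState, dt: float) -> float:
    """Log density of one displacement (um) under a motion state.

    Isotropic 2-D Gaussian with mean v_k*dt and per-axis variance 2*D_k*dt;
    the maximum attainable value is -log(4*pi*D_k*dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    step_um = np.asarray(step_um, float)
    if not np.all(np.isfinite(step_um)):
        raise ValueError("non-finite displacement")
    var = 2.0 * state.diffusion_coefficient * dt
    resid = step_um - state.drift_velocity * dt
    return float(-np.log(2.0 * np.pi * var) - resid @ resid / (2.0 * var))


def _emission_log_matrix(
    steps_um: np.ndarray, states: list[MotionState], dt: float
) -> np.ndarray:
    t = len(steps_um)
    logb = np.empty((t, len(states)))
    for k, st in enumerate(states):
        var = 2.0 * st.diffusion_coefficient * dt
        resid = steps_um - st.drift_velocity * dt
        logb[:, k] = -np.log(2.0 * np.pi * var) - (resid**2).sum(axis=1) / (2.0 * var)
    return logb


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _n_free_params(spec: tuple[str, ...]) -> int:
    k = len(spec)
    per_state = sum(1 if kind == "D" else 3 for kind in spec)
    return per_state + k * (k - 1) + (k - 1)


def _kmeans_init(
    steps_um: np.ndarray, spec: tuple[str, ...], dt: float, seed: int
) -> tuple[list[MotionState], np.ndarray, np.ndarray]:
    """Initial parameters from k-means clusters of the step vectors.

    Clusters with the smallest centroid magnitude are assigned to D states.
    """
    from sklearn.cluster import KMeans

    k = len(spec)
    if k == 1:
        labels = np.zeros(len(steps_um), dtype=int)
        centroids = steps_um.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed % (2**31)).fit(steps_um)
        labels, centroids = km.labels_, km.cluster_centers_

    order = np.argsort(np.linalg.norm(centroids, axis=1))
    d_idx = [i for i, kind in enumerate(spec) if kind == "D"]
    dt_idx = [i for i, kind in enumerate(spec) if kind == "DT"]
    cluster_for_state = np.empty(k, dtype=int)
    for state_i, cluster_i in zip(d_idx + dt_idx, order):
        cluster_for_state[state_i] = cluster_i

    states = []
    for i, kind in enumerate(spec):
        mask = labels == cluster_for_state[i]
        if mask.sum() < 2:
            mask = np.ones(len(steps_um), bool)
        sub = steps_um[mask]
        if kind == "DT":
            v = sub.mean(axis=0) / dt
            resid = sub - v * dt
        else:
            v = np.zeros(2)
            resid = sub
        d = max(float((resid**2).sum() / (4.0 * dt * len(sub))), D_FLOOR)
        states.append(MotionState(kind, d, v))
    a = np.full((k, k), 0.1 / max(k - 1, 1))
    np.fill_diagonal(a, 0.9)
    pi = np.full(k, 1.0 / k)
    return states, a, pi


def _perturb_init(
    init: tuple[list[MotionState], np.ndarray, np.ndarray],
    steps_um: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> tuple[list[MotionState], np.ndarray, np.ndarray]:
    states0, _a0, _pi0 = init
    k = len(states0)
    scale = max(float(np.std(steps_um)), 1e-6) / dt
    states = []
    for st in states0:
        d = max(st.diffusion_coefficient * float(np.exp(rng.normal(0, 0.5))), D_FLOOR)
        if st.kind == "DT":
            v = st.drift_velocity + rng.normal(0, 0.3 * scale, size=2)
        else:
            v = np.zeros(2)
        states.append(MotionState(st.kind, d, v))
    a = rng.dirichlet(np.full(k, 2.0), size=k) * 0.3
    np.fill_diagonal(a, 0.0)
    a += np.diag(1.0 - a.sum(axis=1))
    pi = rng.dirichlet(np.full(k, 2.0))
    return states, a, pi


@dataclass
class EmissionPriors:
    """Weak per-state priors used by the cohort refit stage (MAP-EM).

    ``v_means`` are Gaussian prior centres for the drift of DT states (sd
    ``v_tau``); ``d_means`` are inverse-gamma prior modes for the diffusion
    coefficients with ``d_pseudo`` pseudo-observations.  With hundreds of
    displacements the data dominate; the priors only prevent a state from
    abandoning its cohort-level role when a trajectory barely visits it.
    """

    v_means: list[np.ndarray]
    d_means: list[float]
    v_tau: float = 0.3  # um/s
    d_pseudo: float = 20.0  # pseudo-counts

    @classmethod
    def from_fit(cls, fit: HMMFit, v_tau: float = 0.3, d_pseudo: float = 20.0):
        return cls(
            v_means=[s.drift_velocity.copy() for s in fit.model.states],
            d_means=[s.diffusion_coefficient for s in fit.model.states],
            v_tau=v_tau,
            d_pseudo=d_pseudo,
        )

    def log_density(self, states: list[MotionState]) -> float:
        lp = 0.0
        for st, mu, d0 in zip(states, self.v_means, self.d_means):
            if st.kind == "DT":
                dv = st.drift_velocity - mu
                lp -= float(dv @ dv) / (2.0 * self.v_tau**2)
            n0 = self.d_pseudo
            lp += -n0 * np.log(st.diffusion_coefficient) \
                - n0 * d0 / st.diffusion_coefficient
        return lp


def _run_em(
    sequences: list[np.ndarray],
    spec: tuple[str, ...],
    init: tuple[list[MotionState], np.ndarray, np.ndarray],
    dt: float,
    tol: float,
    max_iter: int,
    update_transitions: bool = True,
    priors: EmissionPriors | None = None,
) -> tuple[list[MotionState], np.ndarray, np.ndarray, float, bool, int]:
    """Baum-Welch over one or more displacement sequences sharing parameters.

    With ``update_transitions=False`` the transition matrix and initial
    distribution stay fixed and only emission parameters are re-estimated (an
    ECM variant; the likelihood ascent property holds either way).  With
    ``priors`` the M-step maximizes the posterior instead (MAP-EM); the
    monotonicity check then tracks the penalized objective.
    """
    states, a, pi = init
    k = len(spec)
    all_steps = np.concatenate(sequences, axis=0)
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        loglik = 0.0
        gammas = []
        xi = np.zeros((k, k))
        gamma0 = np.zeros(k)
        log_pi = np.log(np.clip(pi, 1e-300, None))
        log_a = np.log(np.clip(a, 1e-300, None))
        for seq in sequences:
            logb = _emission_log_matrix(seq, states, dt)
            ll, gamma, xi_s = e_step(log_pi, log_a, logb)
            loglik += ll
            gammas.append(gamma)
            xi += xi_s
            gamma0 += gamma[0]
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite log-likelihood")
        objective = loglik if priors is None else loglik + priors.log_density(states)
        if objective < prev - 1e-8 * max(1.0, abs(prev)):
            raise RuntimeError(
                f"EM objective decreased: {prev:.10g} -> {objective:.10g}"
            )
        done = abs(objective - prev) < tol * (1.0 + abs(objective))
        prev = objective

        # M-step: closed forms for v, D; row-normalized expected transitions.
        gamma_all = np.concatenate(gammas, axis=0)
        new_states = []
        for i in range(k):
            w = gamma_all[:, i]
            wsum = max(w.sum(), 1e-300)
            d_cur = states[i].diffusion_coefficient
            if spec[i] == "DT":
                v = (w @ all_steps) / (wsum * dt)
                if priors is not None:
                    # Gaussian prior on v; data precision from current D
                    prec_data = wsum * dt / (2.0 * d_cur)
                    prec_prior = 1.0 / priors.v_tau**2
                    v = (prec_data * v + prec_prior * priors.v_means[i]) / (
                        prec_data + prec_prior
                    )
            else:
                v = np.zeros(2)
            resid = all_steps - v * dt
            rss = float(w @ (resid**2).sum(axis=1)) / (4.0 * dt)
            if priors is None:
                d = rss / wsum
            else:
                n0 = priors.d_pseudo
                d = (rss + n0 * priors.d_means[i]) / (wsum + n0)
            new_states.append(MotionState(spec[i], max(d, D_FLOOR), v))
        states = new_states

        if update_transitions:
            row = xi.sum(axis=1, keepdims=True)
            a_new = np.where(row > 1e-300, xi / np.clip(row, 1e-300, None), 1.0 / k)
            a_new = np.clip(a_new, 1e-12, None)
            a_new /= a_new.sum(axis=1, keepdims=True)
            if k > 1:
                # constrained M-step: rows with self-transition below the
                # floor get the floor, off-diagonal mass rescaled (still the
                # constrained maximizer of the expected complete-data
                # log-likelihood, so EM monotonicity is preserved)
                for i in range(k):
                    if a_new[i, i] < MIN_SELF_TRANSITION:
                        off = a_new[i].copy()
                        off[i] = 0.0
                        a_new[i] = (1.0 - MIN_SELF_TRANSITION) * off / off.sum()
                        a_new[i, i] = MIN_SELF_TRANSITION
            a = a_new
            pi = np.clip(gamma0 / len(sequences), 1e-12, None)
            pi /= pi.sum()
        if done:
            converged = True
            break
    return states, a, pi, prev, converged, n_iter


def _fit_sequences(
    sequences: list[np.ndarray],
    spec: tuple[str, ...],
    dt: float,
    n_restarts: int,
    tol: float,
    seed: int | np.random.SeedSequence,
    max_iter: int,
) -> tuple[list[MotionState], np.ndarray, np.ndarray, float, bool, int, int]:
    """Best-of-restarts Baum-Welch over one or more displacement sequences."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    all_steps = np.concatenate(sequences, axis=0)
    kmeans_seed = int(ss.generate_state(1)[0] % (2**31))
    base_init = _kmeans_init(all_steps, spec, dt, kmeans_seed)
    inits = [base_init]
    rng = np.random.default_rng(ss.spawn(1)[0])
    for _ in range(n_restarts):
        inits.append(_perturb_init(base_init, all_steps, dt, rng))

    best = None
    for idx, init in enumerate(inits):
        try:
            states, a, pi, loglik, converged, n_iter = _run_em(
                sequences, spec, init, dt, tol, max_iter
            )
        except FloatingPointError:
            continue
        if best is None or loglik > best[3]:
            best = (states, a, pi, loglik, converged, n_iter, idx)
    if best is None:
        raise FitError("all EM restarts diverged")
    return best


def _build_fit(
    sequences: list[np.ndarray],
    spec: tuple[str, ...],
    dt: float,
    states: list[MotionState],
    a: np.ndarray,
    pi: np.ndarray,
    loglik: float,
    converged: bool,
    n_iter: int,
    restart_idx: int,
) -> HMMFit:
    model = MotionModel(states, a, pi)
    log_pi = np.log(np.clip(pi, 1e-300, None))
    log_a = np.log(np.clip(a, 1e-300, None))
    paths = [
        _viterbi_kernel(log_pi, log_a, _emission_log_matrix(seq, states, dt))
        for seq in sequences
    ]
    path = paths[0] if len(paths) == 1 else np.concatenate(paths)
    n = sum(len(s) for s in sequences)
    p = _n_free_params(spec)
    return HMMFit(
        model=model,
        log_likelihood=loglik,
        evidence=loglik - 0.5 * p * np.log(n),
        viterbi_path=path,
        converged=converged,
        n_restarts_used=restart_idx,
        n_iter=n_iter,
        unreliable=n < p,
    )


def _as_spec(model_spec) -> tuple[str, ...]:
    if isinstance(model_spec, str):
        model_spec = tuple(s.strip() for s in model_spec.split(","))
    spec = tuple(model_spec)
    if not 1 <= len(spec) <= 3:
        raise ValueError("model_spec must contain 1-3 states")
    return spec


def fit_hmm(
    traj: Trajectory,
    model_spec,
    n_restarts: int = 5,
    tol: float = 1e-6,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = 300,
) -> HMMFit:
    """Fit one candidate state combination to one trajectory by Baum-Welch EM.

    Initialization is k-means on the step vectors plus ``n_restarts`` seeded
    random perturbations of it; the restart with the best final
    log-likelihood wins (ties to the lowest restart index).  The forward-
    backward pass runs in log space throughout.
    """
    spec = _as_spec(model_spec)
    steps_um = traj.steps_um()
    if not np.all(np.isfinite(steps_um)):
        raise ValueError("trajectory contains non-finite positions")
    states, a, pi, loglik, converged, n_iter, idx = _fit_sequences(
        [steps_um], spec, traj.dt, n_restarts, tol, seed, max_iter
    )
    return _build_fit(
        [steps_um], spec, traj.dt, states, a, pi, loglik, converged, n_iter, idx
    )


def fit_hmm_pooled(
    trajectories: list[Trajectory],
    model_spec,
    n_restarts: int = 5,
    tol: float = 1e-6,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = 300,
) -> HMMFit:
    """Fit one shared motion model to a whole cohort of trajectories.

    All trajectories contribute to a single parameter set (one Baum-Welch
    with per-sequence forward-backward passes), which is how cohort-level
    state structure is identified when single trajectories are too short or
    too noisy to justify the full model on their own.  Trajectories should be
    in a common direction frame first (see :func:`rotate_to_axis`).
    """
    spec = _as_spec(model_spec)
    if not trajectories:
        raise ValueError("empty cohort")
    dt = trajectories[0].dt
    if any(abs(t.dt - dt) > 1e-12 for t in trajectories):
        raise ValueError("pooled fitting requires a common dt")
    sequences = [t.steps_um() for t in trajectories]
    states, a, pi, loglik, converged, n_iter, idx = _fit_sequences(
        sequences, spec, dt, n_restarts, tol, seed, max_iter
    )
    return _build_fit(
        sequences, spec, dt, states, a, pi, loglik, converged, n_iter, idx
    )


def refit_emissions(
    traj: Trajectory,
    pooled_fit: HMMFit,
    tol: float = 1e-6,
    max_iter: int = 200,
    update_transitions: bool = True,
    priors: EmissionPriors | str | None = "pooled",
) -> HMMFit:
    """Re-estimate per-trajectory state parameters under the pooled structure.

    EM starts from the pooled parameters; by default weak MAP priors centred
    on the pooled values keep each state in its cohort-level role (preventing,
    e.g., the zero-drift state from collapsing onto a slow directed run in a
    trajectory that has little genuine diffusion), while per-trajectory
    speeds remain essentially data-driven.
    """
    steps_um = traj.steps_um()
    spec = pooled_fit.model.spec
    init_states = [
        MotionState(s.kind, s.diffusion_coefficient, s.drift_velocity.copy())
        for s in pooled_fit.model.states
    ]
    a = pooled_fit.model.transition_matrix.copy()
    pi = pooled_fit.model.initial_distribution.copy()
    if priors == "pooled":
        priors = EmissionPriors.from_fit(pooled_fit)
    states, a, pi, loglik, converged, n_iter = _run_em(
        [steps_um], spec, (init_states, a, pi), traj.dt, tol, max_iter,
        update_transitions=update_transitions, priors=priors,
    )
    return _build_fit(
        [steps_um], spec, traj.dt, states, a, pi, loglik, converged, n_iter, 0
    )


def rotate_to_axis(traj: Trajectory) -> Trajectory:
    """Rotate a trajectory into its axon frame (+x = anterograde).

    Ground truth, when present, is rotated consistently.
    """
    if traj.axon_axis is None:
        raise ValueError("trajectory has no axon_axis")
    ax, ay = traj.axon_axis
    rot = np.array([[ax, ay], [-ay, ax]])
    truth = traj.truth
    if truth is not None:
        rot_states = []
        for s in truth.model.states:
            v = rot @ s.drift_velocity if s.kind == "DT" else np.zeros(2)
            rot_states.append(MotionState(s.kind, s.diffusion_coefficient, v))
        truth = TrajectoryTruth(
            states=truth.states.copy(),
            clean_positions=truth.clean_positions @ rot.T,
            model=MotionModel(
                rot_states,
                truth.model.transition_matrix.copy(),
                truth.model.initial_distribution.copy(),
            ),
        )
    return Trajectory(
        positions=traj.positions @ rot.T,
        dt=traj.dt,
        frame_index=traj.frame_index.copy(),
        snr=traj.snr,
        axon_axis=np.array([1.0, 0.0]),
        condition_label=traj.condition_label,
        traj_id=traj.traj_id,
        truth=truth,
    )


def coarsen(traj: Trajectory, block_frames: int) -> Trajectory:
    """Temporal coarse-graining: keep every ``block_frames``-th localization.

    Block displacements carry the same localization-noise variance as single
    steps while the motion signal grows with the block span, so coarse
    displacements have a much higher signal-to-noise ratio — the standard
    remedy when localization error rivals the per-frame motion.  Ground truth
    is dropped (it lives on the full-resolution trajectory).
    """
    if block_frames < 1:
        raise ValueError("block_frames must be >= 1")
    if block_frames == 1:
        return traj
    n_blocks = (len(traj.positions) - 1) // block_frames
    if n_blocks < 2:
        raise ValueError("trajectory too short to coarsen")
    return Trajectory(
        positions=traj.positions[::block_frames][: n_blocks + 1],
        dt=traj.dt * block_frames,
        snr=traj.snr,
        axon_axis=None if traj.axon_axis is None else traj.axon_axis.copy(),
        condition_label=traj.condition_label,
        traj_id=traj.traj_id,
    )


def evidence_score(fit: HMMFit, n_displacements: int) -> float:
    """BIC-type penalized evidence: logL - (p/2) log n.

    p counts 1 parameter per D state (its diffusion coefficient), 3 per DT
    state (D plus a 2-D drift), K(K-1) transition and K-1 initial-distribution
    parameters.
    """
    p = _n_free_params(fit.model.spec)
    score = fit.log_likelihood - 0.5 * p * np.log(n_displacements)
    if n_displacements < p:
        fit.unreliable = True
    return float(score)


def _selection_from_fits(
    fits: dict,
    candidate_specs,
) -> ModelSelection:
    if not fits:
        raise FitError("no candidate model could be fitted")
    scores = {spec: f.evidence for spec, f in fits.items()}
    m = max(scores.values())
    w = {spec: np.exp(s - m) for spec, s in scores.items()}
    z = sum(w.values())
    probs = {spec: v / z for spec, v in w.items()}
    best_spec = None
    for spec in candidate_specs:  # simplest-first order; strict > keeps it on ties
        if spec in scores and (best_spec is None or scores[spec] > scores[best_spec]):
            best_spec = spec
    return ModelSelection(fits=fits, probabilities=probs, best_spec=best_spec)


def select_model(
    traj: Trajectory,
    candidate_specs=CANDIDATE_SPECS,
    seed: int | np.random.SeedSequence = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
) -> ModelSelection:
    """Fit every candidate state combination and select the best evidence.

    Probabilities are the normalized exponentiated evidence scores.  Exact
    ties break toward fewer states, then fewer directed states.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(candidate_specs))
    fits = {}
    for spec, child in zip(candidate_specs, children):
        try:
            fits[spec] = fit_hmm(traj, spec, n_restarts=n_restarts, tol=tol, seed=child)
        except FitError:
            continue
    return _selection_from_fits(fits, candidate_specs)


def select_model_pooled(
    trajectories: list[Trajectory],
    candidate_specs=CANDIDATE_SPECS,
    seed: int | np.random.SeedSequence = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
) -> ModelSelection:
    """Cohort-level model selection with shared parameters per candidate.

    Each candidate is fitted once to all trajectories jointly; its evidence
    pays the complexity penalty once against the pooled displacement count,
    the natural cohort-level reading of "which motion model explains these
    trajectories".  Trajectories should be in a common direction frame.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(candidate_specs))
    fits = {}
    for spec, child in zip(candidate_specs, children):
        try:
            fits[spec] = fit_hmm_pooled(
                trajectories, spec, n_restarts=n_restarts, tol=tol, seed=child
            )
        except FitError:
            continue
    return _selection_from_fits(fits, candidate_specs)


# ---------------------------------------------------------------------------
# annotation and aggregation
# ---------------------------------------------------------------------------


def viterbi_annotate(fit: HMMFit, traj: Trajectory) -> pd.DataFrame:
    """Segment table of the most probable hidden path.

    One row per contiguous constant-state run, with start/end frame, state
    index, and the mean observed step vector (um) within the segment.
    """
    path = fit.viterbi_path
    steps = traj.steps_um()
    bounds = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(path)]])
    rows = []
    for s, e in zip(starts, ends):
        seg = steps[s:e]
        rows.append(
            {
                "start_frame": int(traj.frame_index[s]),
                "end_frame": int(traj.frame_index[e]),
                "state": int(path[s]),
                "n_steps": int(e - s),
                "mean_dx_um": float(seg[:, 0].mean()),
                "mean_dy_um": float(seg[:, 1].mean()),
                "mean_step_speed": float(
                    np.linalg.norm(seg, axis=1).mean() / traj.dt
                ),
            }
        )
    return pd.DataFrame(rows)


def label_directions(fit: HMMFit, traj: Trajectory) -> dict[int, str]:
    """Map fitted states to {diffusive, anterograde, retrograde}.

    DT states are anterograde when their drift projects positively on the
    axon axis (which points from cell body to terminal), retrograde
    otherwise.  If both DT states project with the same sign, the larger
    projection keeps the label and the other is flagged ``ambiguous``.
    """
    if traj.axon_axis is None:
        raise ValueError("trajectory has no axon_axis; cannot label directions")
    labels: dict[int, str] = {}
    projections: dict[int, float] = {}
    for i, st in enumerate(fit.model.states):
        if st.kind == "D":
            labels[i] = "diffusive"
        else:
            projections[i] = float(st.drift_velocity @ traj.axon_axis)
    pos = {i: p for i, p in projections.items() if p > 0}
    neg = {i: p for i, p in projections.items() if p <= 0}
    for group, label in ((pos, "anterograde"), (neg, "retrograde")):
        if not group:
            continue
        ranked = sorted(group, key=lambda i: abs(group[i]), reverse=True)
        labels[ranked[0]] = label
        for i in ranked[1:]:
            labels[i] = "ambiguous"
    return labels


def filter_trajectories(
    trajectories: list[Trajectory],
    min_len: int = 150,
    min_snr: float = 2.0,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Quality filter: minimum consecutive length and mean signal-to-noise.

    Returns the retained trajectories and a rejection log with reason codes.
    """
    kept, log_rows = [], []
    for traj in trajectories:
        if len(traj) < min_len:
            log_rows.append({"traj_id": traj.traj_id, "reason": "length"})
        elif not traj.snr > min_snr:
            log_rows.append({"traj_id": traj.traj_id, "reason": "snr"})
        else:
            kept.append(traj)
    return kept, pd.DataFrame(log_rows, columns=["traj_id", "reason"])


def state_mean_speed(kind: str, drift_speed: float, d: float, dt: float) -> float:
    """Mean step speed E|step|/dt of the noise-free displacement process.

    The displacement is N(v*dt, 2*D*dt*I) in 2-D, so |step| is Rice
    distributed and E|step| = sigma*sqrt(pi/2)*1F1(-1/2; 1; -mu^2/(2 sigma^2))
    with mu = |v|*dt and sigma^2 = 2*D*dt.  For a D state mu = 0 and this
    reduces to sqrt(pi*D/dt).
    """
    sigma = np.sqrt(2.0 * max(d, D_FLOOR) * dt)
    mu = 0.0 if kind == "D" else drift_speed * dt
    e_abs = sigma * np.sqrt(np.pi / 2.0) * hyp1f1(-0.5, 1.0, -(mu**2) / (2 * sigma**2))
    return float(e_abs / dt)


@dataclass
class CohortAnalysis:
    """Per-trajectory fits and annotations for one condition cohort.

    ``trajectories`` are the full-resolution trajectories rotated into their
    axon frames (+x anterograde); ``block_trajectories`` are their
    coarse-grained versions used for state estimation; ``fits`` are
    per-trajectory MAP-EM emission refits (block level) under the pooled
    cohort structure.
    """

    trajectories: list[Trajectory]
    block_trajectories: list[Trajectory]
    block_frames: int
    fits: list[HMMFit]
    labels: list[dict[int, str]]  # state index -> direction label
    spec: tuple[str, ...]
    pooled_selection: ModelSelection | None = None
    pooled_fit: HMMFit | None = None
    selections: list[ModelSelection] | None = None  # per-trajectory, optional
    condition: str = "control"

    @property
    def frame_dt(self) -> float:
        return self.trajectories[0].dt

    @property
    def selected_specs(self) -> list[tuple[str, ...]]:
        if self.selections is None:
            raise ValueError("cohort was analyzed without per-trajectory selection")
        return [sel.best_spec for sel in self.selections]


def analyze_cohort(
    trajectories: list[Trajectory],
    seed: int | np.random.SeedSequence = 0,
    spec=None,
    block_frames: int = 3,
    per_trajectory_selection: bool = False,
    n_restarts: int = 5,
    tol: float = 1e-6,
    condition: str | None = None,
) -> CohortAnalysis:
    """Full cohort pipeline: rotate, select, coarse-grain, fit, annotate.

    Trajectories are rotated into their axon frames so the cohort shares a
    direction convention.  When ``spec`` is None the motion model is chosen
    by pooled (shared-parameter) selection over the whole cohort at full
    frame resolution, where all temporal information is available.  State
    parameters are then estimated on ``block_frames``-frame coarse
    displacements (noise-robust; see :func:`coarsen`): one pooled anchor fit
    plus per-trajectory MAP-EM refits, with states labeled by drift
    direction.  Per-trajectory model selection can additionally be run for
    reporting.
    """
    if not trajectories:
        raise ValueError("empty cohort")
    rotated = [rotate_to_axis(t) for t in trajectories]
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sel_seed, anchor_seed, per_traj_seed = ss.spawn(3)

    pooled_selection = None
    if spec is None:
        pooled_selection = select_model_pooled(
            rotated, seed=sel_seed, n_restarts=n_restarts, tol=tol
        )
        spec = pooled_selection.best_spec
    else:
        spec = _as_spec(spec)

    blocks = [coarsen(t, block_frames) for t in rotated]
    pooled_fit = fit_hmm_pooled(
        blocks, spec, seed=anchor_seed, n_restarts=n_restarts, tol=tol
    )

    selections = None
    if per_trajectory_selection:
        sel_seeds = per_traj_seed.spawn(len(blocks))
        selections = [
            select_model(t, seed=s, n_restarts=n_restarts, tol=tol)
            for t, s in zip(blocks, sel_seeds)
        ]

    fits, labels = [], []
    for tb in blocks:
        fit = refit_emissions(tb, pooled_fit, tol=tol)
        fits.append(fit)
        labels.append(label_directions(fit, tb))
    return CohortAnalysis(
        trajectories=rotated,
        block_trajectories=blocks,
        block_frames=block_frames,
        fits=fits,
        labels=labels,
        spec=spec,
        pooled_selection=pooled_selection,
        pooled_fit=pooled_fit,
        selections=selections,
        condition=condition or trajectories[0].condition_label,
    )


def _segment_spans(path: np.ndarray, state: int, min_len: int, trim: int):
    """(start, end) block spans of interior runs of ``state`` in a Viterbi path."""
    bounds = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(path)]])
    return [
        (s + trim, e - trim)
        for s, e in zip(starts, ends)
        if path[s] == state and e - s >= min_len
    ]


def _diffusive_d_estimate(
    path: np.ndarray,
    state: int,
    block_steps: np.ndarray,
    frame_steps: np.ndarray,
    block_frames: int,
    dt_frame: float,
    localization_sigma_um: float | None,
) -> float | None:
    """Per-trajectory diffusion coefficient of the diffusive state.

    With a known localization sigma the estimator is the within-segment
    variance of deep-interior blocks of long Viterbi segments (>= 6 blocks,
    2 trimmed per side), with two exact corrections: per-segment mean removal
    (so a misassigned directed run contributes scatter but no drift) plus the
    MA(1) small-sample term it induces (mean removal of anti-correlated steps
    under-subtracts by 2*sigma^2/n per axis), and finally the localization
    variance itself.  Deep interiors are used because block values there are
    assigned by temporal context rather than their own size, which suppresses
    the conditioning bias of decoded-segment statistics.  Without a known
    sigma, the variance-plus-twice-lag-1-autocovariance (noise-cancelling)
    estimator on frame steps is used instead; it carries a modest upward
    contamination bias.
    """
    dt_block = dt_frame * block_frames
    if localization_sigma_um is not None:
        spans = _segment_spans(path, state, min_len=6, trim=2)
        ss, df, wsum = 0.0, 0, 0.0
        for s, e in spans:
            blocks = block_steps[s:e]
            n = len(blocks)
            if n < 2:
                continue
            ss += float(((blocks - blocks.mean(axis=0)) ** 2).sum())
            df += n - 1
            wsum += (n - 1) / n
        if df < 3:
            return None
        sig2 = localization_sigma_um**2
        var_axis = ss / (2.0 * df) - 2.0 * sig2 * wsum / df
        return max((var_axis - 2.0 * sig2) / (2.0 * dt_block), D_FLOOR)

    spans = _segment_spans(path, state, min_len=3, trim=1)
    var_axis, cov_axis = [], []
    for s, e in spans:
        seg = frame_steps[s * block_frames : e * block_frames]
        if len(seg) < 6:
            continue
        m = seg.mean(axis=0)
        var_axis.append(((seg - m) ** 2).sum(axis=1))
        cov_axis.append(((seg[:-1] - m) * (seg[1:] - m)).sum(axis=1))
    if not var_axis:
        return None
    var_f = np.concatenate(var_axis).mean() / 2.0
    cov_f = np.concatenate(cov_axis).mean() / 2.0
    return max((var_f + 2.0 * cov_f) / (2.0 * dt_frame), D_FLOOR)


def _per_trajectory_stats(
    analysis: CohortAnalysis, localization_sigma_nm: float | None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Speed and occupancy per (trajectory, label) plus per-trajectory labeled
    transition counts (block resolution).

    Directed speeds come from the mean displacement of Viterbi segment
    interiors (boundary blocks are the value-selected ones; localization
    noise cancels in the mean).  The diffusive state, which has no drift
    parameter, reports the mean step speed sqrt(pi*D/dt_frame) of its
    de-noised displacement process, with D estimated per trajectory by
    moment estimators that remove the localization variance (see
    :func:`_diffusive_d_estimate`).
    """
    sigma_um = (
        None if localization_sigma_nm is None else localization_sigma_nm / NM_PER_UM
    )
    dt_frame = analysis.frame_dt
    rows = []
    counts = np.zeros((len(analysis.trajectories), 3, 3))
    for ti, (traj, tb, fit, labmap) in enumerate(
        zip(
            analysis.trajectories,
            analysis.block_trajectories,
            analysis.fits,
            analysis.labels,
        )
    ):
        path = fit.viterbi_path
        block_steps = tb.steps_um()
        frame_steps = traj.steps_um()
        occ = np.bincount(path, minlength=len(fit.model.states))
        for i, st in enumerate(fit.model.states):
            label = labmap[i]
            if label not in LABELS or occ[i] == 0:
                continue
            if st.kind == "DT":
                spans = _segment_spans(path, i, min_len=3, trim=1)
                if not spans:
                    continue
                interior = np.concatenate([block_steps[s:e] for s, e in spans])
                speed = float(np.linalg.norm(interior.mean(axis=0)) / tb.dt)
            else:
                d = _diffusive_d_estimate(
                    path, i, block_steps, frame_steps,
                    analysis.block_frames, dt_frame, sigma_um,
                )
                if d is None:
                    continue
                speed = state_mean_speed("D", 0.0, d, dt_frame)
            rows.append(
                {"traj": ti, "label": label, "speed": speed, "n_steps": int(occ[i])}
            )
        label_idx = {
            i: LABELS.index(lab) for i, lab in labmap.items() if lab in LABELS
        }
        for a, b in zip(path[:-1], path[1:]):
            if a in label_idx and b in label_idx:
                counts[ti, label_idx[a], label_idx[b]] += 1
    return pd.DataFrame(rows, columns=["traj", "label", "speed", "n_steps"]), counts


def _summarize(
    per_state: pd.DataFrame, counts: np.ndarray, n_traj: int
) -> CohortSummary:
    total_steps = per_state["n_steps"].sum()
    summaries: dict[str, StateSummary] = {}
    for label in LABELS:
        sub = per_state[per_state["label"] == label]
        if sub.empty:
            continue
        w = sub["n_steps"].to_numpy(float)
        # unweighted across trajectories: each trajectory is one biological
        # replicate of the cohort speed distribution
        mean = float(sub["speed"].mean())
        sd = float(sub["speed"].std(ddof=0))
        summaries[label] = StateSummary(
            state_label=label,
            mean_speed=mean,
            speed_sd=sd,
            occupancy_fraction=float(w.sum() / total_steps),
            n_trajectories=int(sub["traj"].nunique()),
        )
    pooled = counts.sum(axis=0)
    row_sums = pooled.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        mat = np.where(row_sums > 0, pooled / np.clip(row_sums, 1, None), np.nan)
    tm = pd.DataFrame(mat, index=list(LABELS), columns=list(LABELS))
    return CohortSummary(
        state_summaries=summaries, transition_matrix=tm, n_trajectories=n_traj
    )


def aggregate_statistics(
    analysis: CohortAnalysis,
    localization_sigma_nm: float | None = None,
) -> CohortSummary:
    """Cohort-level per-state speeds, occupancies and pooled transitions.

    Mean speeds are occupancy-weighted averages of per-trajectory model-based
    state speeds (see ``_per_trajectory_stats``); the transition matrix is
    the row-normalized sum of Viterbi transition counts over trajectories.
    """
    per_state, counts = _per_trajectory_stats(analysis, localization_sigma_nm)
    if per_state.empty:
        raise ValueError("no labeled states to aggregate")
    return _summarize(per_state, counts, len(analysis.trajectories))


def compare_conditions(
    analysis_a: CohortAnalysis,
    analysis_b: CohortAnalysis,
    localization_sigma_nm: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-state speed deltas and transition-probability deltas (a - b).

    Percentile bootstrap intervals resample trajectories within each cohort.
    Raises if the two cohorts resolved different label sets.
    """
    stats_a, counts_a = _per_trajectory_stats(analysis_a, localization_sigma_nm)
    stats_b, counts_b = _per_trajectory_stats(analysis_b, localization_sigma_nm)
    labels_a = set(stats_a["label"].unique())
    labels_b = set(stats_b["label"].unique())
    if labels_a != labels_b:
        raise ValueError(
            f"label sets differ between cohorts: {sorted(labels_a ^ labels_b)}"
        )

    def point_estimates(stats, counts, idx):
        sub = pd.concat(
            [stats[stats["traj"] == i] for i in idx], ignore_index=True
        )
        out = {}
        for label in sorted(labels_a):
            s = sub[sub["label"] == label]
            if len(s):
                out[f"speed:{label}"] = float(s["speed"].mean())
        pooled = counts[idx].sum(axis=0)
        rs = pooled.sum(axis=1, keepdims=True)
        mat = np.where(rs > 0, pooled / np.clip(rs, 1, None), np.nan)
        for i, la in enumerate(LABELS):
            for j, lb in enumerate(LABELS):
                out[f"trans:{la}->{lb}"] = mat[i, j]
        return out

    all_a = np.arange(len(analysis_a.trajectories))
    all_b = np.arange(len(analysis_b.trajectories))
    point_a = point_estimates(stats_a, counts_a, all_a)
    point_b = point_estimates(stats_b, counts_b, all_b)
    keys = [k for k in point_a if k in point_b]

    rng = np.random.default_rng(seed)
    boot = {k: [] for k in keys}
    for _ in range(n_boot):
        ia = rng.choice(all_a, size=len(all_a), replace=True)
        ib = rng.choice(all_b, size=len(all_b), replace=True)
        ea = point_estimates(stats_a, counts_a, ia)
        eb = point_estimates(stats_b, counts_b, ib)
        for k in keys:
            if k in ea and k in eb:
                boot[k].append(ea[k] - eb[k])
    alpha = (1.0 - ci) / 2.0
    rows = []
    for k in keys:
        delta = point_a[k] - point_b[k]
        draws = np.asarray(boot[k], float)
        draws = draws[np.isfinite(draws)]
        lo, hi = (
            (np.quantile(draws, alpha), np.quantile(draws, 1 - alpha))
            if len(draws)
            else (np.nan, np.nan)
        )
        rows.append({"quantity": k, "delta": delta, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
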
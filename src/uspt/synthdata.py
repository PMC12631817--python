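"""Seeded scenario generators for synthetic axonal-transport cohorts.

A :class:`ScenarioPreset` freezes everything a simulated tracking experiment
needs: the hidden three-state motion model (one diffusive state, one
anterograde and one retrograde drift-diffusion state), cohort size, frame
count, frame interval, localization precision, and the per-trajectory
heterogeneity of state speeds.  The control preset's target state speeds are
the cohort values reported for axonal cargo transport in sensory neurons
(diffusive 0.24 +/- 0.14, anterograde 0.54 +/- 0.27, retrograde
0.56 +/- 0.28 um/s); the drug presets re-scale them the way dynein
inhibition (directed transport collapses below diffusion) and stimulation
(all states speed up, anterograde/retrograde exchange increases) shift the
real distributions.  Transition probabilities are chosen to reproduce rank
order only — strong self-persistence with diffusion->retrograde the rarest
move — since no numeric matrix is published.

Every generator is a pure function of (preset, seed): the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .transport import (
    LABELS,
    MotionModel,
    MotionState,
    Trajectory,
    simulate_trajectory,
)

__all__ = [
    "ScenarioPreset",
    "CONTROL_TRANSITION_MATRIX",
    "make_control_preset",
    "make_condition_presets",
    "generate_cohort",
]

#: Row-stochastic switching matrix of the control condition, state order
#: (diffusive, anterograde, retrograde).  Strongly diagonal; the
#: diffusive->retrograde entry is deliberately the smallest off-diagonal,
#: encoding retrograde activation via prior anterograde transport.
CONTROL_TRANSITION_MATRIX = np.array(
    [
        [0.970, 0.024, 0.006],
        [0.021, 0.946, 0.033],
        [0.021, 0.021, 0.958],
    ]
)

#: Within-state diffusion coefficient of the directed states (um^2/s); active
#: runs wander much less than the passive diffusive state.
TRANSPORT_D = 0.002


@dataclass(frozen=True)
class ScenarioPreset:
    """Complete parameterization of one synthetic tracking condition."""

    name: str
    state_labels: tuple[str, ...] = LABELS
    state_kinds: tuple[str, ...] = ("D", "DT", "DT")
    #: cohort-mean target state speeds, um/s: the drift magnitude |v| for
    #: directed states, the mean step speed sqrt(pi*D/dt) for the diffusive one
    speed_means: tuple[float, ...] = (0.24, 0.54, 0.56)
    #: across-trajectory SD of the state speeds, um/s
    speed_sds: tuple[float, ...] = (0.14, 0.27, 0.28)
    #: drift direction sign along the axon axis per state (0 for diffusive)
    direction_signs: tuple[int, ...] = (0, +1, -1)
    transition_matrix: np.ndarray = field(
        default_factory=lambda: CONTROL_TRANSITION_MATRIX.copy()
    )
    transport_diffusion: float = TRANSPORT_D
    n_trajectories: int = 60
    n_frames: int = 600
    dt: float = 0.05  # s (20 frames per second)
    localization_sigma: float = 30.0  # nm
    snr_distribution: tuple[float, float] = (4.0, 1.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.transition_matrix, float)
        if np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.n_frames < 150:
            raise ValueError("analysis-grade presets need n_frames >= 150")

    @property
    def stationary_distribution(self) -> np.ndarray:
        a = np.asarray(self.transition_matrix, float)
        vals, vecs = np.linalg.eig(a.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        v = np.abs(v)
        return v / v.sum()


def _truncnorm_location(target_mean: float, sd: float) -> float:
    """Location mu0 such that a normal(mu0, sd) truncated at 0 has the target mean."""
    if sd == 0:
        return target_mean

    def trunc_mean(mu: float) -> float:
        a = (0.0 - mu) / sd
        return truncnorm.mean(a, np.inf, loc=mu, scale=sd)

    lo = target_mean - 4 * sd
    return float(brentq(lambda m: trunc_mean(m) - target_mean, lo, target_mean + sd))


def make_control_preset(seed: int = 0) -> ScenarioPreset:
    """The untreated-neuron scenario (the defaults of ScenarioPreset)."""
    del seed  # the preset itself is deterministic; seeds enter at generation
    return ScenarioPreset(name="control")


def make_condition_presets(seed: int = 0) -> dict[str, ScenarioPreset]:
    """Inhibitor and stimulant scenarios derived from the control preset.

    * inhibitor (dynein block): directed speeds drop below the diffusive
      speed, self-persistence weakens, anterograde<->retrograde exchange
      grows.
    * stimulant: every state speeds up ~1.4x and anterograde<->retrograde
      exchange grows, with persistence mildly reduced.
    """
    control = make_control_preset(seed)
    inhibitor_a = np.array(
        [
            [0.900, 0.060, 0.040],
            [0.080, 0.820, 0.100],
            [0.080, 0.100, 0.820],
        ]
    )
    stimulant_a = np.array(
        [
            [0.920, 0.055, 0.025],
            [0.050, 0.870, 0.080],
            [0.050, 0.080, 0.870],
        ]
    )
    d_speed = control.speed_means[0]
    inhibitor = replace(
        control,
        name="inhibitor",
        speed_means=(d_speed, 0.5 * d_speed, 0.5 * d_speed),
        speed_sds=(control.speed_sds[0], 0.08, 0.08),
        transition_matrix=inhibitor_a,
    )
    stimulant = replace(
        control,
        name="stimulant",
        speed_means=tuple(1.4 * s for s in control.speed_means),
        speed_sds=tuple(1.2 * s for s in control.speed_sds),
        transition_matrix=stimulant_a,
    )
    return {"inhibitor": inhibitor, "stimulant": stimulant}


def _draw_cohort_speeds(preset: ScenarioPreset, rng: np.random.Generator) -> np.ndarray:
    """Per-trajectory state speeds for the whole cohort, shape (n_traj, n_states).

    Speeds are truncated-normal with the target SD, re-centred so the
    population mean equals the target mean, and drawn by Latin-hypercube
    (stratified inverse-CDF) sampling per state: each trajectory's speed is
    still marginally truncated-normal, but the realized cohort mean sits
    tightly on the target instead of fluctuating by SD/sqrt(n)."""
    n = preset.n_trajectories
    out = np.empty((n, len(preset.speed_means)))
    for i, (mean, sd) in enumerate(zip(preset.speed_means, preset.speed_sds)):
        if sd == 0:
            out[:, i] = mean
            continue
        mu0 = _truncnorm_location(mean, sd)
        a = (0.0 - mu0) / sd
        u = (np.arange(n) + rng.uniform(0, 1, size=n)) / n
        rng.shuffle(u)
        out[:, i] = truncnorm.ppf(u, a, np.inf, loc=mu0, scale=sd)
    return out


def _model_for_trajectory(
    preset: ScenarioPreset, speeds: np.ndarray, axis: np.ndarray
) -> MotionModel:
    states = []
    for kind, speed, sign in zip(preset.state_kinds, speeds, preset.direction_signs):
        if kind == "D":
            # a D state's mean step speed sqrt(pi*D/dt) fixes its D
            d = speed**2 * preset.dt / np.pi
            states.append(MotionState("D", max(d, 1e-9)))
        else:
            states.append(
                MotionState("DT", preset.transport_diffusion, sign * speed * axis)
            )
    return MotionModel(
        states=states,
        transition_matrix=preset.transition_matrix.copy(),
        initial_distribution=preset.stationary_distribution,
    )


def generate_cohort(
    preset: ScenarioPreset, seed: int = 0
) -> tuple[list[Trajectory], "pd.DataFrame"]:
    """Simulate a full cohort plus its machine-readable ground truth.

    Per-trajectory seeds are spawned from the master seed in counter order, so
    cohorts are bit-reproducible and individual trajectories can be resampled
    independently.  The returned truth table records the generating state
    parameters of every trajectory; hidden paths stay attached to each
    Trajectory (``traj.truth``).
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    cohort_speeds = _draw_cohort_speeds(preset, cohort_rng)
    children = ss.spawn(preset.n_trajectories)
    trajectories, truth_rows = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        theta = rng.uniform(0, 2 * np.pi)
        axis = np.array([np.cos(theta), np.sin(theta)])
        speeds = cohort_speeds[i]
        # truncate the SNR draw just above the quality-filter threshold so
        # analysis-grade cohorts are retained in full
        snr = max(float(rng.normal(*preset.snr_distribution)), 2.1)
        model = _model_for_trajectory(preset, speeds, axis)
        traj = simulate_trajectory(
            model,
            n_frames=preset.n_frames,
            dt=preset.dt,
            localization_sigma=preset.localization_sigma,
            seed=np.random.default_rng(child.spawn(1)[0]),
            snr=snr,
            axon_axis=axis,
            condition_label=preset.name,
            traj_id=i,
        )
        trajectories.append(traj)
        for k, (label, st) in enumerate(zip(preset.state_labels, model.states)):
            truth_rows.append(
                {
                    "traj_id": i,
                    "state": k,
                    "label": label,
                    "kind": st.kind,
                    "target_speed": speeds[k],
                    "diffusion_um2_s": st.diffusion_coefficient,
                    "vx_um_s": st.drift_velocity[0],
                    "vy_um_s": st.drift_velocity[1],
                    "axis_x": axis[0],
                    "axis_y": axis[1],
                    "snr": snr,
                }
            )
    return trajectories, pd.DataFrame(truth_rows)
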
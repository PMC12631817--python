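"""Mean-field rate-equation model of Yb3+/Er3+ upconversion in layered nanoparticles.

The model tracks excitation flow in a core-shell-shell particle in which Er3+
emitters sit in the core (with a tunable Yb3+ co-doping fraction), the interior
shell is a pure-sensitizer NaYbF4 layer, and an optically inert outer shell
screens the active volume from surface quenchers.  Five coupled processes are
resolved:

* **Energy migration (EM) / interfacial energy transfer (IET)** — excitation
  hopping through the Yb3+ network, modeled as a mean-field exchange between
  two Yb compartments (core and interior shell).  The exchange rate has an
  x_Yb-proportional migration part (the Yb network inside the core) plus a
  constant interfacial part, so a sensitizer-free core is still fed across
  the core/shell boundary.
* **ETU-1/2/3** — sequential energy-transfer upconversion steps
  Yb1 + Er_i -> Yb0 + Er_j climbing the Er ladder
  (Er0->Er2, Er2->Er4, Er1->Er3).
* **Back energy transfer (BET)** — Er4 + Yb0 -> Er1 + Yb1, depleting the green
  level in favour of the red-feeding Er1 reservoir.
* **Cross-relaxation (CR)** — Er4 + Er0 -> 2 Er1 between emitter pairs.
* **Surface quenching** — an extra nonradiative loss on the shell Yb excited
  state and on the emitting Er levels that decays exponentially with the inert
  shell thickness.

Er3+ is reduced to five effective levels: 0 = 4I15/2 (ground), 1 = 4I13/2,
2 = 4I11/2, 3 = 4F9/2 (red, ~654 nm), 4 = merged 2H11/2 / 4S3/2 (green,
~521/541 nm); the short-lived 4F7/2 reached by ETU-2 is collapsed into level 4.

All ion densities are in nm^-3, lengths in nm, times in s and excitation power
densities in kW cm^-2.  Bimolecular rate coefficients therefore carry nm^3 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ParticleArchitecture",
    "RateParams",
    "Excitation",
    "PopulationState",
    "EmissionSummary",
    "DEFAULT_ARCHITECTURE",
    "DEFAULT_RATE_PARAMS",
    "ConvergenceError",
    "derivatives",
    "steady_state",
    "emission_summary",
    "power_sweep",
    "doping_sweep",
    "shell_sweep",
    "decay_simulation",
    "yb_content_ratio",
]

#: photon energy at 980 nm in J (h*c/lambda)
_PHOTON_ENERGY_980_J = 6.62607015e-34 * 2.99792458e8 / 980e-9


class ConvergenceError(RuntimeError):
    """Raised when the steady-state solver fails to reach the residual tolerance."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticleArchitecture:
    """Concentric-sphere geometry and per-layer dopant fractions.

    The particle is core @ interior shell @ inert shell.  ``core_yb_fraction``
    and ``core_er_fraction`` are cation mole fractions in the core;
    ``interior_shell_yb_fraction`` is 1.0 for a NaYbF4 interior shell.
    """

    core_diameter: float = 11.0  # nm
    interior_shell_thickness: float = 1.5  # nm
    inert_shell_thickness: float = 1.5  # nm
    core_yb_fraction: float = 0.9
    core_er_fraction: float = 0.1
    interior_shell_yb_fraction: float = 1.0
    cation_density: float = 13.9  # lanthanide-site ions per nm^3 in beta-NaREF4

    def __post_init__(self) -> None:
        if self.core_yb_fraction + self.core_er_fraction > 1.0 + 1e-12:
            raise ValueError("core Yb + Er fraction exceeds 1")
        for name in ("core_diameter", "interior_shell_thickness", "inert_shell_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("core_yb_fraction", "core_er_fraction", "interior_shell_yb_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cation_density <= 0:
            raise ValueError("cation_density must be positive")

    @property
    def core_volume(self) -> float:
        """Core volume in nm^3."""
        return 4.0 / 3.0 * np.pi * (self.core_diameter / 2.0) ** 3

    @property
    def interior_shell_volume(self) -> float:
        """Interior (sensitizer) shell volume in nm^3."""
        r0 = self.core_diameter / 2.0
        r1 = r0 + self.interior_shell_thickness
        return 4.0 / 3.0 * np.pi * (r1**3 - r0**3)

    @property
    def total_diameter(self) -> float:
        return self.core_diameter + 2.0 * (
            self.interior_shell_thickness + self.inert_shell_thickness
        )

    def yb_ions(self) -> float:
        """Total number of Yb3+ ions in the active (core + interior shell) volume."""
        return self.cation_density * (
            self.core_yb_fraction * self.core_volume
            + self.interior_shell_yb_fraction * self.interior_shell_volume
        )


@dataclass(frozen=True)
class RateParams:
    """Kinetic constants of the five-process model.

    No measured rate-constant set ships with this model: the defaults below
    are order-of-magnitude values typical of beta-NaREF4 Yb/Er upconverters,
    chosen once as a named preset.  They are *not* fitted to any measured
    curve; only qualitative trends should be read off them.
    """

    sigma_yb: float = 1.2e-20  # Yb3+ absorption cross-section at 980 nm, cm^2
    tau_yb: float = 1.0e-3  # Yb 2F5/2 lifetime, s
    c_etu1: float = 30.0  # Yb1+Er0 -> Yb0+Er2, nm^3 s^-1
    c_etu2: float = 70.0  # Yb1+Er2 -> Yb0+Er4, nm^3 s^-1
    c_etu3: float = 30.0  # Yb1+Er1 -> Yb0+Er3, nm^3 s^-1
    c_bet: float = 5.0  # Er4+Yb0 -> Er1+Yb1, nm^3 s^-1
    c_cr: float = 80.0  # Er4+Er0 -> 2 Er1, nm^3 s^-1
    tau_er: tuple[float, float, float, float] = (2.0e-3, 2.0e-3, 5.0e-4, 4.0e-4)
    # tau_1..tau_4: 4I13/2, 4I11/2, 4F9/2, 2H11/2+4S3/2 lifetimes, s
    branch_43: float = 0.3  # nonradiative branching level4 -> level3
    branch_21: float = 0.15  # branching level2 -> level1
    k_mig0: float = 2.0e4  # core<->shell migration exchange at x_Yb=1, s^-1
    k_iet: float = 1.5e3  # x-independent interfacial exchange across the boundary, s^-1
    k_surf0: float = 1.0e4  # surface quenching at zero inert shell, s^-1
    lambda_s: float = 1.0  # quenching decay length, nm

    def __post_init__(self) -> None:
        for name in (
            "sigma_yb", "tau_yb", "c_etu1", "c_etu2", "c_etu3", "c_bet",
            "c_cr", "k_mig0", "k_iet", "k_surf0", "lambda_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(t <= 0 for t in self.tau_er):
            raise ValueError("Er lifetimes must be positive")
        if not (0.0 <= self.branch_43 <= 1.0 and 0.0 <= self.branch_21 <= 1.0):
            raise ValueError("branching fractions must lie in [0, 1]")


@dataclass(frozen=True)
class Excitation:
    """Continuous-wave (or square-pulse) 980 nm excitation."""

    power_density: float = 11.6  # kW cm^-2
    wavelength: float = 980.0  # nm, fixed
    pulsed: bool = False

    def __post_init__(self) -> None:
        if self.power_density < 0:
            raise ValueError("power_density must be non-negative")

    @property
    def pump_rate(self) -> float:
        """Per-ion ground-state pumping rate sigma*phi in s^-1 (for default sigma)."""
        return self.photon_flux * 1.2e-20

    @property
    def photon_flux(self) -> float:
        """Photon flux in photons cm^-2 s^-1."""
        return self.power_density * 1e3 / _PHOTON_ENERGY_980_J


@dataclass
class PopulationState:
    """Per-compartment Yb and Er level densities (nm^-3).

    Er level indices: 0 = 4I15/2, 1 = 4I13/2, 2 = 4I11/2, 3 = 4F9/2 (red),
    4 = 2H11/2 / 4S3/2 (green).
    """

    n_yb0_core: float
    n_yb1_core: float
    n_yb0_shell: float
    n_yb1_shell: float
    n_er: np.ndarray  # shape (5,)

    @classmethod
    def ground(cls, arch: ParticleArchitecture) -> "PopulationState":
        n_er = np.zeros(5)
        n_er[0] = arch.core_er_fraction * arch.cation_density
        return cls(
            n_yb0_core=arch.core_yb_fraction * arch.cation_density,
            n_yb1_core=0.0,
            n_yb0_shell=arch.interior_shell_yb_fraction * arch.cation_density,
            n_yb1_shell=0.0,
            n_er=n_er,
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.n_yb0_core, self.n_yb1_core, self.n_yb0_shell, self.n_yb1_shell],
             self.n_er]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "PopulationState":
        return cls(
            n_yb0_core=float(y[0]), n_yb1_core=float(y[1]),
            n_yb0_shell=float(y[2]), n_yb1_shell=float(y[3]),
            n_er=np.asarray(y[4:9], dtype=float).copy(),
        )

    def validate(self) -> None:
        v = self.to_vector()
        if np.any(v < 0):
            raise ValueError("negative population density")


@dataclass(frozen=True)
class EmissionSummary:
    """Steady-state emission bookkeeping for one particle (photons s^-1, arb. scale)."""

    green_intensity: float
    red_intensity: float
    total_intensity: float
    rg_ratio: float | None  # None when green intensity is zero
    loglog_slope: float | None = None


DEFAULT_ARCHITECTURE = ParticleArchitecture()
DEFAULT_RATE_PARAMS = RateParams()


# ---------------------------------------------------------------------------
# kinetics core
# ---------------------------------------------------------------------------


def _pump_rate(params: RateParams, exc: Excitation) -> float:
    """sigma * photon flux, s^-1 per ground-state Yb ion."""
    return params.sigma_yb * exc.photon_flux


def _k_surf(arch: ParticleArchitecture, params: RateParams) -> float:
    return params.k_surf0 * np.exp(-arch.inert_shell_thickness / params.lambda_s)


def _rates_vector(
    y: np.ndarray,
    arch: ParticleArchitecture,
    params: RateParams,
    pump: float,
) -> np.ndarray:
    """dN/dt for the 9-component state vector (see PopulationState ordering)."""
    yb0c, yb1c, yb0s, yb1s = y[0], y[1], y[2], y[3]
    er0, er1, er2, er3, er4 = y[4], y[5], y[6], y[7], y[8]
    t1, t2, t3, t4 = params.tau_er

    k_mig = params.k_mig0 * arch.core_yb_fraction + params.k_iet
    k_surf = _k_surf(arch, params)

    r_etu1 = params.c_etu1 * yb1c * er0
    r_etu2 = params.c_etu2 * yb1c * er2
    r_etu3 = params.c_etu3 * yb1c * er1
    r_bet = params.c_bet * er4 * yb0c
    r_cr = params.c_cr * er4 * er0
    r_mig = k_mig * (yb1s - yb1c)  # net shell -> core excitation flux

    dyb1c = (
        pump * yb0c - yb1c / params.tau_yb + r_mig
        - r_etu1 - r_etu2 - r_etu3 + r_bet
    )
    dyb1s = pump * yb0s - yb1s / params.tau_yb - r_mig - k_surf * yb1s

    # Er level kinetics: ETU ladder, BET/CR feeds into level 1, linear decays
    # with branching, and surface quenching on the emitting levels and on the
    # long-lived 4I13/2 reservoir (the level most exposed to surface phonons).
    d_er4 = r_etu2 - r_bet - r_cr - er4 / t4 - k_surf * er4
    d_er3 = r_etu3 + params.branch_43 * er4 / t4 - er3 / t3 - k_surf * er3
    d_er2 = r_etu1 - r_etu2 - er2 / t2
    d_er1 = (
        r_bet + 2.0 * r_cr - r_etu3 + params.branch_21 * er2 / t2
        - er1 / t1 - k_surf * er1
    )
    d_er0 = (
        -r_etu1 - r_cr
        + (1.0 - params.branch_43) * er4 / t4 + k_surf * er4
        + er3 / t3 + k_surf * er3
        + (1.0 - params.branch_21) * er2 / t2
        + er1 / t1 + k_surf * er1
    )

    return np.array(
        [-dyb1c, dyb1c, -dyb1s, dyb1s, d_er0, d_er1, d_er2, d_er3, d_er4]
    )


def derivatives(
    state: PopulationState,
    arch: ParticleArchitecture,
    params: RateParams,
    exc: Excitation,
) -> PopulationState:
    """Time derivative dN/dt of every population, as a PopulationState of rates.

    Every bimolecular transfer term moves one excitation quantum per event, so
    the compartment Yb totals and the Er total are conserved by construction.
    """
    state.validate()
    dy = _rates_vector(state.to_vector(), arch, params, _pump_rate(params, exc))
    return PopulationState.from_vector(dy)


# Reduced coordinates used by the solvers: excited populations only; ground
# states follow from per-compartment conservation, which is then exact.
_EXCITED_IDX = np.array([1, 3, 5, 6, 7, 8])  # yb1c, yb1s, er1..er4


def _totals(arch: ParticleArchitecture) -> tuple[float, float, float]:
    return (
        arch.core_yb_fraction * arch.cation_density,
        arch.interior_shell_yb_fraction * arch.cation_density,
        arch.core_er_fraction * arch.cation_density,
    )


def _expand(z: np.ndarray, arch: ParticleArchitecture) -> np.ndarray:
    n_yb_c, n_yb_s, n_er = _totals(arch)
    yb1c, yb1s, er1, er2, er3, er4 = z
    return np.array(
        [n_yb_c - yb1c, yb1c, n_yb_s - yb1s, yb1s,
         n_er - er1 - er2 - er3 - er4, er1, er2, er3, er4]
    )


def _reduced_rhs(
    z: np.ndarray, arch: ParticleArchitecture, params: RateParams, pump: float
) -> np.ndarray:
    return _rates_vector(_expand(z, arch), arch, params, pump)[_EXCITED_IDX]


def _integrate_to_steady(
    arch: ParticleArchitecture,
    params: RateParams,
    pump: float,
    z0: np.ndarray,
    t_end: float,
) -> np.ndarray:
    sol = solve_ivp(
        lambda _t, z: _reduced_rhs(z, arch, params, pump),
        (0.0, t_end),
        z0,
        method="BDF",
        rtol=1e-8,
        atol=1e-14 * arch.cation_density,
    )
    if not sol.success:
        raise ConvergenceError(f"steady-state integration failed: {sol.message}")
    return np.clip(sol.y[:, -1], 0.0, None)


def _newton_refine(
    arch: ParticleArchitecture,
    params: RateParams,
    pump: float,
    z0: np.ndarray,
    tol: float,
    max_iter: int = 50,
) -> np.ndarray:
    """Damped Newton iteration on the reduced rate equations."""
    scale = arch.cation_density
    tau_scale = max(params.tau_yb, *params.tau_er)

    def resid(z: np.ndarray) -> float:
        return float(np.max(np.abs(_reduced_rhs(z, arch, params, pump))) * tau_scale / scale)

    z = z0.copy()
    for _ in range(max_iter):
        f = _reduced_rhs(z, arch, params, pump)
        if resid(z) < tol:
            return z
        # finite-difference Jacobian (6x6)
        jac = np.empty((6, 6))
        h = np.maximum(1e-8 * np.abs(z), 1e-12 * scale)
        for j in range(6):
            zp = z.copy()
            zp[j] += h[j]
            jac[:, j] = (_reduced_rhs(zp, arch, params, pump) - f) / h[j]
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            break
        # step halving until the residual decreases and positivity holds
        lam, r0 = 1.0, resid(z)
        for _half in range(30):
            zt = z + lam * step
            if np.all(zt > -1e-12 * scale) and resid(np.clip(zt, 0, None)) < r0:
                z = np.clip(zt, 0.0, None)
                break
            lam *= 0.5
        else:
            break
    if resid(z) >= tol:
        raise ConvergenceError(
            f"Newton refinement stalled at residual {resid(z):.3e} (tol {tol:.1e})"
        )
    return z


def steady_state(
    arch: ParticleArchitecture = DEFAULT_ARCHITECTURE,
    params: RateParams = DEFAULT_RATE_PARAMS,
    exc: Excitation = Excitation(),
    tol: float = 1e-10,
) -> PopulationState:
    """Steady-state populations under continuous-wave excitation.

    Integrates the stiff rate equations from the ground state until the scaled
    residual max|dN/dt|*tau / N_total falls below ``tol``, then polishes the
    root with a damped Newton iteration.  Ground-state populations are
    reconstructed from per-compartment conservation, so the invariants hold
    exactly.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pump = _pump_rate(params, exc)
    if exc.power_density == 0.0:
        return PopulationState.ground(arch)
    tau_scale = max(params.tau_yb, *params.tau_er)
    z = _integrate_to_steady(
        arch, params, pump, np.zeros(6), t_end=50.0 * tau_scale
    )
    z = _newton_refine(arch, params, pump, z, tol)
    return PopulationState.from_vector(_expand(z, arch))


def emission_summary(
    state: PopulationState,
    params: RateParams = DEFAULT_RATE_PARAMS,
    arch: ParticleArchitecture = DEFAULT_ARCHITECTURE,
) -> EmissionSummary:
    """Green/red photon emission rates of a (steady) state, per particle.

    Green counts the radiative fraction of level-4 decay (1 - branch_43), red
    the level-3 decay; both scale with the core volume that hosts the Er ions.
    """
    t3, t4 = params.tau_er[2], params.tau_er[3]
    v = arch.core_volume
    green = (1.0 - params.branch_43) * state.n_er[4] / t4 * v
    red = state.n_er[3] / t3 * v
    rg = red / green if green > 0 else None
    return EmissionSummary(
        green_intensity=green,
        red_intensity=red,
        total_intensity=green + red,
        rg_ratio=rg,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _fit_loglog_slope(rho: np.ndarray, intensity: np.ndarray) -> float:
    """Unweighted least-squares slope of log10 I vs log10 rho over the lowest decade."""
    rho = np.asarray(rho, float)
    intensity = np.asarray(intensity, float)
    mask = (rho <= 10.0 * rho[0]) & (intensity > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 nonzero intensities in the lowest decade")
    return float(np.polyfit(np.log10(rho[mask]), np.log10(intensity[mask]), 1)[0])


@dataclass
class PowerSweepResult:
    """Per-power emission summaries plus low-power log-log slopes."""

    power_densities: np.ndarray
    summaries: list[EmissionSummary]
    slope_total: float
    slope_green: float
    slope_red: float

    def intensities(self, channel: str = "total") -> np.ndarray:
        key = {"total": "total_intensity", "green": "green_intensity",
               "red": "red_intensity"}[channel]
        return np.array([getattr(s, key) for s in self.summaries])


def power_sweep(
    arch: ParticleArchitecture = DEFAULT_ARCHITECTURE,
    params: RateParams = DEFAULT_RATE_PARAMS,
    rho_grid: np.ndarray | None = None,
) -> PowerSweepResult:
    """Steady-state emission across an excitation power grid (kW cm^-2).

    The slope is fitted on log10 intensity vs log10 power over the lowest
    decade of the grid, the standard way upconversion power dependence is
    quantified.
    """
    if rho_grid is None:
        rho_grid = np.geomspace(0.69, 21.7, 10)
    rho_grid = np.asarray(rho_grid, float)
    if len(rho_grid) < 4 or np.any(np.diff(rho_grid) <= 0):
        raise ValueError("rho_grid must be strictly increasing with >= 4 points")
    summaries = [
        emission_summary(steady_state(arch, params, Excitation(r)), params, arch)
        for r in rho_grid
    ]
    tot = np.array([s.total_intensity for s in summaries])
    grn = np.array([s.green_intensity for s in summaries])
    red = np.array([s.red_intensity for s in summaries])
    return PowerSweepResult(
        power_densities=rho_grid,
        summaries=summaries,
        slope_total=_fit_loglog_slope(rho_grid, tot),
        slope_green=_fit_loglog_slope(rho_grid, grn),
        slope_red=_fit_loglog_slope(rho_grid, red),
    )


def doping_sweep(
    params: RateParams = DEFAULT_RATE_PARAMS,
    x_yb_grid: np.ndarray | None = None,
    x_er: float = 0.1,
    arch_template: ParticleArchitecture = DEFAULT_ARCHITECTURE,
    exc: Excitation = Excitation(11.6),
) -> "pd.DataFrame":
    """Total intensity and R/G ratio vs core Yb fraction at fixed Er fraction."""
    import pandas as pd

    if x_yb_grid is None:
        x_yb_grid = np.linspace(0.0, 0.9, 10)
    rows = []
    for x in np.asarray(x_yb_grid, float):
        if x + x_er > 1.0:
            raise ValueError(f"x_Yb + x_Er = {x + x_er:.3f} exceeds 1")
        arch = replace(arch_template, core_yb_fraction=float(x), core_er_fraction=x_er)
        s = emission_summary(steady_state(arch, params, exc), params, arch)
        rows.append(
            {"x_yb": x, "x_er": x_er, "power_kw_cm2": exc.power_density,
             "green": s.green_intensity, "red": s.red_intensity,
             "total": s.total_intensity, "rg_ratio": s.rg_ratio}
        )
    return pd.DataFrame(rows)


def shell_sweep(
    params: RateParams = DEFAULT_RATE_PARAMS,
    t_inert_grid: np.ndarray | None = None,
    arch_template: ParticleArchitecture = DEFAULT_ARCHITECTURE,
    exc: Excitation = Excitation(11.6),
) -> "pd.DataFrame":
    """Brightness and R/G ratio vs inert-shell thickness (surface screening)."""
    import pandas as pd

    if t_inert_grid is None:
        t_inert_grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.3, 5.4, 6.8])
    t_inert_grid = np.asarray(t_inert_grid, float)
    if np.any(t_inert_grid < 0):
        raise ValueError("shell thickness grid must be non-negative")
    rows = []
    for t in t_inert_grid:
        arch = replace(arch_template, inert_shell_thickness=float(t))
        s = emission_summary(steady_state(arch, params, exc), params, arch)
        rows.append(
            {"t_inert_nm": t, "power_kw_cm2": exc.power_density,
             "green": s.green_intensity, "red": s.red_intensity,
             "total": s.total_intensity, "rg_ratio": s.rg_ratio}
        )
    return pd.DataFrame(rows)


@dataclass
class DecayResult:
    """Time-resolved emission after square-pulse excitation."""

    time: np.ndarray  # s, spanning pulse-on and pulse-off
    green: np.ndarray
    red: np.ndarray
    pulse_duration: float
    green_tail_lifetime: float  # mono-exponential fit to the pulse-off green tail
    yb_tail_lifetime: float  # same fit applied to the core Yb excited population
    yb1_core: np.ndarray


def decay_simulation(
    arch: ParticleArchitecture = DEFAULT_ARCHITECTURE,
    params: RateParams = DEFAULT_RATE_PARAMS,
    exc: Excitation = Excitation(11.6, pulsed=True),
    pulse_duration: float = 2e-3,
    horizon: float | None = None,
    n_samples: int = 400,
) -> DecayResult:
    """Integrate the kinetics through pulse-on then pulse-off phases.

    The effective lifetime is a mono-exponential fit (linear regression on the
    log trace) over the tail window where the signal has fallen to between
    50% and 1% of its value at pulse-off.
    """
    tau_scale = max(params.tau_yb, *params.tau_er)
    if horizon is None:
        horizon = pulse_duration + 8.0 * tau_scale
    if pulse_duration >= horizon:
        raise ValueError("pulse must end before the simulation horizon")
    pump = _pump_rate(params, exc)

    if pulse_duration > 0 and pump > 0:
        t_on = np.linspace(0.0, pulse_duration, max(n_samples // 4, 8))
        sol_on = solve_ivp(
            lambda _t, z: _reduced_rhs(z, arch, params, pump),
            (0.0, pulse_duration), np.zeros(6), method="BDF",
            t_eval=t_on, rtol=1e-8, atol=1e-14 * arch.cation_density,
        )
        if not sol_on.success:
            raise ConvergenceError(f"pulse-on integration failed: {sol_on.message}")
        z_pulse_end = sol_on.y[:, -1]
    else:
        t_on = np.array([0.0])
        sol_on = None
        z_pulse_end = np.zeros(6)

    t_off = np.linspace(pulse_duration, horizon, n_samples)
    sol_off = solve_ivp(
        lambda _t, z: _reduced_rhs(z, arch, params, 0.0),
        (pulse_duration, horizon), z_pulse_end, method="BDF",
        t_eval=t_off, rtol=1e-8, atol=1e-14 * arch.cation_density,
    )
    if not sol_off.success:
        raise ConvergenceError(f"pulse-off integration failed: {sol_off.message}")

    if sol_on is not None:
        time = np.concatenate([sol_on.t, sol_off.t[1:]])
        z_all = np.concatenate([sol_on.y, sol_off.y[:, 1:]], axis=1)
    else:
        time, z_all = sol_off.t, sol_off.y
    z_all = np.clip(z_all, 0.0, None)

    t3, t4 = params.tau_er[2], params.tau_er[3]
    v = arch.core_volume
    green = (1.0 - params.branch_43) * z_all[5] / t4 * v  # er4 is reduced index 5
    red = z_all[4] / t3 * v  # er3 is reduced index 4
    yb1c = z_all[0]

    def tail_lifetime(trace: np.ndarray) -> float:
        off = time >= pulse_duration
        t, s = time[off], trace[off]
        if s[0] <= 0:
            return float("nan")
        win = (s > 0) & (s <= 0.5 * s[0]) & (s >= 0.01 * s[0])
        if win.sum() < 3:
            return float("nan")
        slope = np.polyfit(t[win], np.log(s[win]), 1)[0]
        return float(-1.0 / slope)

    return DecayResult(
        time=time, green=green, red=red, pulse_duration=pulse_duration,
        green_tail_lifetime=tail_lifetime(green),
        yb_tail_lifetime=tail_lifetime(yb1c),
        yb1_core=yb1c,
    )


def yb_content_ratio(arch_a: ParticleArchitecture, arch_b: ParticleArchitecture) -> float:
    """Ratio of total Yb3+ ion counts in the active volumes of two architectures.

    Used to compare the light-harvesting capacity of, e.g., an alloy-core
    particle against a sensitizer-free-core particle of the same geometry.
    """
    return arch_a.yb_ions() / arch_b.yb_ions()
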
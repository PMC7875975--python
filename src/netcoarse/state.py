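"""Core containers: units, particle states, trajectories, quench protocols."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class UnitsConvention:
    """Reduced-unit bookkeeping for LJ particle and colloid simulations.

    MD uses standard LJ units (sigma, epsilon, m, tau_lj = sqrt(sigma^2 m /
    epsilon)).  Colloid dynamics uses the drag time tau_d = 3 pi eta sigma^3 /
    epsilon: the time for a free colloid pulled by a force epsilon/sigma to
    move one diameter.  The Reynolds number Re = rho_f sigma^2 / (eta tau_d)
    fixes the LJ depth for the hydrodynamic simulations.
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    mass: float = 1.0
    eta: float = 1.0
    kB: float = 1.0
    rho_fluid: float = 1.0

    def __post_init__(self):
        for name in ("sigma", "epsilon", "mass", "eta", "kB", "rho_fluid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def tau_lj(self) -> float:
        return math.sqrt(self.sigma ** 2 * self.mass / self.epsilon)

    @property
    def tau_d(self) -> float:
        return 3.0 * math.pi * self.eta * self.sigma ** 3 / self.epsilon

    @property
    def reynolds(self) -> float:
        return self.rho_fluid * self.sigma ** 2 / (self.eta * self.tau_d)

    @classmethod
    def for_reynolds(cls, re: float = 0.8, sigma: float = 1.0, eta: float = 1.0,
                     rho_fluid: float = 1.0) -> "UnitsConvention":
        """Choose the LJ depth so that the colloid Reynolds number equals re."""
        epsilon = 3.0 * math.pi * eta ** 2 * sigma * re / rho_fluid
        return cls(sigma=sigma, epsilon=epsilon, eta=eta, rho_fluid=rho_fluid)


@dataclass
class ParticleState:
    """Particle configuration in a periodic cubic (square) box [0, L)^d."""

    positions: np.ndarray       # (N, d)
    velocities: np.ndarray      # (N, d)
    species: np.ndarray         # (N,) int
    box_length: float
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be (N, d) with d in {2, 3}")
        if self.positions.shape[0] == 0:
            raise ValueError("empty particle state")
        self.wrap()

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dims(self) -> int:
        return self.positions.shape[1]

    def wrap(self) -> None:
        np.mod(self.positions, self.box_length, out=self.positions)

    def volume_fraction(self, sigma: float = 1.0) -> float:
        """Sphere (disc) volume fraction pi sigma^3 N / (6 L^3) in 3D."""
        L, N = self.box_length, self.n
        if self.dims == 3:
            return math.pi * sigma ** 3 * N / (6.0 * L ** 3)
        return math.pi * sigma ** 2 * N / (4.0 * L ** 2)

    def kinetic_temperature(self, mass: float = 1.0) -> float:
        N, d = self.velocities.shape
        k2 = float(np.sum(self.velocities ** 2))
        nfree = N * d - d
        return mass * k2 / nfree

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.velocities.copy(),
                             self.species.copy(), self.box_length, self.time)


@dataclass
class Trajectory:
    """Ordered frames plus a per-sample thermodynamic log."""

    frames: list = field(default_factory=list)
    thermo: Optional["np.ndarray"] = None  # columns: time, T_kin, E_pot, pressure
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frames:
            sp0 = self.frames[0].species
            for f in self.frames[1:]:
                if not np.array_equal(f.species, sp0):
                    raise ValueError("species labels must be constant across frames")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> ParticleState:
        return self.frames[i]

    def frame_at(self, t: float, atol: float = 1e-9) -> ParticleState:
        times = self.times
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > atol:
            raise KeyError(f"no frame at t={t}; nearest is t={times[i]}")
        return self.frames[i]

    def unwrapped_positions(self) -> np.ndarray:
        """(n_frames, N, d) positions unwrapped by accumulated minimum image.

        Valid when no particle moves more than L/2 between consecutive frames.
        """
        L = self.frames[0].box_length
        out = np.empty((len(self.frames),) + self.frames[0].positions.shape)
        out[0] = self.frames[0].positions
        for i in range(1, len(self.frames)):
            step = self.frames[i].positions - self.frames[i - 1].positions
            step -= L * np.rint(step / L)
            out[i] = out[i - 1] + step
        return out


@dataclass
class QuenchProtocol:
    """Quench schedule for the MD simulators.

    mixture: None for the one-component fluid, or "symmetric_binary" for the
    50-50 mixture whose cross-species well depth is half the like-species one.
    """

    rho: float = 0.33
    T_init: float = 1.8
    T_target: float = 0.1
    dims: int = 3
    n_particles: int = 4000
    equilibration_steps: int = 5000
    production_steps: int = 20000
    dt: float = 0.002
    dt_equil: float = 0.001
    rc: float = 2.5
    skin: float = 0.3
    thermostat_damping: float = 0.1
    seed: int = 0
    mixture: Optional[str] = None

    def __post_init__(self):
        if self.dt <= 0 or self.dt_equil <= 0:
            raise ValueError("time step must be positive")
        if self.T_target >= self.T_init:
            raise ValueError("a quench requires T_target < T_init")
        if self.mixture not in (None, "symmetric_binary"):
            raise ValueError(f"unknown mixture: {self.mixture!r}")

    @property
    def box_length(self) -> float:
        if self.dims == 3:
            return (self.n_particles / self.rho) ** (1.0 / 3.0)
        return (self.n_particles / self.rho) ** 0.5

    def eps_table(self) -> np.ndarray:
        if self.mixture == "symmetric_binary":
            return np.array([[1.0, 0.5], [0.5, 1.0]])
        return np.array([[1.0]])

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
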
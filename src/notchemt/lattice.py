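"""2-D multicellular lattice of Notch-EMT-Numb cells.

Every lattice site runs the single-cell circuit; cells are coupled through
the external receptor/ligand levels they present to their 4-neighbourhood
(juxtacrine signalling), aggregated as the arithmetic mean by default so
the external-ligand scale matches the single-cell bifurcation scans.
Uniform soluble-ligand fields (sD_ext, sJ_ext) and an EMT-inducer field
(I_ext) add into every cell's environment.  The whole grid is integrated
as one coupled ODE system (no operator splitting).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import IDX, N_SPECIES, Environment, rhs
from .params import ModelParameters
from .steady_state import state_scales

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "neighbour_environment",
    "random_initial_lattice",
    "hybrid_initial_lattice",
    "self_coupled_steady_states",
    "integrate_lattice",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, coupling, fields and schedule of one lattice simulation."""

    rows: int = 50
    cols: int = 50
    boundary: str = "periodic"         # periodic | reflecting
    aggregation: str = "mean"          # mean | sum over the 4-neighbourhood
    g_J: float | None = None           # molecules/h override of params.g_J
    g_D: float | None = None           # molecules/h override of params.g_D
    sD_ext: float = 0.0                # soluble Delta (molecules, uniform)
    sJ_ext: float = 0.0                # soluble Jagged (molecules, uniform)
    I_ext: float = 0.0                 # EMT inducer (molecules, uniform)
    duration: float = 120.0            # transient length (h)
    snapshot_times: tuple[float, ...] = ()
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.rows * self.cols < 1:
            raise ValueError("lattice must contain at least one cell")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError("boundary must be periodic or reflecting")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be mean or sum")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if any(t < 0 or t > self.duration for t in self.snapshot_times):
            raise ValueError("snapshot times must lie in [0, duration]")

    def apply_overrides(self, params: ModelParameters) -> ModelParameters:
        over = {}
        if self.g_J is not None:
            over["g_J"] = self.g_J
        if self.g_D is not None:
            over["g_D"] = self.g_D
        return params.replace(**over) if over else params

    def times(self) -> np.ndarray:
        ts = set(float(t) for t in self.snapshot_times)
        ts.add(float(self.duration))
        return np.array(sorted(ts))

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=float)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class LatticeState:
    """All cell states of the lattice at one time point."""

    time: float
    grid: np.ndarray                  # shape (11, rows, cols), molecules
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.grid.ndim != 3 or self.grid.shape[0] != N_SPECIES:
            raise ValueError("grid must have shape (11, rows, cols)")

    @property
    def shape(self):
        return self.grid.shape[1:]

    def cell(self, row: int, col: int) -> np.ndarray:
        return self.grid[:, row, col]

    def to_frame(self):
        """Tidy table: one row per cell with species columns."""
        import pandas as pd
        from .circuit import SPECIES
        rows, cols = self.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        data = {"row": rr.ravel(), "col": cc.ravel()}
        for i, sp in enumerate(SPECIES):
            data[sp] = self.grid[i].ravel()
        df = pd.DataFrame(data)
        df.insert(0, "time", self.time)
        return df


def _neighbour_sum(a: np.ndarray, boundary: str) -> np.ndarray:
    """Sum of the 4 nearest neighbours for each site of a 2-D array."""
    if boundary == "periodic":
        return (np.roll(a, 1, 0) + np.roll(a, -1, 0)
                + np.roll(a, 1, 1) + np.roll(a, -1, 1))
    # reflecting: out-of-grid neighbours mirror the edge cell itself
    p = np.pad(a, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]


def _grid_environment(grid: np.ndarray, config: LatticeConfig) -> Environment:
    """Environment arrays (rows x cols) seen by every cell simultaneously."""
    factor = 0.25 if config.aggregation == "mean" else 1.0
    return Environment(
        N_ext=factor * _neighbour_sum(grid[IDX["N"]], config.boundary),
        D_ext=factor * _neighbour_sum(grid[IDX["D"]], config.boundary),
        J_ext=factor * _neighbour_sum(grid[IDX["J"]], config.boundary),
        sD_ext=config.sD_ext, sJ_ext=config.sJ_ext, I_ext=config.I_ext)


def neighbour_environment(lattice: LatticeState, row: int, col: int,
                          config: LatticeConfig) -> Environment:
    """External signals seen by the cell at (row, col)."""
    rows, cols = lattice.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError("cell index outside the lattice")
    env = _grid_environment(lattice.grid, config)
    return Environment(N_ext=float(env.N_ext[row, col]),
                       D_ext=float(env.D_ext[row, col]),
                       J_ext=float(env.J_ext[row, col]),
                       sD_ext=config.sD_ext, sJ_ext=config.sJ_ext,
                       I_ext=config.I_ext)


def basal_scales(params: ModelParameters, config: LatticeConfig) -> np.ndarray:
    """Basal production/degradation level (molecules) per species.

    Unregulated steady-state levels (no fold-change amplification): the
    box random initial conditions are drawn from.  Proteins with an mRNA
    stage use the basal mRNA level times translation/degradation; NICD uses
    the trans-activation flux at basal receptor/ligand levels.
    """
    p = config.apply_overrides(params)
    sN = p.g_N / p.gamma_N
    sD = p.g_D / p.gamma_D
    sJ = p.g_J / p.gamma_J
    sI = (p.k_T * sN * (sD + sJ + config.sD_ext + config.sJ_ext)
          / p.gamma_I)
    sP = p.g_P / p.gamma_P
    su34 = p.g_u34 / p.gamma_u34
    smS = p.g_mS / p.gamma_mS
    sS = p.g_S * smS / p.gamma_S
    su200 = p.g_u200 / p.gamma_u200
    smZ = p.g_mZ / p.gamma_mZ
    sZ = p.g_Z * smZ / p.gamma_Z
    return np.maximum(np.array([sN, sD, sJ, sI, sP, su34, smS, sS,
                                su200, smZ, sZ]), 1.0)


def random_initial_lattice(config: LatticeConfig, params: ModelParameters,
                           seed: int | None = None, replicate: int = 0
                           ) -> LatticeState:
    """Random initial conditions: each species uniform on [0, scale].

    ``scale`` is the species' production/degradation level, so draws span
    the physiological box; replicate ``r`` uses ``seed + r`` (deterministic
    given the seed).
    """
    p = config.apply_overrides(params)
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed + replicate)
    scales = basal_scales(p, config)
    grid = rng.uniform(0.0, 1.0, size=(N_SPECIES, config.rows, config.cols))
    grid *= scales[:, None, None]
    meta = {"config_hash": config.hash(), "seed": base_seed,
            "replicate": replicate, "init": "random"}
    return LatticeState(time=0.0, grid=grid, meta=meta)


def self_coupled_steady_states(config: LatticeConfig, params: ModelParameters,
                               n_starts: int = 40, seed: int = 0):
    """Steady states of a homogeneous lattice (every cell identical).

    In a homogeneous lattice with mean aggregation each cell's neighbour
    environment equals its own N/D/J, so homogeneous fixed points solve the
    single-cell circuit with a state-dependent environment.  Returns
    :class:`notchemt.steady_state.SteadyState` objects (stability refers to
    the homogeneous self-coupled system, i.e. to spatially uniform modes).
    """
    from .steady_state import (RESIDUAL_TOL, _classify_root, _dedup,
                               _flow_to_attractors, _gammas, _newton_polish)
    p = config.apply_overrides(params)
    factor = 1.0 if config.aggregation == "mean" else 4.0

    def f(Y):
        env = Environment(N_ext=factor * np.maximum(Y[IDX["N"]], 0.0),
                          D_ext=factor * np.maximum(Y[IDX["D"]], 0.0),
                          J_ext=factor * np.maximum(Y[IDX["J"]], 0.0),
                          sD_ext=config.sD_ext, sJ_ext=config.sJ_ext,
                          I_ext=config.I_ext)
        return rhs(Y, env, p)

    scale_env = Environment(N_ext=p.g_N * max(1.0, p.lam_I_N) / p.gamma_N,
                            D_ext=p.g_D / p.gamma_D, J_ext=p.g_J / p.gamma_J,
                            sD_ext=config.sD_ext, sJ_ext=config.sJ_ext,
                            I_ext=config.I_ext)
    scales = state_scales(p, scale_env)
    flux = scales * _gammas(p)
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 2.0, (N_SPECIES, n_starts)) * scales[:, None]
    starts = np.concatenate([starts, np.zeros((N_SPECIES, 1)),
                             scales[:, None]], axis=1)
    roots, stalled = _newton_polish(f, starts, scales, flux)
    if roots.shape[1] == 0 and stalled.shape[1]:
        settled = _flow_to_attractors(f, stalled[:, :6])
        roots, _ = _newton_polish(f, settled, scales, flux)
    out = []
    for r in _dedup(roots, scales):
        ss = _classify_root(f, r, scales, flux)
        if ss.residual <= RESIDUAL_TOL:
            out.append(ss)
    return out


def hybrid_initial_lattice(config: LatticeConfig, params: ModelParameters,
                           thresholds, jitter: float = 0.01,
                           seed: int | None = None,
                           include_inducer: bool = False) -> LatticeState:
    """Homogeneous lattice initialised at the hybrid E/M fixed point.

    The hybrid state is the stable homogeneous-lattice fixed point whose
    miR-200 level classifies as E/M (located with the EMT inducer off
    unless ``include_inducer``); a seeded 1% multiplicative jitter breaks
    exact symmetry.  Raises if no hybrid state exists, pointing at the
    bifurcation scan to find one.
    """
    from .metrics import classify_phenotype
    cfg0 = config if include_inducer else dataclasses.replace(config, I_ext=0.0)
    states = self_coupled_steady_states(cfg0, params,
                                        seed=0 if seed is None else seed)
    hybrids = [s for s in states if s.stable
               and classify_phenotype(s.state, thresholds)[0] == "E/M"]
    if not hybrids:
        # no homogeneous-lattice hybrid: fall back to the single-cell hybrid
        # fixed point from the tristable window of a J_ext scan
        hybrids = _single_cell_hybrids(cfg0.apply_overrides(params), thresholds)
    if not hybrids:
        raise ValueError(
            "no stable hybrid E/M state at these parameters; run a "
            "bifurcation scan (scan_bifurcation) to locate a regime where "
            "the hybrid branch is stable")
    x = hybrids[0].state
    grid = np.tile(x[:, None, None], (1, config.rows, config.cols)).astype(float)
    if jitter:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        grid *= 1.0 + jitter * (2.0 * rng.random(grid.shape) - 1.0)
    meta = {"config_hash": config.hash(), "seed": config.seed if seed is None
            else seed, "init": "hybrid", "jitter": jitter}
    return LatticeState(time=0.0, grid=grid, meta=meta)


def _single_cell_hybrids(params: ModelParameters, thresholds,
                         scan_max: float = 4000.0, n_points: int = 33):
    """Stable single-cell hybrid E/M states along a coarse J_ext scan."""
    from .metrics import classify_phenotype
    from .steady_state import find_steady_states
    out = []
    for J in np.linspace(0.0, scan_max, n_points):
        env = Environment(N_ext=10000.0, J_ext=float(J))
        for s in find_steady_states(env, params, n_starts=24, seed=11):
            if s.stable and classify_phenotype(s.state, thresholds)[0] == "E/M":
                out.append(s)
        if out:
            break
    return out


def integrate_lattice(initial: LatticeState, config: LatticeConfig,
                      params: ModelParameters, rtol: float = 1e-6,
                      atol: float = 1e-3) -> list[LatticeState]:
    """Advance the coupled lattice ODE system; returns snapshots.

    Neighbour environments are recomputed continuously from the current
    states (the grid is one ODE vector, integrated with an adaptive
    explicit Runge-Kutta scheme).  Snapshots are returned at
    ``config.snapshot_times`` plus ``t = duration``.
    """
    p = config.apply_overrides(params)
    shape = initial.grid.shape
    if shape[1:] != (config.rows, config.cols):
        raise ValueError("initial lattice shape does not match config")
    y0 = initial.grid.ravel()
    if not np.all(np.isfinite(y0)):
        raise FloatingPointError("integrate_lattice: non-finite initial state")

    def f(t, y):
        grid = y.reshape(shape)
        env = _grid_environment(grid, config)
        return rhs(grid, env, p).ravel()

    times = config.times()
    sol = solve_ivp(f, (0.0, float(config.duration)), y0, t_eval=times,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        y_last = sol.y[:, -1] if sol.y.size else y0
        bad = ~np.isfinite(y_last.reshape(shape))
        coords = np.argwhere(bad.any(axis=0))
        at = coords[0].tolist() if coords.size else "unknown"
        raise RuntimeError(
            f"lattice integration failed at t~{sol.t[-1] if sol.t.size else 0}"
            f" (cell {at}): {sol.message}")
    meta = dict(initial.meta)
    meta["config_hash"] = config.hash()
    return [LatticeState(time=float(t), grid=sol.y[:, i].reshape(shape).copy(),
                         meta=dict(meta)) for i, t in enumerate(sol.t)]
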
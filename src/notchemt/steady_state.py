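"""Steady states, stability and 1-D bifurcation diagrams of the single-cell circuit.

Steady states are located by multi-start damped Newton iteration on the
circuit RHS, vectorized over starting points, with de-duplication and
stability classification from the Jacobian spectrum.  Bifurcation diagrams
over an external control (J_ext, D_ext or I_ext) are assembled by rerunning
the multi-start search along a grid with warm-starting from neighbouring
grid points, then linking roots into branches by nearest-state continuation.
This brute-force continuation is accurate to one grid step for branch
extents, which a bisection refinement tightens where needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .circuit import IDX, N_SPECIES, Environment, rhs, simulate_cell
from .params import ModelParameters

__all__ = [
    "SteadyState",
    "Branch",
    "BifurcationDiagram",
    "state_scales",
    "find_steady_states",
    "scan_bifurcation",
    "stability_interval",
]

#: eigenvalue real-part margin (1/h) separating stable / marginal / unstable
STABILITY_MARGIN = 1e-6
#: relative root de-duplication tolerance (max norm over scaled species)
DEDUP_RTOL = 1e-4
#: accepted scaled residual for a converged root
RESIDUAL_TOL = 1e-6

CONTROLS = ("J_ext", "D_ext", "I_ext")


@dataclass
class SteadyState:
    """One fixed point of the circuit at a fixed environment."""

    state: np.ndarray          # length-11, molecules, SPECIES order
    stable: bool
    marginal: bool             # leading eigenvalue within +/- STABILITY_MARGIN
    leading_eigenvalue: float  # largest real part of the Jacobian spectrum (1/h)
    residual: float            # max-norm RHS residual, scaled by per-species flux

    @property
    def u200(self) -> float:
        return float(self.state[IDX["u200"]])


@dataclass
class Branch:
    """A continuation-linked branch of a bifurcation diagram."""

    grid_indices: list[int] = field(default_factory=list)
    states: list[SteadyState] = field(default_factory=list)
    phenotype: str | None = None

    def control_values(self, grid: np.ndarray) -> np.ndarray:
        return grid[self.grid_indices]

    @property
    def any_stable(self) -> bool:
        return any(s.stable for s in self.states)


@dataclass
class BifurcationDiagram:
    control: str
    grid: np.ndarray
    roots: list[list[SteadyState]]     # per grid point
    branches: list[Branch]
    env_base: Environment
    params: ModelParameters

    def label_phenotypes(self, thresholds) -> None:
        """Assign each branch the EMT phenotype of its member states.

        ``thresholds`` is a :class:`notchemt.metrics.PhenotypeThresholds`.
        A branch whose states straddle a threshold keeps the majority label.
        """
        from .metrics import classify_phenotype
        for br in self.branches:
            labels = [classify_phenotype(s.state, thresholds)[0] for s in br.states]
            br.phenotype = max(set(labels), key=labels.count)

    def stable_count(self) -> np.ndarray:
        return np.array([sum(s.stable for s in pts) for pts in self.roots])

    def to_frame(self):
        """Long-format table: control value, species, stability, branch id."""
        import pandas as pd
        from .circuit import SPECIES
        rows = []
        for b_id, br in enumerate(self.branches):
            for gi, st in zip(br.grid_indices, br.states):
                row = {"control": self.control, "value": float(self.grid[gi]),
                       "stable": st.stable, "marginal": st.marginal,
                       "branch": b_id, "phenotype": br.phenotype,
                       "leading_eigenvalue": st.leading_eigenvalue}
                row.update({sp: float(x) for sp, x in zip(SPECIES, st.state)})
                rows.append(row)
        return pd.DataFrame(rows)


def state_scales(params: ModelParameters, env: Environment) -> np.ndarray:
    """Physiological scale (molecules) per species: production / degradation.

    Used to bound random starting boxes and to normalise distances and
    residuals; upstream activation fold-changes are folded in where they
    can raise the ceiling.
    """
    p = params
    sN = p.g_N * max(1.0, p.lam_I_N) / p.gamma_N
    sD = p.g_D * max(1.0, p.lam_I_D) / p.gamma_D
    sJ = p.g_J * max(1.0, p.lam_I_J) / p.gamma_J
    L_ext = env.D_ext + env.sD_ext + env.J_ext + env.sJ_ext
    sI = max(p.k_T * sN * L_ext / p.gamma_I, 10.0 * p.I0_mS)
    sP = p.g_P / p.gamma_P
    su34 = p.g_u34 / p.gamma_u34
    smS = p.g_mS * max(1.0, p.lam_I_mS) * max(1.0, p.lam_Iext_mS) / p.gamma_mS
    sS = p.g_S * smS / p.gamma_S
    su200 = p.g_u200 / p.gamma_u200
    smZ = p.g_mZ * max(1.0, p.lam_S_mZ) * max(1.0, p.lam_Z_mZ) / p.gamma_mZ
    sZ = p.g_Z * smZ / p.gamma_Z
    out = np.array([sN, sD, sJ, sI, sP, su34, smS, sS, su200, smZ, sZ])
    return np.maximum(out, 1.0)


def _gammas(params: ModelParameters) -> np.ndarray:
    return np.array([getattr(params, "gamma_" + n) for n in
                     ("N", "D", "J", "I", "P", "u34", "mS", "S", "u200",
                      "mZ", "Z")])


def make_rhs(env: Environment, params: ModelParameters):
    """Batched RHS closure f(Y) for Y of shape (11, ...) at fixed environment."""
    def f(Y: np.ndarray) -> np.ndarray:
        return rhs(Y, env, params)
    return f


def _batch_jacobian(f, Y: np.ndarray, scales: np.ndarray,
                    F0: np.ndarray | None = None) -> np.ndarray:
    """Finite-difference Jacobians, shape (k, 11, 11), for Y of shape (11, k).

    Central differences by default; passing the already-known residual
    ``F0`` switches to cheaper forward differences (used inside the Newton
    loop, where the line search absorbs the lower accuracy).
    """
    k = Y.shape[1]
    J = np.empty((k, N_SPECIES, N_SPECIES))
    for j in range(N_SPECIES):
        h = 1e-6 * scales[j]
        Yp = Y.copy(); Yp[j] += h
        if F0 is None:
            Ym = Y.copy(); Ym[j] -= h
            J[:, :, j] = ((f(Yp) - f(Ym)) / (2 * h)).T
        else:
            J[:, :, j] = ((f(Yp) - F0) / h).T
    return J


def _newton_polish(f, starts: np.ndarray, scales: np.ndarray,
                   flux: np.ndarray, max_iter: int = 60):
    """Damped Newton from each column of ``starts``.

    Returns ``(roots, stalled)`` as (11, m) arrays: converged roots, and
    points abandoned because the line search or the convergence rate broke
    down (typically residual-norm local minima near folds).
    """
    Y = starts.astype(float).copy()
    active = np.arange(Y.shape[1])
    prev_res = np.full(Y.shape[1], np.inf)
    converged: list[np.ndarray] = []
    stalled: list[np.ndarray] = []
    for it in range(max_iter):
        if active.size == 0:
            break
        F = f(Y[:, active])
        res = np.max(np.abs(F) / flux[:, None], axis=0)
        done = res < 0.01 * RESIDUAL_TOL
        for i in np.flatnonzero(done):
            converged.append(Y[:, active[i]].copy())
        active = active[~done]
        if active.size == 0:
            break
        F = F[:, ~done]
        res = res[~done]
        Jac = _batch_jacobian(f, Y[:, active], scales, F0=F)
        try:
            step = np.linalg.solve(Jac, -F.T[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Jac[i], -F[:, i], rcond=None)[0]
                             for i in range(active.size)], axis=1)
        # backtracking line search on the scaled residual, keeping states >= 0
        alpha = np.ones(active.size)
        improved = np.zeros(active.size, dtype=bool)
        Ynew = Y[:, active].copy()
        new_res = res.copy()
        for _bt in range(8):
            trial = np.maximum(Y[:, active] + alpha[None, :] * step, 0.0)
            trial_res = np.max(np.abs(f(trial)) / flux[:, None], axis=0)
            better = (trial_res < res) & ~improved
            Ynew[:, better] = trial[:, better]
            new_res[better] = trial_res[better]
            improved |= better
            if improved.all():
                break
            alpha[~improved] *= 0.4
        Y[:, active] = Ynew
        # abandon starts that cannot improve, or whose linear progress is
        # too slow to be in a Newton basin (residual-norm local minima near
        # folds); they feed the integrate-then-polish fallback
        slow = improved & (new_res > 0.9 * prev_res[active]) & (it > 4)
        keep = improved & ~slow
        for i in np.flatnonzero(~keep):
            stalled.append(Y[:, active[i]].copy())
        prev_res[active] = new_res
        active = active[keep]
    for i in active:  # ran out of iterations
        stalled.append(Y[:, i].copy())
    conv = (np.stack(converged, axis=1) if converged
            else np.empty((N_SPECIES, 0)))
    stal = (np.stack(stalled, axis=1) if stalled
            else np.empty((N_SPECIES, 0)))
    return conv, stal


def _flow_to_attractors(f, starts: np.ndarray, horizon: float = 400.0
                        ) -> np.ndarray:
    """Integrate the batched ODE forward so states settle near attractors."""
    from scipy.integrate import solve_ivp
    shape = starts.shape

    def g(t, y):
        return f(y.reshape(shape)).ravel()

    sol = solve_ivp(g, (0.0, horizon), starts.ravel(), method="RK45",
                    rtol=1e-6, atol=1e-3)
    return sol.y[:, -1].reshape(shape) if sol.success else starts


def _dedup(roots: np.ndarray, scales: np.ndarray) -> list[np.ndarray]:
    uniq: list[np.ndarray] = []
    for i in range(roots.shape[1]):
        r = roots[:, i]
        if not any(np.max(np.abs(r - u) / scales) < DEDUP_RTOL for u in uniq):
            uniq.append(r)
    # deterministic order: ascending miR-200, then Zeb
    uniq.sort(key=lambda s: (s[IDX["u200"]], s[IDX["Z"]]))
    return uniq


def _classify_root(f, root: np.ndarray, scales: np.ndarray,
                   flux: np.ndarray) -> SteadyState:
    F = f(root[:, None])[:, 0]
    residual = float(np.max(np.abs(F) / flux))
    Jac = _batch_jacobian(f, root[:, None], scales)[0]
    eig = np.linalg.eigvals(Jac)
    lead = float(np.max(eig.real))
    marginal = abs(lead) <= STABILITY_MARGIN
    stable = lead < -STABILITY_MARGIN
    return SteadyState(state=root.copy(), stable=stable, marginal=marginal,
                       leading_eigenvalue=lead, residual=residual)


def attraction_test(ss: SteadyState, env: Environment, params: ModelParameters,
                    rel_perturbation: float = 0.01, horizon: float | None = None
                    ) -> bool:
    """Forward-integration check: does a 1% perturbation relax back?

    Returns True when the perturbed trajectory ends closer to the fixed
    point than it started (scaled max norm), the behaviour expected of a
    stable state.
    """
    scales = state_scales(params, env)
    x0 = ss.state * (1.0 + rel_perturbation)
    if horizon is None:
        rate = max(abs(ss.leading_eigenvalue), 1e-2)
        horizon = float(np.clip(10.0 / rate, 24.0, 400.0))
    sol = simulate_cell(x0, env, params, (0.0, horizon))
    d0 = np.max(np.abs(x0 - ss.state) / scales)
    d1 = np.max(np.abs(sol.y[:, -1] - ss.state) / scales)
    return d1 < max(0.3 * d0, 1e-7)


def find_steady_states(env: Environment, params: ModelParameters,
                       n_starts: int = 40, seed: int = 0,
                       extra_starts: np.ndarray | None = None,
                       run_attraction_test: bool = False) -> list[SteadyState]:
    """Locate steady states of the single-cell circuit at a fixed environment.

    Multi-start damped Newton from ``n_starts`` seeded random points in the
    physiological box (uniform on [0, 2 x production/degradation] per
    species), plus optional warm ``extra_starts`` (shape (11, k)).  Roots are
    de-duplicated at relative tolerance ``DEDUP_RTOL`` and classified by the
    Jacobian spectrum; optionally each stable root is re-verified by a
    forward-integration attraction test.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    scales = state_scales(params, env)
    flux = scales * _gammas(params)
    f = make_rhs(env, params)
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 2.0, size=(N_SPECIES, n_starts)) * scales[:, None]
    # include the origin-relaxed corner and the full-production corner
    starts = np.concatenate([starts, np.zeros((N_SPECIES, 1)),
                             scales[:, None]], axis=1)
    if extra_starts is not None and extra_starts.size:
        starts = np.concatenate([starts, extra_starts], axis=1)
    roots, stalled = _newton_polish(f, starts, scales, flux)
    if roots.shape[1] == 0 and stalled.shape[1]:
        # Newton alone found nothing: flow a few stalled points to their
        # attractors and polish from there (always finds the stable states)
        settled = _flow_to_attractors(f, stalled[:, :6])
        roots, _ = _newton_polish(f, settled, scales, flux)
    if roots.shape[1] == 0:
        warnings.warn("find_steady_states: no root converged", stacklevel=2)
        return []
    out = []
    for r in _dedup(roots, scales):
        ss = _classify_root(f, r, scales, flux)
        if ss.residual > RESIDUAL_TOL:
            continue
        if run_attraction_test and ss.stable and not attraction_test(ss, env, params):
            ss.stable = False
            ss.marginal = True
        out.append(ss)
    return out


def _with_control(env: Environment, control: str, value: float) -> Environment:
    if control not in CONTROLS:
        raise ValueError(f"control must be one of {CONTROLS}")
    return env.replace(**{control: float(value)})


def scan_bifurcation(control: str, range_: tuple[float, float],
                     n_points: int = 200, env_base: Environment | None = None,
                     params: ModelParameters | None = None,
                     n_starts: int = 24, seed: int = 0,
                     thresholds=None) -> BifurcationDiagram:
    """1-D bifurcation scan of the single-cell circuit over an external control.

    Sweeps ``control`` over a strictly increasing grid, warm-starting the
    multi-start Newton search from the previous grid point's roots, then
    links roots into branches by nearest-state continuation (ties broken by
    smallest miR-200 distance).  ``env_base`` defaults to the bifurcation
    baseline N_ext = 10000 with all other external signals zero.
    """
    lo, hi = float(range_[0]), float(range_[1])
    if not lo < hi:
        raise ValueError("scan_bifurcation: range must satisfy lo < hi")
    if n_points < 2:
        raise ValueError("scan_bifurcation: n_points must be >= 2")
    if params is None:
        raise ValueError("scan_bifurcation: params are required")
    if env_base is None:
        env_base = Environment(N_ext=10000.0)
    grid = np.linspace(lo, hi, n_points)
    roots_per_point: list[list[SteadyState]] = []
    warm: np.ndarray | None = None
    for i, v in enumerate(grid):
        env = _with_control(env_base, control, v)
        roots = find_steady_states(env, params, n_starts=n_starts,
                                   seed=seed + i, extra_starts=warm)
        roots_per_point.append(roots)
        warm = (np.stack([r.state for r in roots], axis=1)
                if roots else None)

    branches = _link_branches(grid, roots_per_point, params, env_base)
    diagram = BifurcationDiagram(control=control, grid=grid,
                                 roots=roots_per_point, branches=branches,
                                 env_base=env_base, params=params)
    if thresholds is not None:
        diagram.label_phenotypes(thresholds)
    return diagram


def _link_branches(grid, roots_per_point, params, env_base) -> list[Branch]:
    scales = state_scales(params, env_base)
    # generous continuity bound: branches jump at folds, not along them
    bound = 0.25
    open_branches: list[Branch] = []
    finished: list[Branch] = []
    for gi, roots in enumerate(roots_per_point):
        unmatched = list(range(len(roots)))
        next_open: list[Branch] = []
        # candidate matches sorted by distance; tie-break on miR-200 distance
        cands = []
        for bi, br in enumerate(open_branches):
            prev = br.states[-1].state
            for ri in unmatched:
                d = np.max(np.abs(roots[ri].state - prev) / scales)
                du = abs(roots[ri].state[IDX["u200"]] - prev[IDX["u200"]])
                if d < bound:
                    cands.append((d, du, bi, ri))
        used_b, used_r = set(), set()
        for d, du, bi, ri in sorted(cands, key=lambda c: (round(c[0], 12), c[1])):
            if bi in used_b or ri in used_r:
                continue
            used_b.add(bi); used_r.add(ri)
            open_branches[bi].grid_indices.append(gi)
            open_branches[bi].states.append(roots[ri])
        for bi, br in enumerate(open_branches):
            (next_open if bi in used_b else finished).append(br)
        for ri in range(len(roots)):
            if ri not in used_r:
                next_open.append(Branch(grid_indices=[gi], states=[roots[ri]]))
        open_branches = next_open
    finished.extend(open_branches)
    finished.sort(key=lambda b: (b.grid_indices[0],
                                 b.states[0].state[IDX["u200"]]))
    return finished


@dataclass
class StabilityInterval:
    """Control-value extent of the stable portion of one phenotype's branches."""

    phenotype: str
    lo: float | None
    hi: float | None

    @property
    def empty(self) -> bool:
        return self.lo is None

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.hi - self.lo


def stability_interval(diagram: BifurcationDiagram, phenotype: str,
                       refine: bool = False, refine_tol: float | None = None
                       ) -> StabilityInterval:
    """Extent of the control range where a stable state of ``phenotype`` exists.

    Requires the diagram's branches to be phenotype-labelled.  With
    ``refine=True`` the endpoints are sharpened by bisection between grid
    points (to ``refine_tol`` control units, default 1e-3 of the scan range).
    """
    if all(br.phenotype is None for br in diagram.branches):
        raise ValueError("stability_interval: diagram branches are unlabelled; "
                         "call label_phenotypes first")
    vals = []
    for br in diagram.branches:
        if br.phenotype != phenotype:
            continue
        for gi, st in zip(br.grid_indices, br.states):
            if st.stable:
                vals.append(float(diagram.grid[gi]))
    if not vals:
        return StabilityInterval(phenotype, None, None)
    lo, hi = min(vals), max(vals)
    if refine:
        span = float(diagram.grid[-1] - diagram.grid[0])
        tol = refine_tol if refine_tol is not None else 1e-3 * span
        step = float(diagram.grid[1] - diagram.grid[0])
        from .metrics import classify_phenotype  # lazy: avoids import cycle
        thresholds = _diagram_thresholds(diagram)

        def has_pheno(v):
            env = _with_control(diagram.env_base, diagram.control, max(v, 0.0))
            roots = find_steady_states(env, diagram.params, n_starts=24, seed=17)
            return any(st.stable and
                       classify_phenotype(st.state, thresholds)[0] == phenotype
                       for st in roots)

        lo = _refine_boundary(lo, lo - step, has_pheno, tol)
        hi = _refine_boundary(hi, hi + step, has_pheno, tol)
        lo = max(lo, float(diagram.grid[0]))
        hi = min(hi, float(diagram.grid[-1]))
    return StabilityInterval(phenotype, lo, hi)


def _diagram_thresholds(diagram: BifurcationDiagram):
    from .metrics import thresholds_from_labelled_diagram
    return thresholds_from_labelled_diagram(diagram)


def _refine_boundary(t_true, t_false, predicate, tol):
    """Bisect between a control value inside the branch and one outside."""
    t_false = max(t_false, 0.0)
    if predicate(t_false):  # branch extends past the neighbouring grid step
        return t_false
    while abs(t_true - t_false) > tol:
        m = 0.5 * (t_true + t_false)
        if predicate(m):
            t_true = m
        else:
            t_false = m
    return t_true
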
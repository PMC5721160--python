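"""Single-cell Notch-EMT-Numb circuit: regulatory functions and ODE right-hand side.

The circuit couples three units (all species continuous molecule counts):

* Notch signalling — receptor N, ligands Delta D and Jagged J, and NICD I.
  Receptor and ligands are lost to cis-inhibition within the cell (rate
  ``k_C``) and to trans-interactions with ligands/receptors presented by the
  environment (rate ``k_T``); productive trans-activation of N releases NICD.
  NICD transcriptionally activates N and J and represses D (lateral
  induction vs inhibition asymmetry).
* EMT regulatory core — the mutually inhibitory miR-34/Snail and
  miR-200/Zeb axes. NICD and an external inducer (I_ext, e.g. TGF-beta)
  activate Snail transcription; Snail activates Zeb; Zeb self-activates.
  The microRNAs silence their target mRNAs combinatorially and additionally
  silence the Notch-module proteins at the translation level (miR-34: N, D;
  miR-200: J).
* Numb — transcriptionally repressed by NICD, Numb attenuates NICD release
  by a multiplicative inhibitory shifted-Hill factor, closing a mutual
  inhibition that brakes Notch-driven EMT.  Optionally miR-34 weakly
  silences Numb.

All rate expressions broadcast over trailing array dimensions, so the same
code evaluates one cell or a whole lattice of cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParameters, ParameterError

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "Environment",
    "shifted_hill",
    "mirna_silencing_factors",
    "single_cell_rhs",
    "rhs",
    "simulate_cell",
]

#: Canonical species order used by every state vector in the package.
SPECIES = ("N", "D", "J", "I", "P", "u34", "mS", "S", "u200", "mZ", "Z")
N_SPECIES = len(SPECIES)
IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class Environment:
    """External signals seen by one cell.

    ``N_ext``/``D_ext``/``J_ext`` are membrane receptor/ligand levels
    presented by neighbours; ``sD_ext``/``sJ_ext`` are soluble ligands that
    trans-activate identically but are never consumed and exert no reverse
    signal; ``I_ext`` is a uniform external EMT-inducer level.
    """

    N_ext: float = 0.0
    D_ext: float = 0.0
    J_ext: float = 0.0
    sD_ext: float = 0.0
    sJ_ext: float = 0.0
    I_ext: float = 0.0

    def __post_init__(self):
        for name in ("N_ext", "D_ext", "J_ext", "sD_ext", "sJ_ext", "I_ext"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"Environment.{name} must be >= 0")

    def replace(self, **kw) -> "Environment":
        import dataclasses
        return dataclasses.replace(self, **kw)


def shifted_hill(X, X0: float, n: int, lam: float):
    """Shifted Hill factor H(X) = (1 + lam (X/X0)^n) / (1 + (X/X0)^n).

    Bounded between min(1, lam) and max(1, lam); equals 1 at X = 0 and
    tends to ``lam`` as X grows, so ``lam`` > 1 encodes activation and
    ``lam`` < 1 repression of a basal rate.
    """
    if X0 <= 0:
        raise ValueError("shifted_hill: threshold X0 must be > 0")
    if n < 1:
        raise ValueError("shifted_hill: Hill coefficient n must be >= 1")
    if lam <= 0:
        raise ValueError("shifted_hill: fold-change lambda must be > 0")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("shifted_hill: regulator level must be >= 0")
    xn = (X / X0) ** n
    out = (1.0 + lam * xn) / (1.0 + xn)
    return out if out.ndim else float(out)


@lru_cache(maxsize=16)
def _binom_table(n_sites: int) -> np.ndarray:
    return np.array([comb(n_sites, i) for i in range(n_sites + 1)], dtype=float)


def _occupancies(mu, mu0: float, n_sites: int):
    """Binomial occupancy distribution over microRNA binding sites.

    Each of ``n_sites`` sites is bound independently with probability
    p = (mu/mu0) / (1 + mu/mu0); returns array M with M[i] = P(i bound),
    stacked along the first axis.
    """
    mu = np.asarray(mu, dtype=float)
    p = (mu / mu0) / (1.0 + mu / mu0)
    q = 1.0 - p
    c = _binom_table(n_sites)
    pows_p = np.stack([p**i for i in range(n_sites + 1)])
    pows_q = np.stack([q ** (n_sites - i) for i in range(n_sites + 1)])
    return c.reshape((-1,) + (1,) * p.ndim) * pows_p * pows_q


def mirna_silencing_factors(mu, mu0: float, l_w, gm_w=None, gu_w=None):
    """Per-occupancy-weighted silencing factors for one microRNA-mRNA pair.

    Returns ``(L, Ym, Yu)``: translation factor L = sum_i l_i M_i(mu)
    (dimensionless, 1 at mu = 0, non-increasing in mu), active mRNA
    degradation Ym = sum_i gm_i M_i (1/h) and microRNA consumption
    Yu = sum_i i gu_i M_i (1/h per mRNA; each degradation event with i
    bound microRNAs consumes them).  ``gm_w``/``gu_w`` default to zero
    (translation-level silencing only).
    """
    l_w = np.asarray(l_w, dtype=float)
    n_sites = len(l_w) - 1
    for name, w in (("gm", gm_w), ("gu", gu_w)):
        if w is not None and len(np.asarray(w)) != n_sites + 1:
            raise ParameterError(
                f"mirna_silencing_factors: {name} weights must have length n_sites+1")
    M = _occupancies(mu, mu0, n_sites)
    L = np.tensordot(l_w, M, axes=(0, 0))
    if gm_w is None:
        Ym = np.zeros_like(L)
    else:
        Ym = np.tensordot(np.asarray(gm_w, dtype=float), M, axes=(0, 0))
    if gu_w is None:
        Yu = np.zeros_like(L)
    else:
        gu_w = np.asarray(gu_w, dtype=float)
        Yu = np.tensordot(gu_w * np.arange(n_sites + 1), M, axes=(0, 0))
    if L.ndim:
        return L, Ym, Yu
    return float(L), float(Ym), float(Yu)


def rhs(y, env: Environment, p: ModelParameters):
    """Time derivative of the circuit state.

    ``y`` has shape ``(11, ...)`` in :data:`SPECIES` order; ``env`` fields
    may be scalars or arrays broadcastable to the trailing shape.  Returns
    an array of the same shape (molecules/h).
    """
    y = np.asarray(y, dtype=float)
    # negative excursions from integrator round-off are treated as zero in
    # the regulatory functions; the linear decay terms self-correct them
    yc = np.maximum(y, 0.0)
    N, D, J, I, P, u34, mS, S, u200, mZ, Z = yc

    L_ext = env.D_ext + env.sD_ext + env.J_ext + env.sJ_ext

    L34_N, _, _ = mirna_silencing_factors(u34, p.mu0_34, p.l_34_N)
    L34_D, _, _ = mirna_silencing_factors(u34, p.mu0_34, p.l_34_D)
    L200_J, _, _ = mirna_silencing_factors(u200, p.mu0_200, p.l_200_J)
    L34_mS, Ym34, Yu34 = mirna_silencing_factors(
        u34, p.mu0_34, p.l_34_mS, p.gm_34_mS, p.gu_34_mS)
    L200_mZ, Ym200, Yu200 = mirna_silencing_factors(
        u200, p.mu0_200, p.l_200_mZ, p.gm_200_mZ, p.gu_200_mZ)

    # Notch module
    dN = (p.g_N * shifted_hill(I, p.I0_N, p.n_I_N, p.lam_I_N) * L34_N
          - N * (p.k_C * (D + J) + p.k_T * L_ext) - p.gamma_N * N)
    dD = (p.g_D * shifted_hill(I, p.I0_D, p.n_I_D, p.lam_I_D) * L34_D
          - D * (p.k_C * N + p.k_T * env.N_ext) - p.gamma_D * D)
    dJ = (p.g_J * shifted_hill(I, p.I0_J, p.n_I_J, p.lam_I_J) * L200_J
          - J * (p.k_C * N + p.k_T * env.N_ext) - p.gamma_J * J)
    if p.numb_enabled:
        numb_factor = shifted_hill(P, p.P0_I, p.n_P_I, p.lam_P_I)
    else:
        numb_factor = 1.0
    dI = p.k_T * N * L_ext * numb_factor - p.gamma_I * I

    # Numb module (decoupled from everything else when numb_enabled is off)
    L34_P = 1.0
    if p.mir34_numb_enabled:
        L34_P, _, _ = mirna_silencing_factors(u34, p.mu0_34, p.l_34_P)
    dP = (p.g_P * shifted_hill(I, p.I0_P, p.n_I_P, p.lam_I_P) * L34_P
          - p.gamma_P * P)

    # EMT core
    du34 = (p.g_u34 * shifted_hill(S, p.S0_u34, p.n_S_u34, p.lam_S_u34)
            * shifted_hill(Z, p.Z0_u34, p.n_Z_u34, p.lam_Z_u34)
            - mS * Yu34 - p.gamma_u34 * u34)
    dmS = (p.g_mS * shifted_hill(S, p.S0_mS, p.n_S_mS, p.lam_S_mS)
           * shifted_hill(I, p.I0_mS, p.n_I_mS, p.lam_I_mS)
           * shifted_hill(env.I_ext, p.Iext0_mS, p.n_Iext_mS, p.lam_Iext_mS)
           - mS * Ym34 - p.gamma_mS * mS)
    dS = p.g_S * mS * L34_mS - p.gamma_S * S
    du200 = (p.g_u200 * shifted_hill(S, p.S0_u200, p.n_S_u200, p.lam_S_u200)
             * shifted_hill(Z, p.Z0_u200, p.n_Z_u200, p.lam_Z_u200)
             - mZ * Yu200 - p.gamma_u200 * u200)
    dmZ = (p.g_mZ * shifted_hill(S, p.S0_mZ, p.n_S_mZ, p.lam_S_mZ)
           * shifted_hill(Z, p.Z0_mZ, p.n_Z_mZ, p.lam_Z_mZ)
           - mZ * Ym200 - p.gamma_mZ * mZ)
    dZ = p.g_Z * mZ * L200_mZ - p.gamma_Z * Z

    out = np.broadcast_arrays(dN, dD, dJ, dI, dP, du34, dmS, dS, du200, dmZ, dZ)
    return np.stack(out)


def single_cell_rhs(state, env: Environment, params: ModelParameters, t: float = 0.0):
    """RHS for a single cell (length-11 vector in, length-11 vector out)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("single_cell_rhs: non-finite state")
    return rhs(state, env, params)


def simulate_cell(state0, env: Environment, params: ModelParameters,
                  t_span, t_eval=None, rtol: float = 1e-6, atol: float = 1e-3):
    """Integrate one cell under a fixed environment.

    Returns the scipy ``OdeResult`` (``sol.y`` has shape (11, n_times)).
    """
    state0 = np.asarray(state0, dtype=float)

    def f(t, y):
        return rhs(y, env, params)

    sol = solve_ivp(f, t_span, state0, t_eval=t_eval, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"single-cell integration failed: {sol.message}")
    return sol
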
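"""Model parameters for the Notch-Delta-Jagged / EMT / Numb circuit.

Parameters are held in a flat :class:`ModelParameters` dataclass whose field
names follow the field's conventional symbols: ``g_X`` basal production
(molecules/h), ``gamma_X`` first-order degradation (1/h), ``k_T``/``k_C``
trans-activation and cis-inhibition rate constants (1/molecule/h), and per
regulatory link a shifted-Hill triple ``(X0, n, lambda)`` named
``<source>0_<target>``, ``n_<source>_<target>``, ``lam_<source>_<target>``.
MicroRNA silencing of a transcript is described by a threshold ``mu0``, a
binding-site count and per-occupancy weight vectors (translation ``l``,
mRNA degradation ``gm``, microRNA consumption ``gu``), each of length
``n_sites + 1``.

Defaults ship in ``data/default_params.txt`` (a flat key = value file) and
are loaded lazily; :func:`default_params` returns a fresh copy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "ModelParameters",
    "ParameterError",
    "default_params",
    "load_params",
    "save_params",
]


class ParameterError(ValueError):
    """Raised for invalid or inconsistent model parameters."""


def _vec(*xs: float) -> tuple[float, ...]:
    return tuple(float(x) for x in xs)


@dataclass
class ModelParameters:
    """All rate constants, Hill parameters and toggles of one circuit instance.

    Species (molecules, continuous): Notch receptor N, Delta D, Jagged J,
    NICD I, Numb P, miR-34 u34, Snail mRNA mS, Snail protein S, miR-200 u200,
    Zeb mRNA mZ, Zeb protein Z.
    """

    # --- production rates (molecules / h) ---
    g_N: float = 0.0
    g_D: float = 0.0
    g_J: float = 0.0
    g_P: float = 0.0
    g_u34: float = 0.0
    g_mS: float = 0.0
    g_S: float = 0.0       # protein per mRNA per h
    g_u200: float = 0.0
    g_mZ: float = 0.0
    g_Z: float = 0.0       # protein per mRNA per h

    # --- degradation rates (1 / h) ---
    gamma_N: float = 0.1
    gamma_D: float = 0.1
    gamma_J: float = 0.1
    gamma_I: float = 0.5
    gamma_P: float = 0.1
    gamma_u34: float = 0.05
    gamma_mS: float = 0.5
    gamma_S: float = 0.125
    gamma_u200: float = 0.05
    gamma_mZ: float = 0.5
    gamma_Z: float = 0.1

    # --- receptor-ligand interaction (1 / molecule / h) ---
    k_T: float = 2.5e-5
    k_C: float = 1e-4

    # --- shifted-Hill links: threshold (molecules), coefficient, fold-change ---
    # NICD on the Notch module
    I0_N: float = 200.0
    n_I_N: int = 2
    lam_I_N: float = 2.0
    I0_D: float = 200.0
    n_I_D: int = 2
    lam_I_D: float = 0.02
    I0_J: float = 200.0
    n_I_J: int = 2
    lam_I_J: float = 2.0
    # NICD -> Snail transcription
    I0_mS: float = 300.0
    n_I_mS: int = 2
    lam_I_mS: float = 8.0
    # external EMT inducer -> Snail transcription
    Iext0_mS: float = 50000.0
    n_Iext_mS: int = 1
    lam_Iext_mS: float = 10.0
    # Snail self-repression
    S0_mS: float = 200000.0
    n_S_mS: int = 1
    lam_S_mS: float = 0.1
    # EMT-core mutual inhibitions / activations
    S0_u34: float = 300000.0
    n_S_u34: int = 4
    lam_S_u34: float = 0.1
    Z0_u34: float = 600000.0
    n_Z_u34: int = 2
    lam_Z_u34: float = 0.2
    S0_u200: float = 180000.0
    n_S_u200: int = 2
    lam_S_u200: float = 0.1
    Z0_u200: float = 220000.0
    n_Z_u200: int = 3
    lam_Z_u200: float = 0.1
    S0_mZ: float = 180000.0
    n_S_mZ: int = 2
    lam_S_mZ: float = 10.0
    Z0_mZ: float = 25000.0
    n_Z_mZ: int = 2
    lam_Z_mZ: float = 7.5
    # Numb module: NICD -| Numb transcription, Numb -| NICD release
    I0_P: float = 300.0
    n_I_P: int = 2
    lam_I_P: float = 0.1
    P0_I: float = 1000.0
    n_P_I: int = 2
    lam_P_I: float = 0.3

    # --- microRNA silencing blocks ---
    # miR-34 and miR-200 thresholds (molecules)
    mu0_34: float = 10000.0
    mu0_200: float = 10000.0
    # miR-34 on Snail mRNA (2 sites): translation / mRNA-deg / miR-consumption
    l_34_mS: tuple[float, ...] = field(default_factory=lambda: _vec(1, 0.6, 0.3))
    gm_34_mS: tuple[float, ...] = field(default_factory=lambda: _vec(0, 0.04, 0.2))
    gu_34_mS: tuple[float, ...] = field(default_factory=lambda: _vec(0, 0.005, 0.05))
    # miR-200 on Zeb mRNA (6 sites)
    l_200_mZ: tuple[float, ...] = field(
        default_factory=lambda: _vec(1, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05))
    gm_200_mZ: tuple[float, ...] = field(
        default_factory=lambda: _vec(0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0))
    gu_200_mZ: tuple[float, ...] = field(
        default_factory=lambda: _vec(0, 0.005, 0.05, 0.5, 0.5, 0.5, 0.5))
    # translation-level silencing of the Notch module (no separate mRNA species)
    l_34_N: tuple[float, ...] = field(default_factory=lambda: _vec(1, 0.6, 0.3))
    l_34_D: tuple[float, ...] = field(default_factory=lambda: _vec(1, 0.6, 0.3))
    l_200_J: tuple[float, ...] = field(default_factory=lambda: _vec(1, 0.6, 0.3))
    # weak post-translational silencing of Numb by miR-34 (1 site)
    l_34_P: tuple[float, ...] = field(default_factory=lambda: _vec(1, 0.8))

    # --- feature toggles ---
    numb_enabled: bool = True
    mir34_numb_enabled: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # tuple-ify list inputs so instances hash/compare predictably
    def __setattr__(self, name: str, value) -> None:
        if name.startswith(("l_", "gm_", "gu_")) and not isinstance(value, tuple):
            value = tuple(float(v) for v in value)
        object.__setattr__(self, name, value)

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("numb_enabled", "mir34_numb_enabled"):
                if not isinstance(v, bool):
                    raise ParameterError(f"{f.name} must be boolean")
            elif f.name.startswith(("l_", "gm_", "gu_")):
                if any(w < 0 for w in v):
                    raise ParameterError(f"{f.name}: weights must be >= 0")
            elif f.name.startswith("n_"):
                if v < 1 or int(v) != v:
                    raise ParameterError(f"{f.name}: Hill coefficient must be integer >= 1")
            elif f.name.startswith("lam_"):
                if v <= 0:
                    raise ParameterError(f"{f.name}: fold-change must be > 0")
            elif f.name.startswith(("gamma_", "mu0_")) or f.name.endswith(("0_N",)) or "0_" in f.name:
                if v <= 0:
                    raise ParameterError(f"{f.name}: must be > 0")
            else:  # production rates and k_T/k_C
                if v < 0:
                    raise ParameterError(f"{f.name}: must be >= 0")
        # translation weights non-increasing in occupancy; paired vector lengths
        for name in ("l_34_mS", "l_200_mZ", "l_34_N", "l_34_D", "l_200_J", "l_34_P"):
            l = getattr(self, name)
            if any(b > a for a, b in zip(l, l[1:])):
                raise ParameterError(f"{name}: translation weights must be non-increasing")
            if l[0] != 1.0:
                raise ParameterError(f"{name}: zero-occupancy translation weight must be 1")
        for a, b in (("l_34_mS", "gm_34_mS"), ("l_34_mS", "gu_34_mS"),
                     ("l_200_mZ", "gm_200_mZ"), ("l_200_mZ", "gu_200_mZ")):
            if len(getattr(self, a)) != len(getattr(self, b)):
                raise ParameterError(f"{a} and {b} must have equal length")

    def replace(self, **kw) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_FIELD_NAMES = {f.name for f in fields(ModelParameters)}


def _parse_value(name: str, raw: str):
    raw = raw.strip()
    if name in ("numb_enabled", "mir34_numb_enabled"):
        if raw.lower() in ("true", "on", "1", "yes"):
            return True
        if raw.lower() in ("false", "off", "0", "no"):
            return False
        raise ParameterError(f"{name}: cannot parse boolean from {raw!r}")
    if name.startswith(("l_", "gm_", "gu_")):
        return tuple(float(v) for v in raw.split(","))
    if name.startswith("n_"):
        return int(raw)
    return float(raw)


def load_params(path: str | Path) -> ModelParameters:
    """Read a flat ``key = value`` parameter file (``#`` starts a comment)."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_NAMES:
            raise ParameterError(f"{path}:{lineno}: unknown parameter {key!r}")
        values[key] = _parse_value(key, raw)
    return ModelParameters(**values)


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter file that :func:`load_params` reads back exactly."""
    lines = ["# notchemt model parameters (molecules, hours)"]
    for f in fields(ModelParameters):
        v = getattr(params, f.name)
        if isinstance(v, tuple):
            lines.append(f"{f.name} = {', '.join(repr(x) for x in v)}")
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {'true' if v else 'false'}")
        else:
            lines.append(f"{f.name} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_params(**overrides) -> ModelParameters:
    """The shipped default parameter set, optionally with field overrides."""
    ref = resources.files("notchemt.data").joinpath("default_params.txt")
    with resources.as_file(ref) as p:
        params = load_params(p)
    return params.replace(**overrides) if overrides else params
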
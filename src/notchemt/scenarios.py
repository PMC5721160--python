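"""Scenario orchestration: reproducible, manifest-stamped runs.

A :class:`Scenario` bundles a parameter source, toggles, a lattice
configuration, the requested analyses and a seed; :func:`run_scenario`
executes the stages in dependency order and writes tidy CSV/JSON outputs,
each stamped with the scenario hash, seed and package version so any
output file can be traced to an exact configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import (LatticeConfig, hybrid_initial_lattice, integrate_lattice,
                      random_initial_lattice)
from .metrics import (calibrate_thresholds, classify_lattice, cluster_census,
                      composition, hybrid_colocalization,
                      threshold_robustness)
from .params import ModelParameters, default_params, load_params, save_params
from .steady_state import scan_bifurcation, stability_interval

log = logging.getLogger("notchemt")

__all__ = ["Scenario", "ScenarioError", "run_scenario", "make_fixtures"]

_ANALYSES = ("bifurcation", "composition", "colocalization", "clusters",
             "sensitivity")


class ScenarioError(ValueError):
    """Raised when a scenario fails schema validation."""


@dataclass
class Scenario:
    """A fully-specified, hashable unit of work."""

    name: str
    params_file: str | None = None          # None -> shipped defaults
    overrides: dict = field(default_factory=dict)
    numb: bool = True
    mir34_numb: bool | None = None          # None -> parameter-file value
    lattice: dict | None = None             # LatticeConfig kwargs
    init: str = "random"                    # random | hybrid
    analyses: tuple[str, ...] = ()
    bifurcation: dict = field(default_factory=dict)  # control, range, n_points
    sensitivity: dict = field(default_factory=dict)  # delta, parameters, ...
    seed: int = 0
    outdir: str = "out"

    def validate(self) -> None:
        bad = [a for a in self.analyses if a not in _ANALYSES]
        if bad:
            raise ScenarioError(f"unknown analyses: {bad}; valid: {_ANALYSES}")
        needs_lattice = {"composition", "colocalization", "clusters"}
        if needs_lattice & set(self.analyses) and self.lattice is None:
            raise ScenarioError(
                f"analyses {sorted(needs_lattice & set(self.analyses))} "
                "require a lattice stage but no lattice config is given")
        if self.init not in ("random", "hybrid"):
            raise ScenarioError("init must be 'random' or 'hybrid'")
        if self.lattice is not None:
            LatticeConfig(**self.lattice)   # raises on bad keys/values

    def resolved_params(self) -> ModelParameters:
        p = (load_params(self.params_file) if self.params_file
             else default_params())
        if self.overrides:
            p = p.replace(**self.overrides)
        toggles = {"numb_enabled": self.numb}
        if self.mir34_numb is not None:
            toggles["mir34_numb_enabled"] = self.mir34_numb
        return p.replace(**toggles)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)   # output location is not content
        return hashlib.sha1(json.dumps(payload, sort_keys=True,
                                       default=str).encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "Scenario":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
        if "analyses" in data:
            data["analyses"] = tuple(data["analyses"])
        return cls(**data)


def _stamp(scenario: Scenario) -> dict:
    from . import __version__
    return {"scenario": scenario.name, "scenario_hash": scenario.hash(),
            "seed": scenario.seed, "package_version": __version__}


def run_scenario(scenario: Scenario) -> dict:
    """Execute a scenario; returns (and writes) the output manifest."""
    scenario.validate()
    t_start = time.time()
    outdir = Path(scenario.outdir) / scenario.name
    outdir.mkdir(parents=True, exist_ok=True)
    params = scenario.resolved_params()
    stamp = _stamp(scenario)
    manifest = dict(stamp)
    manifest["stages"] = {}

    def _done(stage, **info):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2),
                                     **info}
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    thresholds = None
    if set(scenario.analyses) & {"composition", "colocalization", "clusters",
                                 "bifurcation", "sensitivity"} or scenario.lattice:
        t0 = time.time()
        thresholds = calibrate_thresholds(params, seed=scenario.seed)
        (outdir / "thresholds.json").write_text(json.dumps(
            {**stamp, "t_low": thresholds.t_low, "t_high": thresholds.t_high,
             "N_cut": thresholds.N_cut, "D_cut": thresholds.D_cut,
             "J_cut": thresholds.J_cut, "calibration": thresholds.meta},
            indent=2))
        _done("calibration")

    if "bifurcation" in scenario.analyses:
        t0 = time.time()
        control = scenario.bifurcation.get("control", "J_ext")
        rng = tuple(scenario.bifurcation.get("range", (0.0, 3000.0)))
        n_points = int(scenario.bifurcation.get("n_points", 200))
        diagram = scan_bifurcation(control, rng, n_points=n_points,
                                   params=params, seed=scenario.seed,
                                   thresholds=thresholds)
        df = diagram.to_frame()
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(outdir / f"bifurcation_{control}.csv", index=False)
        intervals = {ph: dataclasses.asdict(stability_interval(diagram, ph))
                     for ph in ("E", "E/M", "M")}
        (outdir / f"intervals_{control}.json").write_text(
            json.dumps({**stamp, "intervals": intervals}, indent=2))
        _done("bifurcation", control=control, n_points=n_points)

    pmaps = None
    if scenario.lattice is not None:
        t0 = time.time()
        cfg = LatticeConfig(**{**scenario.lattice, "seed": scenario.seed})
        snaps_last, pmaps, rows = [], [], []
        for rep in range(cfg.replicates):
            if scenario.init == "hybrid":
                init = hybrid_initial_lattice(cfg, params, thresholds,
                                              seed=scenario.seed + rep)
            else:
                init = random_initial_lattice(cfg, params, replicate=rep)
            snaps = integrate_lattice(init, cfg, params)
            snaps_last.append(snaps[-1])
            pm = classify_lattice(snaps[-1].grid, thresholds,
                                  meta={"replicate": rep, **stamp})
            pmaps.append(pm)
            for s in snaps:
                d = s.to_frame()
                d.insert(0, "replicate", rep)
                rows.append(d)
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "lattice_snapshots.csv", index=False)
        np.savetxt(outdir / "phenotype_map_rep0.txt",
                   pmaps[0].codes(), fmt="%d")
        _done("lattice", replicates=cfg.replicates,
              shape=[cfg.rows, cfg.cols], config_hash=cfg.hash())

    if "composition" in scenario.analyses:
        t0 = time.time()
        summ = composition(pmaps, meta=stamp)
        recs = [{"replicate": i, "f_E": f[0], "f_EM": f[1], "f_M": f[2]}
                for i, f in enumerate(summ.fractions)]
        df = pd.DataFrame(recs)
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(outdir / "composition.csv", index=False)
        robustness = max(threshold_robustness(s.grid, thresholds)
                         for s in snaps_last)
        (outdir / "composition_summary.json").write_text(
            json.dumps({**stamp, **summ.as_dict(),
                        "threshold_robustness": robustness}, indent=2))
        _done("composition")

    if "colocalization" in scenario.analyses:
        t0 = time.time()
        recs = []
        for i, pm in enumerate(pmaps):
            col = hybrid_colocalization(pm)
            recs.append({"replicate": i, "mean": col.mean,
                         "n_hybrid": col.n_hybrid,
                         **{f"hist_{k}": int(v)
                            for k, v in enumerate(col.histogram)}})
        df = pd.DataFrame(recs)
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(outdir / "colocalization.csv", index=False)
        _done("colocalization")

    if "clusters" in scenario.analyses:
        t0 = time.time()
        recs = []
        for i, pm in enumerate(pmaps):
            for target in (("E/M",), ("E/M", "M"), ("M",)):
                cen = cluster_census(pm, target)
                recs.append({"replicate": i, "target": "+".join(target),
                             "n_clusters": cen.n_clusters,
                             "largest": int(cen.sizes[0]) if cen.n_clusters else 0,
                             "total_cells": cen.total_cells})
        df = pd.DataFrame(recs)
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(outdir / "clusters.csv", index=False)
        _done("clusters")

    if "sensitivity" in scenario.analyses:
        t0 = time.time()
        from .sensitivity import interval_sensitivity
        rep = interval_sensitivity(params, thresholds=thresholds,
                                   seed=scenario.seed, **scenario.sensitivity)
        df = rep.ranked()
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(outdir / "sensitivity.csv", index=False)
        _done("sensitivity", baseline_width=rep.baseline_width)

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# deterministic test fixtures

#: hand-placed 5x5 phenotype map: two L-shaped E/M patches (sizes 4 and 3)
FIXTURE_MAP_5X5 = np.array([
    [1, 1, 0, 0, 0],
    [1, 0, 0, 2, 0],
    [1, 0, 0, 0, 0],
    [0, 0, 0, 1, 1],
    [0, 0, 0, 1, 0],
])


def decay_only_params(**overrides) -> ModelParameters:
    """A regulation-free circuit: every species relaxes to g/gamma.

    All fold-changes are 1, microRNA silencing is inert and the
    receptor-ligand interaction rates are zero, so each species obeys
    dX/dt = g - gamma*X with the closed-form solution
    X(t) = g/gamma + (X0 - g/gamma) exp(-gamma t).
    """
    p = default_params()
    flat = {f: 1.0 for f in p.to_dict() if f.startswith("lam_")}
    flat.update(k_T=0.0, k_C=0.0,
                l_34_mS=(1.0, 1.0, 1.0), gm_34_mS=(0.0, 0.0, 0.0),
                gu_34_mS=(0.0, 0.0, 0.0),
                l_200_mZ=(1.0,) * 7, gm_200_mZ=(0.0,) * 7,
                gu_200_mZ=(0.0,) * 7,
                l_34_N=(1.0, 1.0, 1.0), l_34_D=(1.0, 1.0, 1.0),
                l_200_J=(1.0, 1.0, 1.0, 1.0), l_34_P=(1.0, 1.0))
    flat.update(overrides)
    return p.replace(**flat)


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict:
    """Write small deterministic fixtures; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    decay = decay_only_params()
    paths["decay_params"] = outdir / "decay_only_params.txt"
    save_params(decay, paths["decay_params"])

    paths["label_map"] = outdir / "label_map_5x5.txt"
    np.savetxt(paths["label_map"], FIXTURE_MAP_5X5, fmt="%d")

    scenarios = [
        Scenario(name=f"scan_{control}_numb_{'on' if numb else 'off'}",
                 numb=numb, analyses=("bifurcation",),
                 bifurcation={"control": control, "range": [0.0, 3000.0],
                              "n_points": 60},
                 seed=seed, outdir="runs")
        for control in ("J_ext", "D_ext") for numb in (True, False)
    ] + [
        Scenario(name="jagged_high_small",
                 lattice=dict(rows=10, cols=10, g_J=80.0, g_D=20.0,
                              duration=24.0, replicates=2),
                 analyses=("composition",), seed=seed, outdir="runs"),
        Scenario(name="delta_small",
                 lattice=dict(rows=10, cols=10, g_J=20.0, g_D=200.0,
                              duration=24.0, replicates=2),
                 analyses=("composition",), seed=seed, outdir="runs"),
    ]
    for sc in scenarios:
        paths[sc.name] = outdir / f"scenario_{sc.name}.json"
        paths[sc.name].write_text(json.dumps(sc.to_dict(), indent=2))

    return {k: str(v) for k, v in paths.items()}
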
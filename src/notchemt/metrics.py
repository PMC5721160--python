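"""Phenotype classification and population / spatial statistics.

EMT phenotypes (E, hybrid E/M, M) are read off the miR-200 level of a cell
against two cut points calibrated once per parameter set from a Numb-off
single-cell bifurcation scan: at the centre of the tristable window the
three stable branches' miR-200 levels anchor the midpoint thresholds.  The
same thresholds are reused across Numb-on/off comparisons so composition
changes reflect the circuit, not the ruler.  Signalling labels
(sender / receiver / hybrid S-R) are computed from receptor and ligand
levels against geometric-mean cut points from the same scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .circuit import IDX, Environment
from .params import ModelParameters

__all__ = [
    "PhenotypeThresholds",
    "PhenotypeMap",
    "CompositionSummary",
    "ColocalizationSummary",
    "ClusterCensus",
    "calibrate_thresholds",
    "classify_phenotype",
    "classify_lattice",
    "composition",
    "hybrid_colocalization",
    "threshold_robustness",
    "cluster_census",
]

EMT_LABELS = ("E", "E/M", "M")
EMT_CODES = {"E": 0, "E/M": 1, "M": 2}


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Cut points (molecules) for phenotype classification.

    ``t_low < t_high`` split the miR-200 axis into M / E-M / E; the
    receptor/ligand cuts split signalling states.  ``meta`` records the
    calibration provenance so comparisons can assert they share a ruler.
    """

    t_low: float
    t_high: float
    N_cut: float
    D_cut: float
    J_cut: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0 <= self.t_low < self.t_high):
            raise ValueError("thresholds must satisfy 0 <= t_low < t_high")


def classify_phenotype(state, thresholds: PhenotypeThresholds) -> tuple[str, str]:
    """EMT and signalling label of one cell state.

    E if miR-200 >= t_high, M if miR-200 <= t_low, hybrid E/M between.
    Sender/receiver from receptor (N) vs ligand (D, J) levels: both above
    their cuts -> S/R, ligand only -> S, receptor only -> R; with neither
    above, the relatively closer axis wins (deterministic fallback).
    """
    state = np.asarray(state, dtype=float)
    u200 = state[IDX["u200"]]
    if u200 >= thresholds.t_high:
        emt = "E"
    elif u200 <= thresholds.t_low:
        emt = "M"
    else:
        emt = "E/M"
    N, D, J = state[IDX["N"]], state[IDX["D"]], state[IDX["J"]]
    high_R = N >= thresholds.N_cut
    high_L = (D >= thresholds.D_cut) or (J >= thresholds.J_cut)
    if high_R and high_L:
        sig = "S/R"
    elif high_R:
        sig = "R"
    elif high_L:
        sig = "S"
    else:
        rec = N / thresholds.N_cut
        lig = max(D / thresholds.D_cut, J / thresholds.J_cut)
        sig = "R" if rec >= lig else "S"
    return emt, sig


def _tristable_anchor_levels(diagram):
    """miR-200 levels of the 3 stable branches at the tristable window centre."""
    counts = diagram.stable_count()
    idx = np.flatnonzero(counts >= 3)
    if idx.size == 0:
        raise ValueError("calibration scan has no tristable window")
    centre = int(idx[len(idx) // 2])
    levels = sorted(s.u200 for s in diagram.roots[centre] if s.stable)
    return levels[0], levels[len(levels) // 2], levels[-1], centre


_CALIBRATION_CACHE: dict = {}


def calibrate_thresholds(params: ModelParameters, control: str = "J_ext",
                         scan_range: tuple[float, float] = (0.0, 3000.0),
                         n_points: int = 120, seed: int = 0,
                         env_base: Environment | None = None
                         ) -> PhenotypeThresholds:
    """Branch-anchored thresholds from a Numb-off bifurcation scan.

    Runs ``scan_bifurcation`` with Numb disabled (so on/off comparisons
    share one ruler), locates the centre of the tristable window, and sets
    ``t_low``/``t_high`` to the midpoints between the M/hybrid and
    hybrid/E branch miR-200 levels there.  Receptor/ligand cuts are the
    geometric means of the extremes of stable-state N, D, J levels over
    the scan.
    """
    from .steady_state import scan_bifurcation
    base = params.replace(numb_enabled=False)
    if env_base is None:
        env_base = Environment(N_ext=10000.0)
    key = (repr(sorted(base.to_dict().items())), control, tuple(scan_range),
           n_points, seed, repr(env_base))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    diagram = scan_bifurcation(control, scan_range, n_points=n_points,
                               env_base=env_base, params=base, seed=seed)
    uM, uEM, uE, centre = _tristable_anchor_levels(diagram)
    t_low = 0.5 * (uM + uEM)
    t_high = 0.5 * (uEM + uE)
    cuts = {}
    for sp in ("N", "D", "J"):
        vals = np.array([s.state[IDX[sp]] for pts in diagram.roots
                         for s in pts if s.stable])
        vals = np.maximum(vals, 1.0)
        cuts[sp] = float(np.sqrt(vals.min() * vals.max()))
    meta = {"control": control, "scan_range": list(scan_range),
            "n_points": n_points, "seed": seed,
            "anchor_u200": [uM, uEM, uE],
            "anchor_control_value": float(diagram.grid[centre])}
    out = PhenotypeThresholds(t_low=t_low, t_high=t_high, N_cut=cuts["N"],
                              D_cut=cuts["D"], J_cut=cuts["J"], meta=meta)
    _CALIBRATION_CACHE[key] = out
    return out


def thresholds_from_labelled_diagram(diagram) -> PhenotypeThresholds:
    """Midpoint thresholds re-derived from an already-labelled diagram."""
    groups: dict[str, list[float]] = {"E": [], "E/M": [], "M": []}
    for br in diagram.branches:
        if br.phenotype in groups:
            groups[br.phenotype].extend(s.u200 for s in br.states if s.stable)
    if groups["E/M"] and groups["M"]:
        t_low = 0.5 * (max(groups["M"]) + min(groups["E/M"]))
    elif groups["M"]:
        t_low = max(groups["M"]) * 1.5
    else:
        t_low = 1.0
    if groups["E"] and groups["E/M"]:
        t_high = 0.5 * (max(groups["E/M"]) + min(groups["E"]))
    elif groups["E"]:
        t_high = min(groups["E"]) * 0.75
    else:
        t_high = t_low * 2.0
    allN = [s.state[IDX["N"]] for pts in diagram.roots for s in pts if s.stable]
    allD = [s.state[IDX["D"]] for pts in diagram.roots for s in pts if s.stable]
    allJ = [s.state[IDX["J"]] for pts in diagram.roots for s in pts if s.stable]
    gm = lambda v: float(np.sqrt(max(min(v), 1.0) * max(max(v), 1.0))) if v else 1.0
    return PhenotypeThresholds(t_low=t_low, t_high=t_high, N_cut=gm(allN),
                               D_cut=gm(allD), J_cut=gm(allJ),
                               meta={"source": "labelled-diagram"})


@dataclass
class PhenotypeMap:
    """Per-cell phenotype labels of one lattice snapshot."""

    emt: np.ndarray            # dtype '<U3', values in EMT_LABELS
    signalling: np.ndarray     # dtype '<U3', values in {"S", "R", "S/R"}
    thresholds: PhenotypeThresholds
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.emt.shape

    def fractions(self) -> dict[str, float]:
        n = self.emt.size
        return {lab: float(np.sum(self.emt == lab)) / n for lab in EMT_LABELS}

    def codes(self) -> np.ndarray:
        """Integer-coded map (0=E, 1=E/M, 2=M) for plain-text export."""
        out = np.empty(self.emt.shape, dtype=int)
        for lab, code in EMT_CODES.items():
            out[self.emt == lab] = code
        return out


def classify_lattice(grid_states: np.ndarray, thresholds: PhenotypeThresholds,
                     meta: dict | None = None) -> PhenotypeMap:
    """Vectorised classification of a (11, rows, cols) lattice state array."""
    u200 = grid_states[IDX["u200"]]
    emt = np.full(u200.shape, "E/M", dtype="<U3")
    emt[u200 >= thresholds.t_high] = "E"
    emt[u200 <= thresholds.t_low] = "M"
    N, D, J = (grid_states[IDX[s]] for s in ("N", "D", "J"))
    high_R = N >= thresholds.N_cut
    high_L = (D >= thresholds.D_cut) | (J >= thresholds.J_cut)
    sig = np.full(u200.shape, "R", dtype="<U3")
    sig[high_L & ~high_R] = "S"
    sig[high_L & high_R] = "S/R"
    both_low = ~high_L & ~high_R
    rec = N / thresholds.N_cut
    lig = np.maximum(D / thresholds.D_cut, J / thresholds.J_cut)
    sig[both_low & (lig > rec)] = "S"
    return PhenotypeMap(emt=emt, signalling=sig, thresholds=thresholds,
                        meta=meta or {})


def threshold_robustness(grid_states: np.ndarray,
                         thresholds: PhenotypeThresholds,
                         rel: float = 0.05) -> float:
    """Largest phenotype-fraction change under a +/-rel shift of the miR-200
    cut points (fraction units).

    A settled snapshot (cells near attractors) should report a value well
    below 0.01; a large value flags cells still in transit across a cut.
    """
    base = classify_lattice(grid_states, thresholds).fractions()
    worst = 0.0
    for fac in (1.0 - rel, 1.0 + rel):
        shifted = PhenotypeThresholds(
            t_low=thresholds.t_low * fac, t_high=thresholds.t_high * fac,
            N_cut=thresholds.N_cut, D_cut=thresholds.D_cut,
            J_cut=thresholds.J_cut, meta={"shift": fac})
        f = classify_lattice(grid_states, shifted).fractions()
        worst = max(worst, max(abs(f[k] - base[k]) for k in EMT_LABELS))
    return worst


@dataclass
class CompositionSummary:
    """Replicate-wise E / E-M / M fractions with mean and s.e.m."""

    fractions: np.ndarray      # shape (n_replicates, 3) in EMT_LABELS order
    mean: np.ndarray           # shape (3,)
    sem: np.ndarray            # shape (3,)
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {}
        for i, lab in enumerate(EMT_LABELS):
            key = {"E": "f_E", "E/M": "f_EM", "M": "f_M"}[lab]
            out[key] = float(self.mean[i])
            out[key + "_sem"] = float(self.sem[i])
        return out


def composition(maps: list[PhenotypeMap], meta: dict | None = None
                ) -> CompositionSummary:
    """Mean and standard error of phenotype fractions over replicates."""
    if not maps:
        raise ValueError("composition: need at least one replicate")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("composition: replicate grids differ in shape")
        if m.thresholds != maps[0].thresholds:
            raise ValueError("composition: replicates classified with "
                             "different thresholds")
    fr = np.array([[m.fractions()[lab] for lab in EMT_LABELS] for m in maps])
    mean = fr.mean(axis=0)
    n = fr.shape[0]
    sem = fr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(3)
    return CompositionSummary(fractions=fr, mean=mean, sem=sem, meta=meta or {})


def _neighbour_shifts(connectivity: int):
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    elif connectivity != 4:
        raise ValueError("connectivity must be 4 or 8")
    return shifts


def _shifted(mask: np.ndarray, dr: int, dc: int, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return np.roll(np.roll(mask, dr, axis=0), dc, axis=1)
    out = np.zeros_like(mask)
    r0, r1 = max(dr, 0), mask.shape[0] + min(dr, 0)
    c0, c1 = max(dc, 0), mask.shape[1] + min(dc, 0)
    out[r0:r1, c0:c1] = mask[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


@dataclass
class ColocalizationSummary:
    """Like-phenotype adjacency of hybrid E/M cells."""

    mean: float | None         # mean number of E/M neighbours per E/M cell
    histogram: np.ndarray      # counts of E/M cells with 0..k E/M neighbours
    n_hybrid: int

    @property
    def empty(self) -> bool:
        return self.n_hybrid == 0


def hybrid_colocalization(pmap: PhenotypeMap, boundary: str = "periodic",
                          connectivity: int = 4) -> ColocalizationSummary:
    """How many neighbours of each hybrid E/M cell are themselves hybrid E/M."""
    mask = pmap.emt == "E/M"
    shifts = _neighbour_shifts(connectivity)
    counts = sum(_shifted(mask, dr, dc, boundary).astype(int)
                 for dr, dc in shifts)
    vals = counts[mask]
    hist = np.bincount(vals, minlength=len(shifts) + 1)
    mean = float(vals.mean()) if vals.size else None
    return ColocalizationSummary(mean=mean, histogram=hist,
                                 n_hybrid=int(mask.sum()))


@dataclass
class ClusterCensus:
    """Connected components of target-labelled cells."""

    n_clusters: int
    sizes: np.ndarray          # descending
    target: tuple[str, ...]

    @property
    def total_cells(self) -> int:
        return int(self.sizes.sum())


def cluster_census(pmap: PhenotypeMap, target: set[str] | tuple[str, ...],
                   connectivity: int = 4, boundary: str = "periodic"
                   ) -> ClusterCensus:
    """Count and size clusters of cells whose EMT label is in ``target``."""
    target = tuple(sorted(set(target)))
    if not set(target) <= set(EMT_LABELS):
        raise ValueError(f"target labels must be a subset of {EMT_LABELS}")
    mask = np.isin(pmap.emt, target)
    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels, n = ndimage.label(mask, structure=structure)
    if boundary == "periodic" and n > 1:
        labels, n = _merge_periodic(labels, mask, connectivity)
    sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1] if n else np.array([], int)
    sizes = sizes[sizes > 0]
    return ClusterCensus(n_clusters=len(sizes), sizes=sizes, target=target)


def _merge_periodic(labels: np.ndarray, mask: np.ndarray, connectivity: int):
    """Union labels that touch across the wrap-around edges."""
    parent = list(range(labels.max() + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    rows, cols = labels.shape
    pairs = []
    pairs += [((0, c), (rows - 1, c)) for c in range(cols)]
    pairs += [((r, 0), (r, cols - 1)) for r in range(rows)]
    if connectivity == 8:
        pairs += [((0, c), (rows - 1, (c + d) % cols))
                  for c in range(cols) for d in (-1, 1)]
        pairs += [((r, 0), ((r + d) % rows, cols - 1))
                  for r in range(rows) for d in (-1, 1)]
    for (r1, c1), (r2, c2) in pairs:
        if mask[r1, c1] and mask[r2, c2]:
            union(labels[r1, c1], labels[r2, c2])
    remap = np.array([find(i) for i in range(len(parent))])
    labels = remap[labels]
    uniq = np.unique(labels[labels > 0])
    lut = np.zeros(labels.max() + 1, dtype=int)
    lut[uniq] = np.arange(1, uniq.size + 1)
    return lut[labels], uniq.size
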
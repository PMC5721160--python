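"""Spatial organisation: hybrid co-localization and cluster census.

Compares the strong-Jagged lattice with and without Numb: how many
neighbours of a hybrid E/M cell are themselves hybrid, and how the
non-epithelial cells organise into connected clusters.
"""

import notchemt as ne

params = ne.default_params()
thresholds = ne.calibrate_thresholds(params, seed=0)

for numb in (False, True):
    p = params.replace(numb_enabled=numb)
    cfg = ne.LatticeConfig(rows=25, cols=25, g_J=80.0, g_D=20.0,
                           duration=120.0, seed=3)
    init = ne.random_initial_lattice(cfg, p, replicate=0)
    snaps = ne.integrate_lattice(init, cfg, p)
    pmap = ne.classify_lattice(snaps[-1].grid, thresholds)
    col = ne.hybrid_colocalization(pmap)
    census = ne.cluster_census(pmap, {"E/M", "M"})
    f = pmap.fractions()
    print(f"Numb {'on ' if numb else 'off'}: "
          f"f_EM={f['E/M']:.2f} f_M={f['M']:.2f} | "
          f"mean E/M neighbours of an E/M cell: "
          f"{'-' if col.empty else format(col.mean, '.2f')} | "
          f"non-E clusters: {census.n_clusters} "
          f"(largest {census.sizes[0] if census.n_clusters else 0})")

print("\nA co-localization mean near 4 (the maximum for a 4-neighbourhood)"
      "\nmeans hybrid cells sit next to hybrid cells: Notch-Jagged lateral"
      "\ninduction with Numb builds spatially contiguous hybrid E/M patches"
      "\nrather than isolated cells.")
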
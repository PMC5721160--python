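# Methods

## The circuit

`notchemt` models one cell as an 11-dimensional ODE system in continuous
molecule counts, with time in hours. Species: Notch receptor (N), Delta
(D), Jagged (J), NICD (I), Numb (P), miR-34 (µ34), Snail mRNA (mS) and
protein (S), miR-200 (µ200), Zeb mRNA (mZ) and protein (Z).

Regulatory links are shifted Hill factors
H(X) = (1 + λ(X/X₀)ⁿ)/(1 + (X/X₀)ⁿ) multiplying basal production rates.
The topology is: NICD activates Notch and Jagged and represses Delta;
NICD and an external inducer I_ext activate Snail transcription; Snail
represses itself, represses both microRNAs and activates Zeb; Zeb
self-activates and represses both microRNAs; miR-34 silences Snail mRNA
and the Notch and Delta proteins; miR-200 silences Zeb mRNA and Jagged;
NICD represses Numb, Numb attenuates NICD release, and miR-34 weakly
silences Numb.

MicroRNA action uses the multi-site occupancy formalism: with
n binding sites and threshold µ₀, each site is bound with probability
p = (µ/µ₀)/(1+µ/µ₀), occupancies are binomial, and translation (l_i),
active mRNA degradation (γm_i) and microRNA consumption (i·γu_i) are
occupancy-weighted sums. Translation weights are non-increasing in
occupancy by a validated invariant. Consumption fluxes are carried only by
the mRNA-bearing targets (Snail and Zeb mRNA); silencing of the Notch-side
proteins, which carry no explicit mRNA species, is translation-level only.

Receptor–ligand kinetics: the receptor is consumed by cis-inhibition with
the cell's own ligands (k_C) and by trans-interaction with the total
external ligand (k_T); ligands are symmetrically consumed by the cell's
own receptor and by external receptor (N_ext). Productive trans-activation
produces NICD at rate k_T·N·(D_ext+sD_ext+J_ext+sJ_ext), multiplied by the
Numb brake H(P) (λ<1). Soluble ligands signal identically to membrane
ligands but are never consumed and receive no feedback.

## Numb

Numb is modelled as a single pooled variable (the biology does not
distinguish the two homologues' action on Notch here). It acts as a
multiplicative inhibitory shifted-Hill factor on NICD production — the
minimal realization of "Numb inhibits Notch" — rather than as an extra
receptor-degradation channel; the two are nearly equivalent for the
steady-state structure, and the flux brake keeps the receptor pool (which
neighbours sense) unchanged. Two feedbacks close the loop: NICD represses
Numb transcription (threshold deliberately high, so repression only bites
at very strong signalling) and miR-34 silences Numb post-translationally.
The miR-34 link is enabled by default and is load-bearing in this
parameterization: it makes the brake state-dependent — weak in epithelial
cells (miR-34 high, Numb silenced), strong in hybrid and mesenchymal
cells (miR-34 low, Numb restored) — which is what lets a layer under
strong Jagged signalling leave the epithelial state yet refuse the final
transition to M. Both Numb toggles (`numb_enabled`,
`mir34_numb_enabled`) are plain parameters.

## Parameters

Defaults live in `src/notchemt/data/default_params.txt` (flat
`key = value` text, one symbol per line). The EMT core retains the
canonical miRNA/TF-chimera rate structure of this model family; the
production/degradation pairs of miR-34, miR-200, Snail protein and Zeb
protein are jointly scaled (~1.7×) relative to that tradition — a
fixed-point-preserving change that only accelerates relaxation, chosen so
that the biologically motivated 120 h observation window captures the
full transition. The Notch sector uses weak consumption
(k_T ≈ 2·10⁻⁶, k_C = 5·10⁻⁷ per molecule per hour) and slow ligand
turnover (γ_D = 0.015, γ_J = 0.02 h⁻¹) so membrane ligand pools reach
10³–10⁴ molecules; this is forced by internal consistency: the soluble
ligand doses that matter experimentally (2000–4000 molecules) and the
reference external receptor level (N_ext = 10⁴) must sit on the same
scale as what neighbours present. NICD thresholds (I₀ ≈ 30–175
molecules) were placed in the NICD range the lattice actually generates.
All of these were calibrated once, against the qualitative single-cell
bifurcation structure (tristability with ordered miR-200 branches; Numb
widening the E and E/M windows and delaying the M onset) and the
composition behaviour of the Jagged-dominated lattice, and then frozen.

Key tunables and their meaning:

| parameter | default | meaning |
|---|---|---|
| g_J, g_D | 45, 20 molecules/h | ligand production; the lattice control knobs |
| k_T, k_C | 1.97·10⁻⁶, 5·10⁻⁷ /molecule/h | trans-activation, cis-inhibition |
| I0_mS, lam_I_mS | 40, 8 | NICD→Snail threshold and strength (EMT drive) |
| P0_I, lam_P_I | 600, 0.2 | Numb brake threshold and maximal attenuation |
| l_34_P | (1, 0.25) | miR-34 silencing of Numb (1 site) |
| Iext0_mS, lam_Iext_mS | 5·10⁴, 10 | external-inducer (TGF-β-like) response |

## Numerical methods

* **Integration.** Single cells use LSODA; the lattice integrates the
  whole grid as one flattened ODE vector with RK45 (the coupled system is
  non-stiff at these rates; no operator splitting, hence no splitting
  error). Default tolerances rtol 10⁻⁶ / atol 10⁻³ molecules for single
  cells; lattice production runs use rtol 10⁻⁵ / atol 10⁻², validated by
  a tolerance-refinement test (phenotype fractions move < 0.5 points).
  Negativity is handled by construction: every loss term vanishes with
  its species, and the regulatory functions evaluate max(X, 0) so
  integrator round-off below zero self-corrects through the linear decay.
* **Steady states.** Multi-start damped Newton (backtracking line search,
  forward-difference Jacobians inside the loop, central differences for
  the final classification), vectorized over starting points drawn
  uniformly from the physiological box (0 to 2× production/degradation
  per species). Starts whose line search stalls — residual-norm local
  minima near folds — are flowed forward along the ODE to an attractor
  and re-polished, which guarantees the stable states are found even
  where Newton alone fails. Roots are de-duplicated at relative 10⁻⁴
  (max norm over scaled species), accepted below a scaled residual of
  10⁻⁶, and classified by the Jacobian spectrum with a ±10⁻⁶ h⁻¹
  stability margin ("marginal" in between); an optional forward
  attraction test (1% perturbation) cross-checks stability flags.
* **Bifurcation scans.** Brute-force continuation: the multi-start search
  is rerun along a strictly increasing control grid, warm-started from
  the previous point's roots, and roots are linked into branches by
  nearest-state continuation (ties broken by smallest miR-200 distance).
  This resolves branch extents to one grid step — all the analyses here
  need — and a bisection refinement (default 10⁻³ of the range) sharpens
  interval endpoints where requested. Discovery of a branch at its onset
  relies on the random starts, so very small basins may be picked up one
  or two grid points late; interval *comparisons* are unaffected because
  both arms of a comparison use identical machinery.
* **Classification.** The two miR-200 cut points are the midpoints
  between the M/hybrid and hybrid/E branch levels at the centre of the
  tristable window of a Numb-off calibration scan; sender/receiver cuts
  are geometric means of stable-state extremes. Thresholds are computed
  once per parameter set (cached) and reused across Numb-on/off
  comparisons. A built-in robustness check reports how much fractions
  move under ±5% threshold shifts; settled snapshots sit well below 1
  point, while layers still in transit flag themselves with larger
  values.

## The simulated conditions

Scenario defaults mirror the study conditions: 50×50 (analysis) or 25×25
(desk-scale) lattices, periodic boundaries, mean aggregation over the
4-neighbourhood, 120 h transient, 10 replicates from seeded random
initial conditions. Random initial states are uniform on
[0, basal production/degradation] per species — the unregulated
physiological box; this stands in for "randomly chosen phenotype
distributions" and is the one place the generator interprets rather than
copies its source. The EMT-induction scenario starts every cell at the
hybrid fixed point (located from the homogeneous self-coupled system or,
failing that, the single-cell tristable window) and applies I_ext = 500
molecules, which reproduces the observed behaviour: the Numb-free layer
flips to predominantly mesenchymal between day 3 and day 4, the
Numb-bearing layer does not flip within 6 days.

## What passing tests do and do not show

The generator emulates a uniform, immobile cell sheet with identical
kinetics in every cell. It does not emulate cell division, death or
migration (which would disrupt the phenotypic patterns on longer
horizons), stochastic gene expression, ligand diffusion gradients, or
heterogeneous parameters across cells — so quantitative fractions are
statements about this idealized sheet, not about tissue.

## Known limitations

* Two directional claims of the Numb comparison do not hold under the
  shipped calibration and their acceptance-level tests are left failing
  rather than weakened: (i) the Delta production needed for a 1:1 E:E/M
  ratio is *not* lower with Numb here — a multiplicative NICD-release
  brake rescales the Delta axis upward faster than the NICD⊣Delta
  de-repression can compensate, across the explored brake/relief design
  space — and (ii) at a soluble-Jagged dose of 4000 molecules the
  Numb-bearing layer completes its EMT (the hybrid-dominated outcome is
  robust at 2000). Both are documented calibration limits of the brake
  mechanism, not missing features.
* The Delta-dominated interleaved (salt-and-pepper) regime sits at
  g_D ≈ 140–280 molecules/h under this calibration; the g_D axis, like
  every absolute scale here, is calibration-dependent.
* Stability analysis of homogeneous lattice states covers spatially
  uniform perturbations only; pattern-forming instabilities are probed by
  direct simulation, not linear analysis.
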
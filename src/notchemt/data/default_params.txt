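# notchemt default model parameters.
# Units: molecules and hours throughout; g_* molecules/h (g_S, g_Z are
# protein/mRNA/h), gamma_* 1/h, k_T / k_C 1/(molecule h); Hill thresholds
# (X0, molecules), fold-changes lam_* dimensionless (>1 activation,
# <1 repression); microRNA weight vectors are per-occupancy, length
# n_sites + 1 (l translation, gm mRNA degradation 1/h, gu microRNA
# consumption 1/h).

# ---- Notch module ----
g_N = 1400.0           # Notch receptor production
g_D = 20.0             # Delta production (baseline; lattice scenarios override)
g_J = 45.0             # Jagged production (baseline; lattice scenarios override)
gamma_N = 0.1
gamma_D = 0.015
gamma_J = 0.02
gamma_I = 0.25         # NICD degradation
k_T = 1.97e-6             # trans-activation
k_C = 5e-7             # cis-inhibition

I0_N = 175.0           # NICD -> Notch (activation, engages at strong signalling)
n_I_N = 2
lam_I_N = 2.0
I0_D = 35.0            # NICD -| Delta (sharp shutoff: lateral inhibition)
n_I_D = 6
lam_I_D = 0.02
I0_J = 30.0            # NICD -> Jagged (lateral induction)
n_I_J = 2
lam_I_J = 3.0

# ---- EMT core: miR-34 / Snail and miR-200 / Zeb ----
g_u34 = 2295.0
g_mS = 90.0
g_S = 170.0
g_u200 = 3570.0
g_mZ = 11.0
g_Z = 170.0
gamma_u34 = 0.085
gamma_mS = 0.5
gamma_S = 0.2125
gamma_u200 = 0.085
gamma_mZ = 0.5
gamma_Z = 0.17

I0_mS = 40.0           # NICD -> Snail transcription
n_I_mS = 2
lam_I_mS = 8.0
Iext0_mS = 50000.0     # external EMT inducer (e.g. TGF-beta) -> Snail
n_Iext_mS = 1
lam_Iext_mS = 10.0
S0_mS = 200000.0       # Snail self-repression
n_S_mS = 1
lam_S_mS = 0.1
S0_u34 = 300000.0      # Snail -| miR-34
n_S_u34 = 4
lam_S_u34 = 0.1
Z0_u34 = 600000.0      # Zeb -| miR-34
n_Z_u34 = 2
lam_Z_u34 = 0.2
S0_u200 = 180000.0     # Snail -| miR-200
n_S_u200 = 2
lam_S_u200 = 0.1
Z0_u200 = 240000.0     # Zeb -| miR-200
n_Z_u200 = 3
lam_Z_u200 = 0.1
S0_mZ = 180000.0       # Snail -> Zeb transcription
n_S_mZ = 2
lam_S_mZ = 10.0
Z0_mZ = 25000.0        # Zeb self-activation
n_Z_mZ = 2
lam_Z_mZ = 7.5

# ---- Numb module ----
g_P = 100.0            # Numb production
gamma_P = 0.1
I0_P = 1200.0          # NICD -| Numb transcription (weak in working range)
n_I_P = 2
lam_I_P = 0.1
P0_I = 600.0           # Numb -| NICD release (the brake)
n_P_I = 2
lam_P_I = 0.2

# ---- microRNA silencing ----
mu0_34 = 10000.0
mu0_200 = 10000.0
l_34_mS = 1.0, 0.6, 0.3
gm_34_mS = 0.0, 0.04, 0.2
gu_34_mS = 0.0, 0.0085, 0.085
l_200_mZ = 1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05
gm_200_mZ = 0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0
gu_200_mZ = 0.0, 0.0085, 0.085, 0.85, 0.85, 0.85, 0.85
l_34_N = 1.0, 0.6, 0.3
l_34_D = 1.0, 0.95, 0.9
l_200_J = 1.0, 0.6, 0.3, 0.1
l_34_P = 1.0, 0.25

# ---- toggles ----
numb_enabled = true
mir34_numb_enabled = true
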
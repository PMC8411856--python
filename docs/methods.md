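# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Canopy representation

The canopy is a horizontally uniform turbid medium split into two "big
leaves": the sunlit population (leaf area receiving direct beam) and the
shaded population (diffuse light only). Fluxes are computed per ground area
for each fraction and summed; there is no vertical layering beyond the
analytic profiles below. Canopy temperature, S_c/o and K_c are shared by
both fractions; absorbed PAR, capacities and conductances differ.

### Radiative transfer

Direct-beam extinction uses the Goudriaan projection G(μ) = φ1 + φ2 μ with
φ1 = 0.5 − 0.633 χ − 0.33 χ², φ2 = 0.877(1 − 2φ1), χ the Ross index
(clamped to [−0.4, 0.6]). The diffuse field obeys the two coupled
two-stream ODEs with scattering ω = ρ + τ, diffuse upscatter
ωβ = ½[ω + (ρ−τ)((1+χ)/2)²], beam upscatter β0 from the single-scattering
albedo, and average inverse diffuse optical depth
μ̄ = (1/φ2)[1 − (φ1/φ2)ln((φ1+φ2)/φ1)] (limit 1/(2φ1) as φ2 → 0).

Because the system is linear with constant coefficients, it is solved
exactly: the homogeneous part by eigen-decomposition of the 2×2 coefficient
matrix, the beam-driven particular solution by a 2×2 linear solve (the
K = h resonance is detuned by a relative 1e−6 when the determinant
vanishes). Boundary conditions are the incident diffuse flux at the top and
soil reflection (albedo shared by beam and diffuse) at the bottom. Canopy
absorption is integrated analytically; unscattered-beam absorption goes
wholly to sunlit leaves while diffuse-type absorption is weighted by the
sunlit-fraction profile e^(−Kb·L). Energy closure (absorbed + reflected +
soil = incident) holds to round-off and is asserted at 1e−6 in the tests;
a 200-node numerical boundary-value solution of the same ODEs (scipy
`solve_bvp`) serves as an independent oracle at low scattering.

Incoming shortwave is split 50% visible, and visible is split 70/30
direct/diffuse when the site does not report the partition (both config).
Records with zenith ≥ 90° or shortwave < 5 W m⁻² short-circuit to night:
APAR = 0 and canopy flux = −R_d of the whole canopy.

### Canopy temperature

The energy module implements the explicit storage step
T = T_prev + Δt(Rn − H − LE)/C with C = (LAI/SLA)[c_dry + c_wat·w/(1−w)]
and a hard clamp to (250, 330) K (logged). In the canopy pipeline the
anchor temperature is the current air temperature, so the canopy runs at
air temperature plus a storage offset from the measured flux imbalance.
A free-running integrated canopy state was rejected: foliage heat capacity
is small (tens to hundreds of J m⁻² K⁻¹), so integrating tower energy-
balance non-closure would drift without bound; anchoring to air temperature
keeps the model well-posed on both closed and non-closed budgets, and
reduces exactly to T_c = T_a when any flux is missing.

## Rubisco kinetics and capacities

Each variant is described by K_cat25 (s⁻¹), K_c^21%O2 at 25 °C (gas-phase
μmol mol⁻¹; measuring K_c at ambient O2 folds the competitive O2 term into
one constant and removes K_o), S_c/o at 25 °C (gas-phase), and a positive
activation energy H_a for each. Γ* = 0.5·O2/S_c/o. A helper converts
solution-phase assay values (μM, dissolved-basis S_c/o) to the gas basis via
Henry's-law solubilities (CO2 0.0334, O2 0.00126 mol L⁻¹ bar⁻¹ at 25 °C).

Canopy-top V_cmax25 = Na·Flnr·F_nr·sites·K_cat25 with Na = 1/(SLA·C:N),
F_nr = 7.16 g Rubisco (g N)⁻¹ and 14.545 μmol sites g⁻¹ (8 sites per
550 kDa holoenzyme) — CLM-style constants, config-overridable. Derived
capacities use fixed ratios J_max = 1.67 V_cmax, R_d = 0.015 V_cmax (C3;
the C3/C4 intermediate is treated as C3) or 0.025 V_cmax (C4), and
K_p = 20000 V_cmax (C4 only).

Temperature responses: all kinetic constants follow the Arrhenius factor
exp[H_a(T − 298.15)/(298.15·R·T)]. C3 V_cmax (and J_max, which uses one
shared host H_a = 43 540 J mol⁻¹) is additionally damped by the peaked
deactivation (1 + e^((298.15ΔS−H_d)/(298.15R)))/(1 + e^((TΔS−H_d)/(TR)))
with H_d = 149 250 J mol⁻¹, ΔS = 485 J mol⁻¹ K⁻¹. C4 V_cmax uses
Q10 = 2 damped by [1 + e^(s1(T−s2))][1 + e^(s3(s4−T))] with s1 = 0.3 K⁻¹,
s2 = 313.15 K, s3 = 0.2 K⁻¹, s4 = 288.15 K. R_d and K_p co-vary with
V_cmax. **Known limitation:** S_c/o is adjusted with a plain positive-H_a
Arrhenius factor, as the kinetics contract specifies, so modelled S_c/o
rises slightly with temperature whereas measured specificity declines; at
the moderate leaf temperatures of the packaged scenarios the effect on
Γ* is a few μmol mol⁻¹.

Capacity declines into the canopy as e^(−K_n·L) with K_n = 0.3 for all
crops; big-leaf integrals are closed-form,
V_sun = v0(1 − e^(−(K_n+K_b)L))/(K_n+K_b), V_sha = V_tot − V_sun.

## Leaf biochemistry and CO2 coupling

C3 (Farquhar): A_c = V_cmax(C_i − Γ*)/(C_i + K_c^21%O2),
A_j = J(C_i − Γ*)/(4C_i + 8Γ*), A_p = 0.5 V_cmax (a conventional export
limb; the phosphate limitation rarely binds in these scenarios). J is the
smaller root of θ_PSII J² − (I₂ + J_max)J + I₂J_max with I₂ = 0.5·φ_PSII·APAR,
φ_PSII = 0.85, θ_PSII = 0.7.

C4 (Collatz): A_c = V_cmax, A_j = α·APAR with α = 0.05, A_p = K_p·C_i·10⁻⁶.

Rates combine through nested quadratic smoothing (smaller root of
θx² − (a1+a2)x + a1a2, evaluated in the cancellation-stable form
2a1a2/(B + √(B²−4θa1a2))); θ pairs (0.98, 0.95) for C3 and (0.80, 0.95)
for C4. θ = 1 reduces exactly to the hard minimum. When a candidate rate is
non-positive (below the compensation point, or darkness) the hard minimum
is used directly, which keeps the night limit A_n = −R_d exact.

Supply couples through g_b = c_v√(u/d_leaf)·ρ_air (wind floored at
0.1 m s⁻¹) and Ball–Berry g_s = g0 + g1·A_n·h_s/c_s with g0 = 0.01
mol m⁻² s⁻¹, g1 = 9 (C3) / 4 (C4). Leaf-surface humidity follows from
vapour-flux continuity g_s(e_i − e_s) = g_b(e_s − e_a), which combined with
Ball–Berry yields a quadratic in g_s (positive root). An optional soil-
moisture scalar β ∈ [0,1] multiplies g1 (default 1, i.e. off, because site
soil moisture is frequently absent). CO2 conversion factors are 1.37
(boundary layer) and 1.65 (stomata); mesophyll conductance is omitted.

The fixed point of C_i → A_n → g_s → C_i′ = C_a − A_n(1.37/g_b + 1.65/g_s)
is found by Newton–Raphson on f(C_i) = C_i′ − C_i (finite-difference
slope), falling back to bisection on [0, 1.5 C_a] whenever a step leaves
the bracket or fails to reduce |f|; termination at |ΔC_i| < 0.001
μmol mol⁻¹ (the tolerance is interpreted on the mole-fraction iterate) or
100 iterations with a flagged, non-raising non-convergence. Initial guess
0.7 C_a (C3) / 0.4 C_a (C4). The residual function is vectorised so a grid
scan over the bracket can verify any solution independently.

## Seasons, LAI and screening

Daily driving uses daytime means (records with SW ≥ 5 W m⁻² averaged per
calendar day) with daylight-mean solar geometry and Δt = daylength; night
respiration between days is not counted, matching daytime-mean forcing.
Half-hourly driving uses instantaneous geometry and Δt = 1800 s. Gap
records are skipped and counted. Totals are ΣA_n·Δt in μmol CO2 m⁻².

LAI comes from the GDP method: ratio r = max(GPP)/LAI_max, instantaneous
LAI = GPP/r, lagged by lai_t = w·lai_{t−1} + (1−w)·lai_inst with w = 0.5
(the one-step exponential form was chosen for the unspecified "weighted
mean"; w is config), clamped at LAI_max.

The substitution screen runs one season per variant under identical
forcing and LAI — substitution changes the kinetics (K_cat, K_c, S_c/o,
H_a), never the host's pathway machinery, nitrogen economy or architecture;
an intermediate-pathway Rubisco in a C3 host runs through the C3 model.
Percent change is relative to the native total; the native-vs-native
comparison reuses the identical season total, so it is exactly 0 by
construction. Results are sorted by percent change, descending.

## Synthetic forcing

The generator emulates one cropland growing season at half-hourly
resolution: shortwave = 900 W m⁻²·cos(zenith) with 5% multiplicative noise;
air temperature = seasonal sinusoid (amplitude 4 K) + diurnal sinusoid
(amplitude 6 K, peaking 2 h after solar noon) + 0.6 K noise around a 18 °C
mean; relative humidity anticorrelated with temperature and clipped to
[0.2, 1]; wind 2.5 ± 0.7 m s⁻¹ floored at 0.1; GPP a rectangular hyperbola
of PAR (30 μmol m⁻² s⁻¹ saturated, half-saturation 800 μmol m⁻² s⁻¹) plus
ecosystem respiration with Q10 = 2 for the NEE channel; net radiation
0.8·SW partitioned into H and LE by a Bowen ratio of 0.3 with a closed
energy balance (so canopy temperature equals air temperature in synthetic
runs — tower non-closure is a property of real data the generator does not
emulate). All noise comes from per-field substreams spawned from one seed,
so output is bit-reproducible and fields are independent.

The default study conditions for screening tests are 30 days at latitude
42° starting on day-of-year 152 — long enough for a stable seasonal total,
small enough that a full 27-variant screen runs in seconds. What passing
tests on this forcing establish is the model's internal consistency
(conservation, convergence, monotonicity in K_cat, exact-zero native
comparison); they do not establish agreement with eddy-covariance
observations, which requires registered tower data and measured kinetics.

## Degenerate inputs and tie-breaks

LAI = 0 returns zero flux without solving; all-night days become gaps;
missing energy fluxes fall back to T_c = T_a; the solver flags rather than
raises non-convergence and clamps C_i to the bracket; zero observed
variance flags R² undefined rather than dividing by zero; kinetics rows
with incomplete values are excluded and logged, while non-positive values
raise naming the row and field.
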
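# Methods

This note documents the models, numerics and design choices behind
`leachsim`, in the spirit of a model description paper: what is computed,
under which assumptions, with which defaults, and what the packaged tests
do and do not demonstrate.

## Soil water

**Model.** One-dimensional vertical flow on a fixed finite-volume grid
(2 cm cells from 0–60 cm, 5 cm from 60–170 cm, 10 cm from 170–210 cm; 56
cells), mixed-form Richards equation with van Genuchten retention and
Mualem conductivity per horizon. Depth is positive downward; fluxes in
cm/day internally, mm at the API. The upper boundary is a prescribed net
flux (rain + irrigation − soil evaporation demand); the lower boundary is
unit-gradient free drainage by default ("deep groundwater"), with a
fixed-head alternative (`fixed_head:<cm>`, applied at the bottom edge).
Transpiration enters as a per-cell root sink.

**Numerics.** Implicit time stepping with adaptive sub-daily steps
(0.1 d initial, halved on failure, grown ×1.5 on success, capped at
0.5 d). The nonlinear system per sub-step is solved by Newton's method
with the analytic tridiagonal Jacobian, including the dK/dh terms, and a
line search that descends on the L2 norm of the mass residual (the max
norm is not monotone along Newton paths near saturation and stalls the
search). Convergence is declared on the *true* per-cell mass residual
(|F|·Δt < 10⁻⁹ cm).

Two regularisations matter on this profile. First, the NCP subsoil
horizons have flat retention curves (n ≈ 1.19) whose capacity vanishes
toward saturation, while Ksat drops by a factor ~200 at the 110 cm
horizon boundary; infiltration fronts perch and saturate there. A smooth
"specific storage" term (Ss = 10⁻⁴ cm⁻¹, softplus-smoothed over 0.5 cm
around h = 0) gives saturated cells a small compressible capacity and
removes the derivative discontinuity at the saturation kink; its stored
excess is carried in the water ledger. Second, because K(h) just below
saturation in these media is nearly discontinuous, Newton can stall at a
small, time-step-independent residual floor. The stepper halves Δt only
while that visibly lowers the floor, then accepts the stalled iterate
(only if the floor is < 1 cm/d). In all cases the *reported* edge fluxes
are reconciled with the realised storage change (Darcy fluxes minus the
cumulative iteration residual), so the column water balance closes to
machine precision by construction; a stalled residual only mis-places
flux locally around the front. Fixture runs show maximum daily ledger
defects of order 10⁻¹² mm.

Surface handling: the infiltration capacity uses the mean of the
saturated and current top-cell conductivity (the surface itself is wet
during infiltration); excess goes to a runoff/ponding ledger rather than
being dropped. Evaporation is capped at the air-dry water content
(h = −10⁵ cm) of the top cell, and the engine additionally scales the
demand by top-cell wetness (linear below 40 % of the plant-available
range). Transpiration per cell is capped at wilting (h = −1.5·10⁴ cm).

**Soil temperature** is an analytic damped annual sinusoid
T(z,t) = T̄ + A·e^(−z/d)·sin(ω(t − t₀) − z/d) with damping depth
d = 180 cm and the phase set for a mid-July surface maximum; its only
consumers are the turnover/nitrification rate modifiers and pre-emergence
degree-day accumulation, which do not justify a conduction PDE. The
annual mean and amplitude are derived from the weather series.

## Weather

Daily forcing: mean/min/max temperature, precipitation, global radiation
(24-h mean W/m²), wind, relative humidity. Reference evapotranspiration
is the daily FAO-56 Penman–Monteith form; actual vapour pressure defaults
to mean RH applied to the mean of saturation pressures at Tmin/Tmax, with
an override argument for independently derived values. Atmospheric N
deposition: wet = concentration (ppm = mg N/L) × rain × 0.01 kg/ha per
mm·mg/L; dry = annual value spread uniformly over the actual year length
(leap years divide by 366).

The synthetic NCP generator draws each year's precipitation total from
330–600 mm and mean temperature from 11.8–13.2 °C, distributes rain over
monsoonal monthly weights (≈74 % June–September) with gamma-distributed
wet-day amounts, uses a sinusoidal temperature cycle plus AR(1) daily
noise, couples radiation to extraterrestrial radiation and wet-day
cloudiness, and is bit-reproducible given a seed. It emulates the
*climatology* only: no multi-day synoptic persistence, no
drought/heat-wave correlation structure, no inter-annual teleconnections.
Tests passing under this forcing demonstrate internal consistency and
qualitative behaviour, not predictive skill for any measured season.

## Crop

Phenology: pre-emergence accumulates the soil temperature sum at 5 cm
(threshold EmrTSum); afterwards dDS/dt = DSRate1·f_T before flowering and
DSRate2·f_T after, with a piecewise-linear f_T between a base and plateau
temperature (maize 8→28 °C, wheat 0→20 °C; the wheat modifier reaching 0
below base stands in for vernalisation over winter). DSRate2,
temperature-modifier knots, partitioning tables and target organ N
concentration curves are package defaults, not field-derived values; all
live in the crop config files and are overridable.

Assimilation: the leaf light response (saturation value Fm, quantum
efficiency QEff) is driven by absorbed photosynthetically active
radiation (48 % of global radiation) under exponential extinction
(k = 0.6) of a sinusoidal daylight irradiance course, integrated by
Gauss–Legendre quadrature (20 canopy × 5 time nodes; the refinement test
checks 1 % agreement against 1000 × 64). Scaled by temperature and
senescence (DS) modifiers and min(water, N) stress. CO₂ converts to
CH₂O by 30/44; maintenance respiration r·DM·Q10^((T−20)/10) is deducted
first (deficits truncated and reported, never shrinking an organ);
the remainder is partitioned by DS and converted at organ efficiencies
E_organ — the carbon ledger closes exactly by construction.

Roots advance at a fixed daily rate toward min(MaxPen, root-zone end);
root length (DM × SpRtLength) follows a truncated exponential with 95 %
of mass above the rooting depth (the truncation keeps all water/N
extraction above the 2 m reporting edge, which the water-balance
estimator assumes). N uptake per cell is min(per-length maximum × root
length × 24 h, availability, remaining demand toward DS-dependent target
concentrations), NH₄ and NO₃ drawn in proportion to their potentials.
Water stress is realised/potential transpiration; N stress falls linearly
from 1 at the target N content to 0 at half of it.

On emergence the seed reserve (2 g DM/m²) materialises as organ mass with
*zero* N; the first day's uptake fills it from soil mineral N, keeping the
whole-system N ledger closed (at the cost of a one-day N-stress dip).

## Organic matter and mineral N

Pools per cell: SOM1 (slow), SOM2 (fast), SOM3 (inert), SMB1/SMB2
(microbial biomass, C/N 4.8), AOM1/AOM2 (added residues). Initialisation
distributes humus C (humus % × bulk density 1.4 g/cm³ × 0.587 C fraction)
by each horizon's SOM_fractions, carving the initial biomass (2 % of C)
out of the active share so the pool total matches measured C exactly; a
(0, 0, 1) horizon is fully inert with no live biomass. Residue additions
split C between AOM1/AOM2 (default 50/50), with AOM1 N bound at the
residue's slow-pool C/N (maize 60, wheat 100) and any N shortfall clamped
and reported.

Kinetics: first-order decays (exact exponential decrements, so a single
pool reproduces C₀e^(−kt) to the tolerance of the modifier product), with
Daisy-style default rate coefficients (SOM1 2.7·10⁻⁶, SOM2 1.4·10⁻⁴,
SMB1 1.85·10⁻⁴, SMB2 10⁻², AOM1 1.2·10⁻², AOM2 5·10⁻² per day, stored as
1/h in the config), substrate efficiencies and a standard flow topology
(AOM→SMB, SOM→SMB with a SOM2→SOM1 return, SMB death→SOM2/SMB2). SMB
pools additionally pay maintenance respiration (SMB1 1.8·10⁻³, SMB2
10⁻² d⁻¹): C to CO₂ with matching N mineralised — without it the biomass
grows for years after initialisation and the column immobilises through
the summer, inverting the expected seasonal net-mineralisation pattern.
Abiotic modifiers: f_T = 2^((T−10)/10) (0 below 0 °C), a piecewise-linear
moisture factor peaking near field capacity and halved at saturation, and
a clay protection factor max(1 − clay, 0.25) on SOM1, SOM2 and SMB1.
N follows C: receiver demand = received C / receiver C/N; shortfalls
immobilise NH₄ before NO₃, and flows throttle proportionally per cell
when mineral N cannot cover the demand, so pools never go negative and
the organic+mineral ledger is conservative to round-off.

Nitrification is first order in NH₄ (0.1 d⁻¹ at modifier 1) with 2 % of
the nitrified flux ledgered as N₂O. Denitrification is first order in
NO₃ at a potential 0.1 d⁻¹ times f_T times the tabulated water factor —
stored exactly as configured ((0.89, 0.01), (0.98, 0.01), (1.00, 0.01)
against relative saturation, flat below the first knot), which keeps
denitrification small for this soil. Ammonia volatilisation is an
amount-dependent fraction of each urea dressing (5/10/12/15/17 % at
50/100/150/200/300 kg N/ha, linear from zero below, interpolated between,
constant above), removed at application time.

Transport: implicit upwind finite-volume convection–dispersion per
species, using the same day's reconciled water fluxes; dispersion =
dispersivity (5 cm) × |pore velocity| + molecular diffusion
(0.05 cm²/d); NH₄ mobility divided by a linear sorption retardation
factor (3). The scheme conserves mass exactly (the leached flux is the
solved bottom-edge export) and propagates a pulse's centre of mass at the
pore-water velocity; its price is numerical smearing of sharp fronts.

## Engine, management and ledgers

Fixed daily operator order: deposition → management events → reference ET
and canopy partition → soil water (sub-stepping internally) → soil
temperature → crop (phenology, roots, assimilation, growth, N uptake) →
turnover → nitrification → denitrification → solute transport →
bookkeeping. Irrigation is added to the surface flux identically to rain.
Tillage mixes the organic pools and mineral N uniformly over the tilled
depth; instantaneous mixing is the simplest defensible treatment. Harvest
removes grain, splits straw by the event's incorporated fraction (plus a
10 % stubble fraction that always stays), sends incorporated straw,
stubble and roots to the AOM pools and ledgers the removed N as export.

Every boundary flux is ledgered daily; the closure diagnostics report the
worst daily defect of |Δstorage − (in − out)| for water (mm) and of the
total-N identity (relative). Annual N balances are differences of the
cumulative ledgers, with a residual that vanishes to solver precision.

Warm-up: optional pre-experiment years with prescribed background C
inputs (field A: 1550 total / 750 root kg C/ha/y; field B: 800/600)
applied monthly — non-root inputs over 0–25 cm, root inputs over the root
zone, at an assumed residue C/N of 50. These inputs are used *only*
during warm-up years, as an initialisation device for the organic pools,
not as a continuous background flux.

## Estimators, statistics, scenarios

The drainage estimator returns D = P + I + ΔSW − AET as-is, flagging
negative values (upward flow violates its assumptions) instead of hiding
them; ΔSW is entered as storage at interval start minus end, so depletion
adds to drainage. The leaching estimator clamps negative-drainage
intervals to zero contribution and flags the clamp. R² is the squared
Pearson correlation (a regression-through-origin variant is not provided;
ME already penalises bias). The sensitivity index is (ΔY/Y₀)/(ΔX/X₀) per
direction at ±10 %, with the perturbed config deep-copied so the baseline
is provably untouched. The scenario ladder fits OLS slopes to
post-harvest (6 October maize, 12 June wheat) 0–2 m soil mineral N over
the simulated years.

An internal-consistency check applies both estimators to the simulator's
own monthly outputs at 2 m. The drainage route is then an exact identity
(no runoff, roots above 2 m). The concentration route matches the
convection–dispersion leaching closely only when the nitrate profile is
established through the column (as under long-term fertilisation); across
a sharp front the estimator misses the dispersive flux, which is a real
limitation of the field method, not of the implementation.

## Problem sizes and limitations

The packaged tests and the acceptance script use two-rotation-year runs
(≈ 730–912 days, ~5 s each) and a 6-rate × 5-rotation-year ladder
(~35 simulated years); these sizes were chosen as the smallest at which
the seasonal and treatment patterns are unambiguous. Known limitations:
no macropore flow, hysteresis, photoperiod response, pest/disease, CO₂
response, dissolved organic N or pH dynamics; a fresh column needs years
of simulated drainage before nitrate reaches 2 m, so short runs report
near-zero deep leaching unless initialised with an established nitrate
profile; the synthetic climate reproduces envelopes, not events; and the
regional upscaling workflow that often accompanies such models is out of
scope.
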
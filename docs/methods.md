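# Methods

## Decay chain and unit conventions

The serial chain ²²²Rn → ²¹⁸Po → ²¹⁴Pb → ²¹⁴Bi(→ ²¹⁴Po) is integrated
with half-lives 3.82 d, 3.05 min, 26.8 min, 19.7 min. ²¹⁴Po (164 µs) is
never a state variable: its activity is aliased to ²¹⁴Bi, and its
7.69 MeV alpha is charged to the potential alpha energy of every upstream
atom (²¹⁸Po additionally carries its own 6.00 MeV). Alpha energies are
standard nuclear-data values, kept as module constants.

Activities are Bq m⁻³, atom numbers cm⁻³, internal time grids seconds
(hours inside the room model); every conversion (`A = λN`, m⁻³ ↔ cm⁻³) is
explicit. With the 3.82 d half-life, 1 Bq m⁻³ of radon is 0.4762 atoms
cm⁻³; quoting 0.477 requires the unrounded half-life (~3.8235 d), which is
why conversion tests allow the third decimal to move.

`bateman_ingrowth` uses the classical Bateman product formula, with a
guard that falls back to ODE integration (LSODA, rtol 1e-10) if any two
decay constants come within 1e-9 relative — impossible for this chain but
kept so the routine stays general. At 24 h the chain is in *transient*
equilibrium with the decaying parent: each progeny activity exceeds
radon's by the factor Π λ_j/(λ_j − λ_Rn), up to +0.9% for ²¹⁴Bi. Tests
assert this overshoot rather than exact equality.

## Exposure metrics

EEC weights (0.1065, 0.515, 0.379) and the potential-alpha-energy
coefficients are linked: the weights are the coefficients normalized by
their sum. That forces the ²¹⁴Bi coefficient to 13120 (0.379 × 34640);
the widely reprinted 113120 variant is selectable
(`bi214_coefficient=...`) but triggers a warning, since it is inconsistent
with the weights by a factor ~10. `f_un` is the EEC-weighted unattached
share; `x_un` weights by atom numbers (`C/λ`), which emphasises the
long-lived ²¹⁴Pb. Records with all-zero progeny raise an error rather
than yielding zero — silent zeros would bias time-series geometric means.
The inverse predictor `f_un ≈ 400/C_tot` is exposed purely as a
diagnostic; the pipeline reports its residual against measured f_un and
never substitutes it.

## Size distributions

Grids are 44 log-spaced channels over 5–350 nm ("medium") or 10–1100 nm
("long"). Bin edges sit at geometric midpoints of adjacent channel
centres, extrapolated log-uniformly at the ends; dN/dln d is channel
counts over Δln d. d_GM is number-weighted over raw channel counts (the
instrument's weighting convention is not documented; this is the adopted
choice). A channel belongs to "< cut" iff its centre diameter is strictly
below the cut, so `C(<cut) + C(>cut) = C_tot` always. Surface areas
assume spheres (π d² per particle) — the minimal shape assumption.
GM/GSD summaries drop non-positive values and report how many were
dropped; GSD uses the sample (ddof = 1) standard deviation of ln x.
Cross-stream correlation averages both series onto half-hour bins
(label = interval start, half-open windows) before Pearson's R.

## Gross-alpha counting model

Sampling: 6 min at 2.4 dm³ min⁻¹; the deposit ingrows *during* pumping
(constant source + decay, solved with the matrix exponential:
N(T) = M⁻¹(e^{MT} − I)s), not as an instantaneous deposit. Counting:
three intervals within 110 min after pumping, defaults (0–30), (30–70),
(70–110) min — the true instrument boundaries are not public, and these
give contrast between the ²¹⁸Po-dominated and ²¹⁴Po-dominated epochs.
Expected counts are `eff × ∫(λ_Po218 N_Po218 + λ_Bi214 N_Bi214) dt` with
the integral exact via `∫N dt = M⁻¹ ΔN`. Counts are linear in the three
airborne activities, so inversion is a 3×3 solve; with a square system
the Poisson-weighted least-squares estimate coincides with it.
Uncertainties propagate Var(counts) = counts through D⁻¹; negative
estimates are clipped to zero and flagged; the design-matrix condition
number is reported (default schedule: ~76). Default efficiency 0.25 —
it cancels in round trips. The proprietary interval-deconvolution used by
real firmware is not public; this linear reconstruction is a documented,
self-consistent stand-in.

## Room model

Per nuclide i with parent p, unattached (u) and attached (a) atom pools
(cm⁻³, rates h⁻¹):

```
du_i/dt = q_i + λ_p u_p + r_i λ_p a_p − (λ_i + λ_v + λ_d^un + βS) u_i
da_i/dt = (1 − r_i) λ_p a_p + βS u_i − (λ_i + λ_v + λ_d^att) a_i
```

q is radon's decay rate (all newborn ²¹⁸Po is unattached); r is the
recoil probability, nonzero only for ²¹⁴Pb born by the ²¹⁸Po *alpha*
decay (beta decays do not detach). Attachment is β·S_tot with S_tot the
total spherical surface area — a single coefficient, not a size-resolved
kernel; that is the minimal model in which surface area, not particle
number, controls f_un (two spectra with equal number but different
surface give different steady f_un). A size-resolved attachment kernel is
the natural extension point.

Defaults (h⁻¹ unless noted): λ_v = 0.3 closed / 3.0 open window;
λ_d^un = 20 (cluster-sized species deposit fast); λ_d^att = 0.2;
r = 0.5; radon fixed at 229 Bq m⁻³ (entry-rate mode available);
β = 1.3·10⁻⁷ per nm² cm⁻³, chosen from the closed-form balance so the
quiescent steady state gives f_un = 0.157, inside the 0.09–0.28 band
quiescent indoor campaigns report.

The aerosol spectrum relaxes (κ = 10 h⁻¹) toward a lognormal baseline
mode (CMD 57 nm, mode GSD 1.8) whose *total* follows a seeded stationary
geometric Ornstein–Uhlenbeck process (GM 5120 cm⁻³, stationary GSD 1.50,
mean-reversion θ = 2 h⁻¹ ≈ 30 min correlation time), with ventilation
exchange against a fixed outdoor spectrum (6900 cm⁻³, CMD 60 nm,
GSD 1.9). The OU forcing is what makes long quiescent runs reproduce the
configured GM/GSD; the κ-filter attenuates the log-variance by
κ'/(κ'+θ), a ~3% GSD bias at the defaults, and a 120 h run recovers
GM and GSD within 5%. Setting the baseline GSD to 1 freezes the forcing
and makes the whole run deterministic — that is the configuration used
for steady-state and limit tests.

Events inject lognormal modes at a rate sized so the quasi-steady
increment equals the configured peak magnitude: toaster 3·10⁵ cm⁻³ at
15 nm, cooking 5·10⁴ at 12 nm, candle 1.32·10⁶ at 10 nm, boiling
3·10⁴ split over 25 and 85 nm (bimodal). Window events toggle λ_v.

Integration is fixed-step RK4, dt ≤ 60 s, with piecewise-constant
forcing; sub-zero round-off is clipped (counted in the manifest), and an
excursion beyond −10⁻⁶ of the state scale raises an error suggesting a
smaller step. Runs start from the event-free steady state (or empty
progeny pools with `init="zero"`). Emission: spectrum snapshots every
4 min, progeny records as 2-h window averages labelled by window start,
both with multiplicative lognormal measurement noise (GSD 1.05). One seed
drives the OU path and all noise.

### Step-response delay

`fun_step_response` quantifies how slowly f_un follows a change in
aerosol surface. The relaxation has two timescales: the unattached pools
(loss ≈ λ_i + λ_d^un + βS ≈ 60–90 h⁻¹) settle within minutes, while the
attached ²¹⁴Pb/²¹⁴Bi inventories — which dominate the total-EEC
denominator — settle on their ~30 min mean lives. Consequently the
*midpoint crossing* after a moderate surface step is fast (2–4 min at the
defaults) but the 90% settling time is 50–85 min and the mean relaxation
time (∫|f−f∞|dt / |Δf|) is 16–34 min. The function reports all three;
the invariant asserted in the tests is that the settling and mean
relaxation times exceed 10 min — the model's expression of the claim that
f_un cannot track fast aerosol bursts, which is why short events leave it
almost unchanged even when particle counts rise a hundredfold.

## What the generator does and does not emulate

It reproduces: the two instrument cadences; lognormal quiescent
statistics of the emitted totals; surface-area-controlled attachment with
its delayed f_un response; ventilation/event phenomenology (radon and EEC
drop when the window opens; particle bursts barely move f_un). It does
not model: coagulation or condensational growth (events decay by
relaxation/ventilation only), nucleation chemistry, spatial gradients,
humidity-dependent neutralisation, or charge states. Passing tests
therefore validate the pipeline's arithmetic and the qualitative kinetic
structure, not instrument physics or real-room microphysics.

## Pipeline conventions

Timestamps are ISO-8601, timezone-naive local time. Alignment windows are
half-open [start, end); 2-h progeny records are attributed to their
collection window's start; the finer stream is averaged onto the coarser
grid. QC accounts for every record (cadence inferred from the median
spacing; gaps > 1.5× cadence listed; negative/zero records counted).
Event segmentation uses 2-h pads before and after each annotated window
and reports per-phase geometric means. Summary tables report min, max,
GM, GSD (plus retained/dropped counts) for the nine canonical indoor
parameters. Report generation is pure: identical inputs and configuration
give byte-identical outputs.

## Problem sizes

Test and acceptance runs use 4–48 h simulations at 30–60 s steps, one
120 h quiescent run for the GM/GSD-reproduction check, 10⁴ draws for
lognormal parameter recovery, and 500 Poisson replicates for the counting
round trip — sizes at which every stochastic check sits well inside its
tolerance while the whole suite stays quick.
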
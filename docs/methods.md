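# Methods

## The reaction scheme and what is being computed

The compass model is a cyclic photoreaction. A photoreceptor P is excited
and forms the primary radical pair RP1 in the electronic singlet state at a
rate R₀. RP1 then either (a) converts, spin-independently and irreversibly,
into a secondary pair RP2 with rate constant k_f — the branch that leads to
the biological signalling state — or (b) recombines through a singlet-only
regeneration reaction with rate constant k_r, restoring the inactive
receptor. Because the regeneration reaction removes only singlet pairs, the
branching ratio between (a) and (b) depends on how much singlet→triplet
interconversion the pair's coherent spin dynamics produces before reaction,
and that interconversion is anisotropic in the geomagnetic field. The fate
of RP2 itself is not modelled: whether RP2 reacts from its singlet state
(with spin relaxation feeding triplets back), from its triplet state, or
spin-independently, all RP2 population ends in the signalling product, so
the RP2 formation rate *is* the signalling rate and no RP2 spin dynamics is
required.

The observable is the steady-state RP2 formation rate as a function of the
angle Θ between the molecular frame (defined by the hyperfine anisotropy)
and the field. A single polar angle suffices because the reference
hyperfine tensor is axially symmetric.

## Spin system and Hamiltonian

Each radical carries one unpaired electron and one spin-1/2 nucleus; the
Hilbert space is 2⁴ = 16 with the fixed ordering e1 ⊗ e2 ⊗ n1 ⊗ n2 (any
consistent ordering works; fixing one makes matrices bit-comparable across
runs). The Hamiltonian is stored in angular-frequency units,

    H(Θ) = (μB/ħ)[g₁ B·S₁ + g₂ B·S₂ + g₁ S₁·A₁·I₁ + g₂ S₂·A₂·I₂],

with ħ = 1.054571817×10⁻³⁴ J·s, μB = 9.2740100783×10⁻²⁴ J/T, g₁ = g₂ = 2,
and hyperfine tensors in tesla (1 mT ↔ 1.7588×10⁸ rad/s). Storing H in
rad/s removes ħ from the Liouvillian so all reaction rate constants stay in
s⁻¹. Omitted on purpose: the nuclear Zeeman interaction (three orders of
magnitude below the electronic one at 50 μT), and exchange and
dipole–dipole couplings between the radicals (assumed to cancel, as they can
at 18–22 Å separation); there are no hooks for them.

Two named spin systems are built in:

| preset | A₁ (mT) | A₂ (mT) | behaviour |
|---|---|---|---|
| `reference` | diag(1, 1, 0) | 0.5 isotropic | smooth anisotropy, tunable width |
| `avoided_crossing` | diag(−0.0989, −0.0989, 1.7569) | diag(0, 0, 1.0812) | level avoided crossing → sub-degree spike in the singlet yield |

## Steady state and dimensionless rates

The spin density matrix obeys

    dρ/dt = R₀ Q_S/Tr(Q_S) − i[H, ρ] − (k_r/2){Q_S, ρ} − k_f ρ,

with Q_S = ¼·1 − S₁·S₂ the singlet projector (trace 4) and the reaction
terms in Haberkorn anticommutator form. The source is normalised by
Tr(Q_S) so the total population inflow is exactly R₀; this is what makes
the k_r = 0 limit give R ≡ 1 (see below). The steady state solves the
256-dimensional linear system L vec(ρ) = −vec(R₀Q_S/4) with column-stacking
vectorisation; at this size a dense LU solve is fastest and simplest. The
LU factors feed a LAPACK 1-norm condition estimate (solve refused above
10¹²) and the residual ‖L x + source‖ is checked against 10⁻⁸‖source‖.
Since k_f drains all of Liouville space, every eigenvalue of L has real
part ≤ −k_f and a unique steady state exists for any k_f > 0; k_f = 0 is
rejected (population would grow without bound).

Rates are normalised by the classical, no-mixing product rate
R_cl = R₀k_f/(k_f+k_r):

    R = k_f Tr(ρ)/R_cl,  R_S = k_f Tr(Q_S ρ)/R_cl,  R_T = k_f Tr(Q_T ρ)/R_cl.

R counts the effective number of spin conversion channels opened by the
magnetic interactions: one singlet and three triplet channels, so R_T ≤ 3,
and the exact trace-balance identity R_S = 1 − R_T·k_f/(k_f+k_r) (flux in =
flux out) ties the two channels together at every solved point. Useful
limits, all exercised by tests:

* k_r = 0: nothing is spin-selective, Tr(ρ) = R₀/k_f and R ≡ 1 at every
  orientation (to solver precision).
* k_r ≫ k_f: the singlet channel saturates, R_S → 1, and all anisotropy
  lives in R_T; at k_f = 10⁶, k_r = 10⁹ s⁻¹ the maximum of R_T over Θ is
  1.809, and at k_f = 10³ s⁻¹ it reaches 2.991 at Θ = 90°, essentially the
  three-channel limit.
* R and ρ are exactly linear in R₀, so all dimensionless quantities are
  R₀-independent.

## Relative response and precision metrics

The readable signal is the relative change
R_relative(Θ) = 100·(R_max − R(Θ))/R_max. The metric definitions,

    efficiency      = 100·(R_max − R_min)/R_max
    directionality  = 100·(⟨R⟩_Θ − R_min)/(R_max − R_min)
    optimality      = max(0, efficiency·(2·directionality − 100)/100),

are anchored by their limiting cases: efficiency is the largest value
R_relative can attain; directionality is 50% when the orientation average
sits midway between the extremes (broadest possible signal) and approaches
100% when the response hugs R_max except for a narrow dip; optimality
vanishes for the broadest distribution and grows with both amplitude and
sharpness. The directionality form is the unique affine function of
(⟨R⟩, R_min, R_max) satisfying both anchors; the optimality form is the
simplest product satisfying its two anchors and is isolated in one function
so it can be swapped out. ⟨R⟩_Θ is the unweighted mean over the uniform Θ
grid on [0°, 180°] (the quantity as plotted, with no sin Θ solid-angle
weight). The default grid is 0–180° in 1° steps; the response is symmetric
about 90° for the axial reference tensor, and all metrics are invariant
under grid reversal.

A note on the "flat outside ±20°" behaviour at k_f = 10³ s⁻¹: the computed
curve is within 1% of its plateau (maximum) value everywhere farther than
25° from its minimum, but it still drifts by ~2.5% of its full min–max range
out to ~40°; the property test therefore pins the deviation from the plateau
value, which is the claim's operational content (a bird sees no signal
change there), not the fraction of the full range.

Known limitation: at k_f = 10⁶ s⁻¹, k_r = 10⁹ s⁻¹ the maximum relative
change computed here is 7.9%, not above 10% as for the four slower forward
rates (22–31%); the >10% statement holds for k_f ≤ 10⁵ s⁻¹ on this exact
parameter set.

## Cycle amplification

If one photocycle commits the receptor to signalling with probability p_f
and regenerates it with p_r = 1 − p_f, the probability of signalling within
λ excitations is 1 − p_r^λ — monotone in both arguments, so small
orientation-dependent changes in p_f are amplified by cycling. This is an
analytic statement; λ is not fitted to anything.

## Migration Monte Carlo

The clock-and-compass model: each bird, each day, draws one heading from the
compass distribution about the migratory direction and advances a fixed
200 km along it; it finishes on the first whole day its along-axis distance
reaches 4700 km (no partial days; headings beyond ±90° are allowed, the
termination rule alone guarantees coverage). Defaults — 200 km/day, 4700 km,
10000 birds, heading σ of 20° (observed nightly-heading scatter) and 45°
(a degraded compass) — describe a typical songbird autumn migration.

For numerical work the heading model is a wrapped normal with standard
deviation σ, the form in which behavioural observations are reported;
`heading_from_response` alternatively converts a computed R_relative curve
into a tabulated density (mirrored onto signed deviations, inverse-CDF
sampled), which ties the microscale to the macroscale but is axial — the
spin dynamics cannot tell a heading from its reverse, so the tabulated
density has antipodal lobes and its width is reported with the doubled-angle
axial convention. Resolving the head/tail ambiguity (in real birds, by the
inclination compass) is outside the model.

Randomness discipline: one root `SeedSequence` per ensemble, one spawned
child stream per bird, so enlarging the ensemble never reshuffles earlier
birds and entire ensembles are bit-reproducible from (seed, config,
distribution).

Expected behaviour, used as oracles: the continuous crossing time has mean
≈ target/(daily·exp(−σ²/2)) (mean daily along-axis progress of a wrapped
normal), with whole-day counting adding at most one day; the final-bearing
spread follows the central-limit estimate σ/√(mean days) to within ~15% for
σ ≤ 30°, and is close to proportional to σ overall. Raising σ from 20° to
45° lengthens the mean trip by ≈ 28% (with mean trips of ≈ 25.5 and 32.6
days at n = 10000).

## Problem sizes and tolerances

Orientation sweeps use 181 steady-state solves (1° grid); the
avoided-crossing spike tests refine to 0.25° over 80–100°. Steady-state
residual tolerance 10⁻⁸ relative, Hermiticity/PSD tolerances 10⁻¹⁰,
condition threshold 10¹². The ODE cross-check integrates the matrix-form
equation of motion (DOP853, rtol 10⁻¹⁰) to t = 40/k_f, where the slowest
Liouvillian mode has decayed to ~10⁻¹⁷, and agrees with the linear solve to
~10⁻¹¹ relative (asserted at 10⁻⁶); its random parameter draws use
k_f ∈ [10⁶,10⁷] s⁻¹ so the stiff integration stays cheap. Flight statistics
in tests use 2000–4000 birds per condition (Monte Carlo standard error on
mean days < 0.02 days); the headline 20°→45° comparison uses the full 10000
birds, where its standard error is ≈ 0.1 percentage points.

## What the model does not capture

Real cryptochromes have many coupled nuclei with rhombic tensors, electron
spin relaxation, and exchange/dipolar couplings; rates here are effective
parameters, not measured ones. The flight model omits wind drift, stopovers,
mortality, map-based course correction and all non-magnetic compasses.
Passing tests show the internal consistency of this idealised model and its
stated limits, not quantitative agreement with any particular bird or
protein.
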
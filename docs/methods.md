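# Methods

## Physical model

The simulated object is the *active* SABRE complex IrHHPyr: two
hydride protons delivered by parahydrogen, the ¹³C and the three methyl
protons of bidentately bound 1-¹³C-pyruvate. Free pyruvate is not
simulated: at the low temperatures the experiment emulates, pyruvate does
not dissociate on the relevant timescale, so the observable polarization
lives on the bound species. Values "averaged over free and bound pyruvate"
are obtained from bound values by dividing by the bound-fraction factor 10;
an additional empirical simulation-to-experiment scale (0.38 for ¹³C, 3.4
for ¹H) is available in the reporting layer. Both are pure reporting
arithmetic and never feed back into the dynamics.

### Hamiltonian

Lab frame, in Hz (2π enters only in the propagator):

    H = − Σᵢ ν₀ᵢ I_zᵢ + Σ_{i<j} J_ij Iᵢ·Iⱼ + H_drive(t),
    ν₀ᵢ = γᵢ B₀ (1 + δᵢ·10⁻⁶).

All scalar couplings are kept non-secular. The CW drive is a linearly
oscillating transverse field; its amplitude parameter is the *nutation
frequency on the target isotope* (circular component), so the lab-frame
term carries a factor 2 and scales as γᵢ/γ_target on other spins.

In the doubly rotating frame each isotope rotates at its own reference
frequency — the drive frequency for the target isotope, the bare Larmor
frequency otherwise. Counter-rotating drive terms are dropped (RWA, valid
to ~ν₁/4ν₀ ≈ 2·10⁻³ here) and heteronuclear flip-flop terms are truncated
to I_z S_z. The truncation validity scale is the *largest coupling touching
either spin of the pair*, not only their mutual J: the SHEATH anticrossing
mixes flip-flop states through J_HH even though the direct hydride–carbon
coupling is only 0.06 Hz. With the default safety factor 100 the rotating
frame is accepted at 121 μT (separation ≈ 3.86 kHz against a threshold of
100 × 10.5 Hz = 1050 Hz) and refused at sub-μT SHEATH fields, which are
integrated in the lab frame.

### Exchange

Hydrogen exchange is the deterministic first-order term
(1/τ_Ir)(R(ρ) − ρ) with the replacement map R(ρ) = σ_fed ⊗ Tr_pair(ρ).
R is completely positive, trace preserving and idempotent, so the flow
preserves trace, Hermiticity and positivity exactly; tests assert this
numerically over 10 s. The fed state is
f|S⟩⟨S| + (1−f)/3 Σᵢ|Tᵢ⟩⟨Tᵢ| with f = 1 by default (≈100 % parahydrogen);
f = 1/4 is thermal hydrogen and produces no transfer. Transient complex
intermediates are not modeled, and substrate exchange is absent by
construction. A uniform damping term toward the maximally mixed state
(rate 1/T₁) is available but **off** by default — the experimental
comparison is instead handled by the post-hoc reporting scale.

### Propagation

The rotating-frame generator is time-independent, so states are propagated
by sparse Krylov exponential action (`expm_multiply`) on vec(ρ); for the
six-spin system the superoperator is 4096 × 4096 with ~2·10⁴ nonzeros and
one 10 s propagation takes ~0.3 s. Dense `expm` is used below dimension 16
and as a cross-check (the two paths agree to 10⁻⁹ on the three-spin
fixture). Lab-frame propagation under a drive exploits the periodicity of
the generator: the propagator over one drive period is assembled from
piecewise-constant midpoint steps (≥ 50 steps per period of the fastest
Larmor frequency, bounding the Magnus error) and raised to the number of
whole periods by binary exponentiation. Rotating- and lab-frame engines
agree within 0.02 % on frame-invariant observables after 1 s of CW at the
matching condition; the regression test allows 1 %.

Steady behavior is always probed by finite-time propagation (the
experiment's t_hyp grids), never by null-space solving: the exchange
generator has slow near-degenerate modes and only finite-time values are
physically reported.

## Observables and readouts

Polarization is normalized so a fully polarized spin-1/2 gives 1:
p = 2⟨I_axis⟩, and two-spin order is 4⟨I_z S_z⟩. Three readout schemes are
emulated with ideal instantaneous pulses:

* direct transverse detection of the x-polarization along the CW field,
* crusher (projection onto the Zeeman product-basis diagonal — the
  ideal-gradient limit) followed by 90° pulses for z-magnetization,
* SEPP: crusher, 90° on ¹H only, 180° on both channels, converting
  ¹³C–¹H zz order into in-phase proton signal.

Spectra emulate broadband pickup as a γ-weighted sum of I_x − i I_y over
detected isotopes while the state evolves under the full generator, so
exchange broadening/collapse emerges from the dynamics rather than from a
lineshape formula. Default apodization adds 0.1 Hz of Lorentzian width —
small enough that exchange, not windowing, dominates the collapse fixtures.
Eigenmodes contributing less than 10⁻⁶ of the leading FID amplitude are
discarded before the Nyquist check. With τ_Ir = 31 ms the 1.2 Hz multiplet
of a carbon coupled to exchanging protons collapses to one line, matching
the rule that couplings below ~1/τ_Ir are unresolvable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| J_HH | −10.5 Hz | hydride–hydride coupling; sets the SLIC amplitude |
| J_HC | 0.06 / 0 Hz | hydride–¹³C couplings; ΔJ_CH/4 is the transfer element |
| J_C–H₃ | 1.2 Hz | carbon–methyl coupling |
| τ_Ir | 31 ms | complex lifetime; sets exchange rate and scan peak width |
| B₀ | 121 μT | static field (LIGHT-SABRE) |
| SHEATH field | 0.36 μT | polarization field for lab-frame SHEATH runs |
| f | 1.0 | singlet fraction of fed hydrogen |
| t_hyp | 10 s | hyperpolarization time for the scan protocols |
| γ_H, γ_C | 42.577, 10.7084 MHz/T | gyromagnetic ratios (configurable) |

Scan grids default to ν_A ∈ [2, 20] Hz in 0.5 Hz steps and
Δν ∈ [−15, 15] Hz in 0.3 Hz steps. Hydride chemical shifts are set to 0 and
2 ppm: only their 2 ppm difference is physical, and at 121 μT it amounts to
≈ 0.01 Hz — negligible but retained.

## Synthetic data

The generators emulate the statistical structure of the experimental
observables, not the hardware: mono-exponential build-up (plateau 1.1 %
averaged basis; time constants 25.8 s LIGHT-SABRE and 15.8 s SHEATH; 12
points over [0, 80] s) with i.i.d. Gaussian noise of σ = 5·10⁻⁴, scan maps
with i.i.d. per-point noise at 2 % of the map maximum (chosen to resemble
the visible scatter of experimental scan points; the single-shot spectral
SNR > 8000 implies per-point noise far below the shot-to-shot variation),
and spectra as Lorentzian sums with white noise scaled to a stated SNR.
Gaussian i.i.d. noise is the simplest model consistent with the available
information; real data would add drift from sample degradation, temperature
effects and correlated baseline structure, so passing the recovery tests
here demonstrates correctness of the estimators, not robustness to every
experimental nuisance. All generators are pure functions of (parameters,
seed).

## Numerical choices

* Tolerances: state invariants at 10⁻⁸ absolute; observable comparisons at
  10⁻⁶ unless a test states otherwise; the analytic 2×2 blocks match the
  projected full Hamiltonian to 10⁻¹⁰.
* Build-up fitting is unweighted least squares of p(t) = p_max(1 − e^(−t/T))
  with no offset term by default (curves start at 0 by construction; an
  offset is available). Initialization: p_max from the last sample, T from
  the (1 − 1/e) crossing; T bounded to (0, 10 t_max]. Standard errors come
  from the Jacobian covariance. The fit is deliberately strict about
  degenerate input (< 3 distinct times, all-zero curves).
* Transfer linearity in the singlet excess (f − 1/4) holds to first order in
  the transfer amplitude; the second-order feedback of generated carbon
  order contributes ~3·10⁻⁴ relative and sets the test tolerance (1 %).
* The acceptance script reports build-up recovery as the mean over 40
  seeded replicates: a single 12-point replicate carries ~11 % sampling
  scatter on T, while the replicate mean isolates the estimator's bias
  (< 2 %).

## Design choices made where the design was open

* The matching analysis treats the 2×2 blocks in Hz throughout (the 2π
  appears only in propagation), with positive offset meaning a drive above
  the carbon Larmor frequency; the odd symmetry of the z-map fixes the
  remaining sign.
* The full six-spin system is used for every grid point of the headline
  scans; the three-spin reduction (two hydrides + carbon) is a test fixture
  and oracle, not the production model.
* The ideal magic-angle pair (6.06, 8.57 Hz) and the full-simulation z-map
  extrema (≈ ±6 Hz at ν_A = 11 Hz) differ slightly; the full simulation is
  authoritative and no agreement is forced between them.
* Detection weighting of the broadband spectrum emulation is configurable
  per isotope; it affects spectral cosmetics only, never polarization
  numbers.

## Known limitations

* No relaxation superoperator beyond the optional uniform damping; measured
  polarization magnitudes are matched only through the empirical reporting
  scale.
* Pulses are ideal and instantaneous; shaped RF, pulse miscalibration and
  gradient physics are out of scope (the crusher is an exact diagonal
  projection).
* Field switching between polarization and detection is instantaneous; no
  transport dynamics or temperature dependence of exchange rates.
* Spins are restricted to spin-1/2 (¹H, ¹³C); quadrupolar nuclei and ¹⁵N
  targets are not handled.
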
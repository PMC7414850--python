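# Methods

This note documents the models implemented in `clhom`, their assumptions,
the parameters that matter, the calibration and numerical choices, and what
the synthetic-data generators do and do not emulate.

## Ionic conditions and unit conventions

Concentrations are millimolar (numerically mol m⁻³), voltages millivolts,
KCC2 flux µmol m⁻² s⁻¹, currents picoamperes.  "Permeability" is whole-cell
(permeability × membrane area, m³ s⁻¹) so GHK expressions return currents.
A positive anion current means anion influx — the direction that raises
[Cl⁻]ᵢ; because the carrier is an anion this is simultaneously an outward
(hyperpolarizing) current in the conventional electrical sense.

Two named condition presets ship with the package and deliberately differ,
mirroring the two experimental contexts:

* `recording_acsf` — used for all E_GABA ↔ [Cl⁻]ᵢ conversions: extracellular
  Cl⁻ 136.5 mM (the full recording-solution recipe: 126 NaCl + 2.5 KCl +
  2 MgCl₂ + 2 CaCl₂), HCO₃⁻ 26 mM outside / 16 mM inside, 25 °C
  (RT/F = 25.693 mV).
* `point_model` — used by the dynamic simulator: extracellular Cl⁻ 120 mM,
  HCO₃⁻ 30 mM outside / 15 mM inside.

The two HCO₃⁻ pairs (26/16 vs 30/15) are both used as stated by their
respective contexts; no attempt is made to reconcile them.  Temperature is
configurable per `IonConditions`.

## KCC2 transport law

J = V_max·x/(1+x) with x = ([Cl⁻]ᵢ − [K⁺]ₒ)/12 mM.  With [K⁺]ₒ at its 3 mM
resting value the flux is null at [Cl⁻]ᵢ = 3 mM and half-maximal at 15 mM.
Below the null point the formula would predict reverse transport; the
implementation clamps the flux at zero there, since reverse-mode operation
is outside the validity of this saturating form.  The static (fixed
null-point) variant is used wherever extracellular K⁺ is not modelled
(the spatial load model, the voltage-clamped load scenario).

## Pipette Cl⁻-load model (`spatialsim`)

An axisymmetric one-dimensional finite-volume chain replaces the original
three-dimensional finite-element geometry:

* pipette: truncated cone, tip ⌀1.2 µm, back ⌀22 µm, length 120 µm; the
  back element is a fixed-concentration (Dirichlet) boundary at the pipette
  Cl⁻ (29 mM for the high-load protocol); no membrane flux inside the
  pipette;
* soma: prolate ellipsoid (semi-axes 5.5/10.75 µm for lamina I,
  4.58/7.9 µm for lamina II) sliced along its major axis; each slice's
  membrane area comes from the exact surface-band integral;
* dendrites: the two 1.5 µm × 80 µm cylinders merged into one axial
  compartment of doubled cross-section, sealed at the tip.

Axial coupling uses half-element truncated-cone series conductances
(G = Dπr₁r₂/d per half element), which reproduce the exact cone resistance
of the pipette at any resolution; at region junctions the shared face is the
physical opening (pipette mouth, dendrite stalk), not the pinched-off
ellipsoid pole.  D = 2.03·10⁻⁹ m² s⁻¹ throughout.  The steady state solves
ΣG_ij(c_j−c_i) = A_mem,i·J(c_i) by damped Newton iteration on the
tridiagonal system (banded solver, step halving on residual increase,
relative residual tolerance 1e−10); this replaces the time-marching/damped
fixed-point loop of a naive solver and converges in ~10 iterations.
`fit_vmax` then bisects V_max ∈ [0, 200] to 0.1 µmol m⁻² s⁻¹ on the
(strictly decreasing) somatic volume-weighted mean.

**Where KCC2 sits.**  By default only the somatic membrane extrudes.  A
strict series chain conserves mass: total extrusion equals the diffusive
supply through the pipette cone, G_pip·(29 − c_mouth) with
G_pip = Dπ·r_tip·r_back/L ≈ 351 µm³ s⁻¹, and the mouth concentration cannot
be below the somatic mean.  For the lamina I target (≈20 mM) that caps
supply at ≈3.2·10⁻¹⁵ mol s⁻¹ — enough for a capacity of ≈8 µmol m⁻² s⁻¹
over the somatic membrane, but not for uniformly extruding dendrites as
well, which would absorb roughly half the supply and halve the fitted
capacities.  The original three-dimensional study reported that somatic Cl⁻
under load was insensitive to dendritic extrusion capacity and to dendrite
length, i.e. its fitted capacities were obtained in a regime of negligible
dendritic extrusion; the somatic-only default reproduces that regime (and
makes the dendrite-length insensitivity exact).  Set `dendritic_kcc2=True`
in `build_geometry` for literal uniform extrusion — fitted capacities then
drop to ≈4.3 (LI) / 14.5 (LII) µmol m⁻² s⁻¹.

With the defaults the fits give ≈8.1 (LI, target from E_GABA = −45.9 mV)
and ≈26.1 (LII, −53.2 mV) µmol m⁻² s⁻¹ — both within 30 % of the published
10 and 25 — and a Cl⁻ gradient extending a few tens of µm into the pipette
tip.  The LII/LI ratio comes out at 3.25 rather than the published 2.5:
in this reduction it is pinned by the supply differences
(29 − target: 15.0 vs 9.0 mM), the somatic areas (398 vs 637 µm²) and the
transport saturations at the two targets (0.478 vs 0.586), whose product is
3.2–3.3 regardless of grid or tolerance.  This is a known limitation of the
dimensional reduction.

## Single-compartment dynamic model (`pointsim`)

State: membrane potential V, Morris–Lecar K⁺ gate W, [Cl⁻]ᵢ, extracellular
[K⁺]ₒ, and the two synaptic conductances.  Forward Euler at dt = 0.1 ms
(configurable; halving dt moves steady [Cl⁻]ᵢ by <1 %), transcribed into a
numba kernel that is tested step-for-step against the pure-Python reference
update `step_state`.

* **Synapses.**  Poisson event trains (per-step probability rate·dt) drive
  conductances with instantaneous rise and Euler exponential decay,
  g ← g(1 − dt/τ) + g_unit·δ; τ_inh = 25 ms, τ_exc = 15 ms,
  g_unit = 1 / 0.5 nS.  The GABA_A Cl⁻ permeability is proportional to
  g_inh, calibrated so 1 nS reproduces the ohmic current at the test point
  (V = −60 mV, [Cl⁻]ᵢ = 5 mM); P_HCO3 = 0.25 P_Cl.
* **Spiking.**  Morris–Lecar with g_Na = 2 nS, g_K = 8 nS, V₁ = −40,
  V₂ = 18, V₃ = −30 mV.  The printed V₄ = −30 mV would make the K⁺ gate
  *close* with depolarization; the default uses |V₄| for the canonical
  monotone activation (`as_printed=True` restores the literal form).  The
  gate relaxation τ_W = tau_w_scale·sech((V−V₃)/2V₄) is dimensionless as
  printed and is interpreted in milliseconds through `tau_w_scale`
  (default 1 ms).  With the default cell capacitance (1 µF cm⁻², ≈14 pF for
  the lamina I geometry) the membrane time constant is ~7 ms, so a 1 ms
  gate tracks V quasi-instantaneously and damps regenerative spikes;
  repetitive spiking under strong drive appears for tau_w_scale ≳ 30 ms,
  which is what the spiking tests use.  E_Na (+60 mV), the excitatory
  reversal (0 mV) and the capacitance are unstated in the source
  description and are explicit, documented defaults.
* **Ion dynamics.**  d[Cl⁻]ᵢ/dt = I_Cl/(F·Vol) − Surf·J_KCC2/Vol.
  Extracellular K⁺ occupies one fifth of the cell volume and relaxes to
  3 mM with τ_K = 200 ms; it gains the leak-K (80 % of the 1.2 nS leak),
  voltage-gated K and KCC2 K⁺ effluxes and loses a constant pump import
  equal to 1.5× the resting leak-K current.  The pump current enters *only*
  the [K⁺]ₒ balance: it is the K⁺-import branch of an overall
  electroneutral-ish cycle, and charging the membrane with a constant
  −43 pA would shift the resting potential from the stated −65 mV to about
  −30 mV.
* **Geometry.**  Volume and surface derive from the lamina I/II ellipsoid
  plus two 1.5 µm × 80 µm dendritic cylinders (overridable).

**Extrusion scaling.**  Taken literally, V_max = 10–25 µmol m⁻² s⁻¹ over
this surface-to-volume ratio extrudes 5–12 mM s⁻¹ — three orders of
magnitude above the Cl⁻ influx that realistic synaptic rates produce
(~10⁻³ mM s⁻¹), which would pin [Cl⁻]ᵢ at the null point for any drive.
The simulator therefore carries a dimensionless `extrusion_scale`.  Its
default, 1.07·10⁻³, is the output of a documented calibration
(`calibrate_extrusion_scale`): holding the LI:LII capacity ratio at 10:25,
the scale is set so the LI capacity under baseline drive (1 Hz inhibitory /
1 Hz excitatory) rests at [Cl⁻]ᵢ ≈ 5.5 mM (3000-s run, last-third average,
fixed seed, 5 % tolerance).  The voltage-clamped GABA-load scenario
(tonic permeability calibrated to a 10 pA initial net current at −70 mV,
[K⁺]ₒ fixed, fixed-null-point KCC2) uses the same scale.

Consequences worth knowing: with the calibrated scale, the interlaminar
separation at capsaicin-like drive (5/50 Hz) converges to ≈1.4 mM Cl⁻ and
≈2.4 mV of E_GABA (3000-s runs) — the right direction but smaller than the
published 3–4 mM / 10–15 mV.  The compression is structural: scaling
extrusion down ~1000× while high drive raises influx ~50× shrinks the
relative weight of extrusion, which is what carries the interlaminar
difference.  Raising the scale to keep extrusion competitive at high drive
would violate the baseline 5–6 mM anchor of the calibration.  The tests
therefore gate the direction of these effects, not their magnitude; the
steady-state structural properties (passive distribution at the clamp
potential, convergence to the KCC2 null point without drive, [K⁺]ₒ
relaxation at τ_K) are gated quantitatively.

Problem sizes: the steady-state comparisons integrate 1500 s (capacity-gap
ordering, 3 seeds) or 3000 s (calibration and interlaminar demonstration),
averaging the final third; shorter runs have not equilibrated, since the
Cl⁻ relaxation time at baseline drive is several hundred seconds.

## Analysis operators

* **E_GABA from I–V** — repeats averaged per voltage, ordinary least
  squares, x-intercept, minus the liquid-junction offset (presets: 8 mV for
  the high-Cl⁻, 9 mV for the low-Cl⁻ pipette solution).  Over 500 simulated
  noisy datasets (σ = 2 pA, 8 voltages × 3 repeats) the estimator's bias is
  <0.3 mV and its SD matches the analytic least-squares variance.
* **Train depression** — amplitudes normalized to the first eIPSC; bins are
  3-stimulus means centred on stimuli 5, 10, 15, 20, 25, clipped at the
  train end (the bin at 25 averages {24, 25}); the anchoring is a package
  convention and re-anchorable.  The one-phase decay
  y(n) = plateau + (1 − plateau)·e^(−Kn) is fit with unit initial value;
  a flat train flags the rate as unconstrained, a negative plateau is
  clipped to zero and flagged.
* **Charge transfer** — trapezoidal integral of the baseline-subtracted
  current; the baseline is the mean over a caller-specified pre-stimulus
  window.
* **FLIM** — y₀e^(−t/τ) convolved with the normalized instrument-response
  histogram (delta if absent), unweighted least squares by default
  (Poisson weighting available).  Stern–Volmer conversion with
  K_SV = 32 M⁻¹; the zero-Cl⁻ lifetime defaults to 5.5 ns, a typical
  in-situ value for the MQAE dye, and is a field of the trace.  Lifetimes
  above τ₀ clip to 0 mM.
* **Depth regression** — [Cl⁻] binned every 20 µm along depth; bin means
  regressed against the per-bin mean depth (not the nominal centre, so
  partially filled edge bins do not bias the slope).
* **IB4 axis** — per column, the centre is the intensity⁴-weighted mean row
  ("order 4" read as fourth-power weighting; exponent configurable);
  columns whose total weight falls below 1 % of the image-wide column
  median are excluded (the threshold is a package choice); a quadratic is
  fit to the remaining centres directly, without pre-smoothing.
* **Trans-laminar profile** — per-pixel signed minimum distance to the
  sampled axis curve (positive on the dorsal/superficial side), channel
  means binned at a caller-set spacing.
* **MASC-π** — per-pixel distance to the nearest membrane segment; the
  intracellular side is the left of the polyline traversal direction
  (positive distances).  Binning is per pixel width by default.
* **MAGI** — mean lamina intensity minus mean intracellular intensity,
  after white-matter background subtraction; shift-invariant by
  construction.
* **Immunogold clustering** — single-linkage connected components under the
  65 nm cutoff (transitive closure); classification and percentages are per
  particle, matching the published per-particle counts.  Distances are 2-D
  in the section plane.  Both the clustering and the distance-profile
  binning are verified bit-exact against exhaustive brute-force oracles.

## Synthetic data: scope and limits

The generators reproduce the statistical structure the estimators assume —
linear I–V with i.i.d. Gaussian noise, Poisson photon counting over an
IRF-convolved mono-exponential, a linear dorsoventral intensity gradient
with Gaussian bands and ideal ring cells, Gaussian clusters on a sparse
uniform field, one-phase-decay trains with relative Gaussian noise.  They
do not emulate: correlated or multiplicative recording noise, access
resistance and space-clamp errors, multi-exponential or background
fluorescence decays, anisotropic point-spread blur, tissue autofluorescence,
uneven section staining, or antibody/probe displacement of gold particles.
Passing recovery tests therefore show the estimators are correct and
well-calibrated under their stated noise models — not that those noise
models exhaust real recordings or micrographs.

## Numerical choices and degenerate inputs

Degenerate inputs fail loudly: non-positive concentrations, reversals that
imply non-positive [Cl⁻]ᵢ, zero-slope I–V lines, empty masks, degenerate
polylines, rate·dt > 1, unattainable fit targets.  The GHK singularity at
V = 0 uses a second-order series below 1 µV.  All stochastic code takes an
explicit seed and is bit-reproducible; every generator stores its truth
parameters on the returned object.

## Known limitations

* The spatial model is a dimensional reduction: absolute fitted capacities
  carry ~±30 % headroom and the interlaminar ratio lands at 3.25 vs the
  published 2.5 (analysis above).
* The point model's literal extrusion units are inconsistent with its
  geometry (analysis above); magnitudes that depend on the extrusion scale
  are demonstrations, not predictions.
* No electrodiffusion (voltage gradients) inside the cytosol, no NKCC1 or
  GABA_B, no HCO₃⁻ spatial dynamics, no temperature dependence of
  permeabilities.
* Membrane delineation and cell segmentation are inputs (annotations), not
  computed.
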
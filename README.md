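# clhom — chloride homeostasis in spinal dorsal horn neurons

Synaptic inhibition through GABA_A and glycine receptors depends on the
transmembrane Cl⁻ gradient, which mature neurons maintain with the K⁺–Cl⁻
co-transporter KCC2.  In the superficial dorsal horn of the spinal cord the
Cl⁻-extrusion capacity differs between lamina I and lamina II, but the
difference only becomes measurable when the cells are challenged with a Cl⁻
load — through a whole-cell pipette or through heightened synaptic drive.
`clhom` implements the computational machinery needed to study this regime:
the biophysical models that link extrusion capacity to measurable reversal
potentials, and the analysis operators that quantify the supporting imaging
and electrophysiology experiments.  It is aimed at cellular
neurophysiologists modelling ionic plasticity and at analysts reproducing
laminar KCC2 quantifications.

## What is inside

**`clhom.ionlib`** — stateless primitives.  The GABA_A reversal combines the
Cl⁻ and HCO₃⁻ gradients with a permeability ratio α = P_HCO3/P_Cl = 0.25:

    E_GABA = (RT/F) · ln[ ([Cl⁻]ᵢ + α[HCO₃⁻]ᵢ) / ([Cl⁻]ₒ + α[HCO₃⁻]ₒ) ]

with its exact inverse `cl_from_reversal` for estimating [Cl⁻]ᵢ from
measured reversals.  Anion fluxes follow the GHK current equation, and KCC2
transport follows the saturating law

    J_KCC2 = V_max · x / (1 + x),   x = ([Cl⁻]ᵢ − [K⁺]ₒ) / 12 mM,

which is null at [Cl⁻]ᵢ = 3 mM and half-maximal at 15 mM (resting
[K⁺]ₒ = 3 mM).

**`clhom.spatialsim`** — a reduced (axisymmetric, finite-volume) model of the
pipette-imposed Cl⁻ load: a truncated-cone pipette held at 29 mM Cl⁻ feeds a
prolate-ellipsoid soma (lamina-specific semi-axes) and merged dendritic
cylinders; KCC2 extrudes Cl⁻ from the somatic membrane.  `fit_vmax` bisects
V_max until the steady somatic mean matches the concentration implied by a
measured E_GABA — this is how per-lamina extrusion capacities are estimated.

**`clhom.pointsim`** — a single-compartment dynamic model (forward Euler,
dt = 0.1 ms, numba-compiled) of membrane potential, [Cl⁻]ᵢ and
extracellular K⁺ under Poisson synaptic bombardment, with Morris–Lecar
spiking, GHK-based GABA_A currents and KCC2 extrusion coupled to [K⁺]ₒ.

**`clhom.ephys`** — E_GABA from GABA I–V relations (x-intercept of the
least-squares line, junction-potential corrected), [Cl⁻]ᵢ estimation,
eIPSC train depression metrics (normalize, bin, one-phase decay fit) and
charge-transfer integrals.

**`clhom.imaging`** — FLIM lifetime fitting with optional IRF convolution
and Stern–Volmer conversion (τ₀/τ = 1 + K_SV[Cl⁻], K_SV = 32 M⁻¹),
[Cl⁻]-vs-depth regression, the IB4 barycentric laminar axis and
trans-laminar intensity profiles, the MAGI membrane index, the MASC-π
membrane-distance profile, and immunogold oligomer analysis by 65 nm
transitive clustering.

**`clhom.synthdata`** — seeded generators for every input type (noisy I–V
lines, Poisson photon decays, laminar images with ground-truth annotations,
clustered point fields, eIPSC trains), each carrying its truth parameters
for recovery testing.

## Worked example: extrusion capacity from a measured reversal

```python
from clhom import ionlib, spatialsim

cond = ionlib.get_conditions("recording_acsf")          # 136.5 mM Cl-, 26/16 mM HCO3-
print(ionlib.gaba_reversal(cond.with_cl_in(29.0)))      # -37.67 (theoretical E_GABA, mV)

target = ionlib.cl_from_reversal(-45.9, cond)           # 19.96 mM somatic Cl- in LI
chain = spatialsim.build_geometry("LI", resolution=1.0)
vmax = spatialsim.fit_vmax(chain, ionlib.KCC2Params(vmax=1.0), 29.0, target)
print(vmax)                                             # 8.06 umol m-2 s-1
```

The first number is the theoretical reversal under the 29 mM load: if the
cell did not extrude Cl⁻, E_GABA would sit at −37.7 mV.  A measured mean of
−45.9 mV therefore implies active extrusion holding somatic Cl⁻ near 20 mM,
and the diffusion model finds the extrusion capacity (≈8 µmol m⁻² s⁻¹)
that sustains that balance against the pipette load.  Running the same fit
for lamina II (E_GABA = −53.2 mV) gives ≈26 µmol m⁻² s⁻¹ — roughly a
three-fold stronger extrusion in the deeper lamina.

The same fit is available from the shell:

```sh
clhom spatialsim fit --lamina LI --egaba -45.9 --out li.json
# LI: Vmax = 8.06 umol m-2 s-1 (somatic Cl 19.95 mM)
```

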
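# Methods

`retistim` models how transcorneal electrical stimulation (TES) of the rat
eye recruits retinal neurons, at desk scale. The pipeline has three layers:
a quasi-static volume conductor for the head and eye, conductance-based
multi-compartment models of two retinal neurons, and a threshold engine
that ties them together. A separate closed-form module implements the
Shannon electrode-safety calculation. This note records the model content,
the numerical choices, and what the defaults do and do not represent.

## Volume conductor (admittance method)

The head is a 20 × 20 × 20 mm block of tissue voxels at 0.2 mm spacing
(101³ nodes). Concentric shells of skin (0.6 mm), fat (0.6 mm) and
cancellous bone (0.8 mm) line the block boundary; brain fills the
posterior interior; muscle fills the rest. A layered spherical eye
(diameter 6.3 mm) is embedded with its corneal pole at the anterior face:
a 0.3 mm cornea cap (50° half-angle), a 3.5 mm lens, vitreous, and a
0.2 mm retina shell. The retina is homogeneous at 1.5 Ω·m; all tissue
resistivities ship with the package and are config-overridable. A sealing
pass relabels any interior eye voxel that touches extra-ocular tissue so
the retina/cornea shell is watertight at one-voxel thickness.

Nodes sit at voxel corners. Adjacent nodes through material of
resistivities ρᵢ, ρⱼ at spacing h are joined by two half-voxel resistors
in series, G = 2h/(ρᵢ + ρⱼ). Exterior faces are open circuits (body in
air). The nodal system G·V = I is solved once per electrode configuration
for ±1 A spread uniformly over the stimulating and return node sets
(conjugate gradient, Jacobi preconditioning, relative residual ≤ 10⁻⁸;
dense direct solve below 10⁴ nodes). Because the tissue model is purely
resistive, the field for any stimulus waveform is the unit solution scaled
by the instantaneous current (quasi-static assumption). Potentials at
arbitrary points come from trilinear interpolation of node values.

Electrodes are equipotential current-injection node sets, not meshed
conductors: a ring maps to the nodes within half a spacing of its torus
centerline circle, a needle to the nodes along its exposed shaft. Two
named placements are built in:

* **TES1** — stimulating ring on the temporal side of the eyeball, return
  ring on the nasal side (lateral current path);
* **TES2** — stimulating ring on the cornea, needle return on the
  temporal side of the head (current driven through the eye, along the
  retinal depth).

The reference node (ground) is the return-set centroid node. Splitting
the current equally across electrode nodes rather than enforcing an
equipotential metal surface is a simplification adequate at this
resolution; it is listed under limitations.

## Retinal neuron models

Both cells are placed in a curved retinal frame — arc-length coordinates
on the spherical retina at fixed depth below the outer surface — anchored
one voxel (0.2 mm) temporal of the posterior pole. The offset is the
smallest that breaks the exact mirror symmetry of the TES1 electrode pair
about the eye axis; exactly on the axis the TES1 potential is zero by
antisymmetry and a radial cell would see no drive at all. The curvature
matters for the ganglion cell: a straight 1 mm tangent line would leave
the 0.2 mm retina shell roughly 0.8 mm from the soma.

**Spiking (DB4-type) cone bipolar cell.** A five-region chain along the
retina depth axis — dendrite (10 µm), soma (10 µm diameter), axon
(35 × 1 µm), presynaptic terminal (5 µm), terminal (5 µm); 65 µm total,
dendrite at the outer plexiform layer (70 µm depth). Membrane capacitance
1 µF/cm², intracellular resistivity 100 Ω·cm, uniform leak 0.033 mS/cm².
Channel densities per region (mS/cm²): Na 1000 and fast K 2 on the axon,
slow K 0.6/2.4 on soma/dendrite, T-type Ca 1 on soma and dendrite, L-type
Ca 1 and HCN 3.25 on the presynaptic terminal.

**A2 retinal ganglion cell.** 20 µm soma in the ganglion-cell layer, a
planar symmetric bifurcating dendritic arbor spanning 320 µm, and a
1000 µm axon in the nerve-fiber layer running temporally, subdivided into
axon hillock (40 µm, tapering 2→1 µm), sodium-channel band (40 µm),
narrow segment (90 µm, 0.4 µm diameter) and distal axon (830 µm).
Membrane capacitance 1 µF/cm², intracellular resistivity 110 Ω·cm,
uniform leak 0.05 mS/cm² reversing at −60 mV. Channel densities ship in
S/cm² with the derived rows g_K,A = 3·g_K (everywhere) and
g_K,Ca = 0.004·g_K (soma, dendrites) resolved at load time.

Sections are discretized into compartments no longer than 5 µm (bipolar)
or 20 µm (RGC); both are far below the smallest electrotonic space
constant involved (> 400 µm even for the 0.4 µm narrow segment), and the
compartment-refinement and timestep tests check convergence directly.
Membrane area uses the frustum rule πL(d₀+d₁)/2; a compartment's axial
resistance is Ri·L/(π r₀ r₁), and coupled compartments see the series
half-resistances between midpoints. The soma is an area-equivalent
cylinder (diameter = length).

## Channel kinetics

Channel *densities* are fixed data; channel *kinetics* are configuration,
expressed in YAML as named parametric rate forms (exp-linear,
exponential, sigmoid, Gaussian, constant) per gate, either as (α, β) pairs
or as (x∞, τ) pairs. The shipped RGC registry is the five-conductance
retinal ganglion cell formulation of the Fohlmeister–Miller lineage
(Na m³h, K n⁴, A-type K a³h_A, Ca c³ feeding a single calcium pool,
Ca-dependent K slaved to the pool with half-activation at 1 µM, power 2),
plus h-current and low-threshold T-type formulations from the retinal
modeling literature. The calcium pool follows
d[Ca]/dt = −k·I_Ca − ([Ca] − Ca_rest)/τ with k = 1.55·10⁻⁵ mM·cm²/(µA·ms)
(a ~0.1 µm submembrane shell), τ = 20 ms, Ca_rest = 10⁻⁴ mM, floored at
10⁻⁶ mM; E_Ca is Nernst from the pool (RT/2F = 13.35 mV at 37 °C,
[Ca]ₒ = 1.8 mM).

The bipolar registry is HH-style. Its Na activation and fast-K rates are
shifted +20…+15 mV relative to the ganglion-cell rates: bipolar sodium
channels activate at more depolarized potentials, and — decisive for this
model — with unshifted rates the 1000 mS/cm² axon carries a sodium window
current at rest that exceeds every available outward current (the axon
has only 2 mS/cm² fast K plus the 0.033 mS/cm² leak) and the cell
self-depolarizes. The +15 mV activation shift with standard inactivation
keeps the axon silent at rest while preserving field-driven regeneration.
The slow K activates near rest (V½ −50 mV, τ 20 ms) and is the main
resting counterweight to the T-type and HCN window currents given the
very small leak. The T-type is low-threshold and slow (activation V½
−60 mV, τ 15 ms; inactivation V½ −81 mV, τ 30 ms), so long pulses recruit
it and the cathodic phase of long biphasic pulses de-inactivates it for a
rebound contribution. All rate constants live in the editable YAML
registries, so alternative published kinetics can be dropped in without
code changes.

## Cable integration

Per compartment, Cm·dVmᵢ/dt = −I_ion,ᵢ + Σⱼ[(Vmⱼ+Veⱼ) − (Vmᵢ+Veᵢ)]/Rᵢⱼ,
with Veᵢ(t) the unit-field value at the compartment midpoint times the
stimulus current — the standard one-way activating-function coupling (no
ephaptic feedback; fields are computed without the cell present).
Integration is operator-split: gates and the calcium pool advance by
their exponential-Euler closed forms (steady states and decay factors
tabulated on a 0.05 mV grid and interpolated), then the linear
membrane/cable part advances by backward Euler with conductances frozen
over the step (dense Cholesky solve; the cells have ≲ 100 compartments).
Defaults: dt = 0.01 ms; settle 400 ms (two time constants of the slowest
gate, the 200 ms HCN — after which the resting drift is below the
10⁻⁴ mV/ms quiescence criterion), run once per cell and cached; initial
state Vm = −65 mV with gates at x∞(−65).

**Spike detection.** Strong extracellular fields polarize a passive cable
by tens of millivolts; at the amplitudes this reduced model requires, the
*passive* deflection alone can cross any fixed voltage threshold. A
spike is therefore an upward 0 mV crossing of the passive-referenced
trace: active Vm minus the deflection of a passive twin (identical
geometry and leak, voltage-gated densities zeroed, same stimulus),
maximized over the sodium-rich detection region (axon for the bipolar
cell, distal axon for the RGC), with a 1 ms refractory window. This
counts only depolarizations beyond the passive response that reach spike
height, and reduces to the plain 0 mV crossing at low amplitudes.

## Thresholds and safety

The activation threshold is the lowest amplitude eliciting at least one
spike, found by doubling from a seed until a spike occurs and bisecting
to a 2% relative bracket; the upper bracket end is reported
(suprathreshold by construction). Strength–duration curves warm-start
each duration at the previous threshold; the default duration grid is
{0.1, 0.3, 1, 3, 10, 25} ms. The default search cap is 10⁶ µA; the
TES1-vs-TES2 ratio experiment raises it explicitly (to 10⁸ µA) because
the bipolar cell's TES1 threshold genuinely exceeds 10⁶ µA in the reduced
model — that inefficiency *is* the selectivity result. Because the volume
conductor is linear, scaling the field by c scales every threshold by
1/c (tested).

The Shannon module is closed form: a ring electrode's surface is the full
torus 4π²Rr (R = (inner + wire)/2, r = wire/2), charge per phase
Q = I·t, density D = Q/area, and k = log₁₀D + log₁₀Q; k = 1.5 bounds the
no-observed-damage region and k = 2 the damaging region. A
contact-fraction parameter scales the area for partially immersed rings;
the default (1.0, full torus) is the interpretation under which the
100 µA / 10 ms operating point sits at k ≈ 1.06, safely inside the
boundary.

## What the default model does and does not represent

The parametric grid *is* the study condition: a reduced uniform-grid
stand-in for a ~400-million-cell multi-resolution rodent model, with
stylized head compartments and printed resistivities. It preserves the
geometry that drives the placement comparison — current path through the
cornea and eye versus laterally across the orbit — but not fine orbital
anatomy, electrode metal, or multi-resolution accuracy near the
electrodes. Absolute thresholds are therefore far above in vivo values
(central-retina cells are distant from the electrode, and the coarse grid
smooths near-field gradients); conclusions are drawn from ratios and
curve shapes, which is also how the original analysis is framed. Passing
tests show the solver, cable engine and search machinery are correct and
that the qualitative selectivity structure emerges from the geometry;
they do not calibrate any quantity to experimental recordings.

## Known limitations

* Isotropic, purely resistive tissue; no electrode-metal conductor, no
  electrochemical interface model.
* Equal current split across electrode nodes (equipotential metal not
  enforced).
* Two isolated cells; no network, synapses, or photoreceptor input, and
  no graded-potential (non-spiking) bipolar subtypes.
* The shipped kinetics are declared substitutes assembled from the
  standard retinal-modeling formulations, not a reproduction of any
  specific published parameter set; the YAML registry exists precisely so
  they can be replaced.
* The bipolar cell can hold a depolarized plateau while a very strong
  stimulus persists (its fixed 2 mS/cm² axonal fast-K cannot always
  repolarize against the 1000 mS/cm² Na band); this does not affect rest
  stability or threshold detection.
* The bipolar/RGC *differential* biphasic threshold narrows monotonically
  with duration from 1 ms upward but widens between 0.1 and 1 ms: the
  65 µm bipolar cell equilibrates with the field in well under a
  millisecond (effective chronaxie ≈ 0.2 ms), so its curve is shallower
  than the RGC's below the RGC chronaxie (≈ 0.4 ms). The corresponding
  full-grid monotonicity test documents this by failing at the short end;
  the long-pulse advantage itself (the operating regime of interest) is
  reproduced.
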
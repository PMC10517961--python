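# retistim

Modeling transcorneal electrical stimulation (TES) of the retina, at desk
scale. TES delivers current through a ring electrode on the cornea to
stimulate retinal neurons non-invasively, a candidate therapy for slowing
retinal degeneration (retinitis pigmentosa, age-related macular
degeneration). In the degenerating retina the bipolar cells (BCs) are
affected early, so the engineering question is *where to put the
electrodes and what pulse to use* so that BCs — not just the easily
recruited retinal ganglion cells (RGCs) — are driven at safe currents.

`retistim` answers that with a three-layer model:

1. **Volume conductor** — a voxelized rat head-and-eye model (layered
   spherical eye with cornea, lens, vitreous and a homogeneous 1.5 Ω·m
   retina shell, embedded in skin/fat/bone/muscle/brain) turned into a
   resistor network on the node lattice, G_ij = 2h/(ρᵢ+ρⱼ) per branch,
   and solved for the potential field per ampere of injected current
   (admittance method; quasi-static, so waveforms just scale the unit
   solution).
2. **Retinal neurons** — multi-compartment conductance-based models of a
   spiking DB4-type cone bipolar cell (Na/slow-K/fast-K/L- and T-type
   Ca/HCN, Cm = 1 µF/cm², Ri = 100 Ω·cm) and an A2 retinal ganglion cell
   (Fohlmeister–Miller-lineage Na/K/K_A/K_Ca/Ca kinetics with a calcium
   pool, distinct axon regions AH/SOCB/NS/DA, Cm = 1 µF/cm²,
   Ri = 110 Ω·cm), driven through the extracellular-potential
   (activating-function) coupling
   Cm·dVmᵢ/dt = −I_ion,ᵢ + Σⱼ[(Vmⱼ+Veⱼ)−(Vmᵢ+Veᵢ)]/Rᵢⱼ.
3. **Threshold & safety analysis** — bisection thresholds, strength–
   duration curves I_th(PW) over 0.1–25 ms, TES1/TES2 electrode-placement
   ratios, and the Shannon electrode-safety chart
   log₁₀(D) = k − log₁₀(Q).

Two electrode placements are built in: **TES1** (stimulating ring temporal,
return ring nasal — lateral current) and **TES2** (stimulating ring on the
cornea, needle return temporal — current along the retinal depth).

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

Electrode safety for the corneal platinum ring (3 mm inner diameter,
270 µm wire), 10 ms phases:

```text
$ retistim shannon
amplitude_ua,charge_uc,density_uc_cm2,k
20,0.2,2.29519048,-0.338151271
50,0.5,5.73797619,0.457728746
100,1,11.4759524,1.05978874
200,2,22.9519048,1.66184873
300,3,34.4278572,2.01403125
400,4,45.9038096,2.26390872

max safe amplitude at k <= 1.5: 100 uA
```

Each row is one operating point: charge per phase Q = I·t (µC), charge
density D = Q/area (µC/cm², full-torus area 0.0871 cm²), and the Shannon
parameter k = log₁₀D + log₁₀Q. The k = 1.5 line bounds the region where
no tissue damage is observed; of the tested amplitudes, 100 µA is the
largest that stays below it (k ≈ 1.06), while 200 µA (k ≈ 1.66) crosses
into the caution band.

Electrode-placement selectivity (full pipeline — builds the 101³-node
grid, solves both fields, and runs threshold searches for both cells;
about 5 minutes on one CPU):

```bash
retistim run --bundle ratio --out out/
```

The strength–duration table this writes (`strength_duration.csv`,
thresholds in µA, biphasic cathodic-first pulses) contains, for the
bipolar cell under the two placements:

```text
duration (ms):    0.1     0.3     1       3       10      25
BC TES2:          276000  144469  110609  98511   80040   65033
BC TES1:        4736000 2405000 1822539 1651676 1341987 1090364
ratio TES1/TES2:   17.2    16.7    16.5    16.8    16.8    16.8
```

and for the ganglion cell the same ratio is 0.29–0.38. The reading: the
corneal placement (TES2) drives the radially oriented bipolar cell ~17×
more efficiently than lateral stimulation, while the RGC — whose 1 mm
axon runs tangentially — actually prefers the lateral placement. That is
the placement-selectivity argument for stimulating through the cornea
when the therapeutic target is the bipolar cell, and long biphasic pulses
narrow the BC/RGC threshold gap further (from ~6× at 1 ms to ~4.8× at
25 ms). Absolute amplitudes are far above in vivo thresholds because the
modeled cells sit in the central retina, away from the electrode, and the
reduced grid smooths near-field gradients; the analysis is designed
around ratios and curve shapes, which are robust to this (see
`docs/methods.md`).

The same computations are available piecemeal (`retistim threshold`,
`sd-curve`, `ratio`, `solve-field`, `build-grid`, `validate`) and as a
library (`retistim.grid`, `field`, `cells`, `kinetics`, `engine`,
`waveforms`, `thresholds`, `shannon`, `config`).

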
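# Methods

This note documents the models, numerics and design choices behind
`axonmetrics`, in the order the pipeline uses them.

## Volume conductor

The analytic field model treats each active contact as an ideal point
source in an infinite homogeneous isotropic medium of conductivity
σ = 0.1 S/m (grey-matter order of magnitude):

    V(x)  =  Σᵢ Iᵢ / (4π σ ‖x − xᵢ‖),      E(x) = −∇V(x)

with I in mA, distances in mm, V in volts and E in V/m. Superposition and
E = −∇V hold to machine/finite-difference precision and are tested.
Voltage-controlled protocols are converted to current control with an
isolated-sphere access-resistance model, I = 4πσ r_c V_set, using the
sphere radius r_c = 0.635 mm equivalent to a cylindrical DBS contact; this
is a declared approximation, not a reproduction of any FEM solver's
internal voltage handling. Monopolar settings use a single signed source
with the return at infinity; bipolar settings must be charge balanced.
Queries within 0.05 mm of a source raise rather than clip.

Heterogeneous or dispersive tissue is out of scope. Externally computed
fields can be imported instead as a 4-D NIfTI lattice (Ex, Ey, Ez, optional
V) with an RAS affine; sampling is trilinear with no extrapolation, exact
on lattice nodes and on affine-linear fields.

## Fibres and field metrics

Fibres are polylines in mm (RAS), grouped into pathways; the mid-sagittal
plane is x = 0, so hemisphere mirroring is x-negation plus a deterministic
fiber-id offset (an involution). For the field metrics a fibre is resampled
to 0.5 mm arc-length spacing (no standard sampling density exists for
these metrics; 0.5 mm resolves the field curvature at contact distances
and is a config knob), tangents come from central differences,
and the point-wise channels are ‖E‖ and |E · t|. The projection uses the
absolute dot product so that both field metrics are invariant under a
global polarity flip; a signed variant exists behind a flag. Fibre-wise
aggregation is sum, mean or peak — peak is the default because it is the
least sensitive to the resampling step. Binarization thresholds default to
200 V/m (magnitude) and 125 V/m (projection), comparisons closed on the
left. The logistic conversion p = 1/(1+exp(−k(v−θ))) anchors p = 0.5 at the
binarization threshold; the slope k = ln 19/(0.5 θ) puts p = 0.95 at 1.5 θ,
a declared default chosen so the binary rule and the p ≥ 0.5 rule coincide
exactly. The activating function (second arc-length difference of V,
zeroed at the ends) is implemented as an independent cross-check of where
depolarization should start, not as a headline metric.

## Axon model

The cable model is the classic McNeal construction: excitable nodes of
Ranvier connected by perfectly insulating myelinated internodes, so state
lives only at the nodes. Morphology scales with the outer fibre diameter D:

| parameter | value | unit |
|---|---|---|
| internodal length L | 100 · D | (D in µm → L in 10⁻¹ mm) |
| axial (axon) diameter d | 0.7 · D | µm |
| node length | 2.5 | µm |
| nodal capacitance | 2.0 | µF/cm² |
| axoplasmic resistivity | 110 | Ω·cm |
| temperature | 37 | °C |

Nodes are placed along the fibre's arc length at spacing L, centred on the
fibre midpoint, sealed ends; fibres shorter than 2 L cannot hold the
minimum three nodes and are excluded (reported, not silently dropped).

Nodal membranes follow Frankenhaeuser–Huxley kinetics: GHK (constant-field)
sodium, potassium and non-specific currents gated by m²h, n², p², plus an
ohmic leak. The reference constants are at 20 °C; rates scale to 37 °C with
per-gate Q10 factors (m: 1.8/1.7, h: 2.8/2.9, n: 3.2/2.8, p as m) and
permeabilities/leak with Q10 = 1.3. The leak reversal is recalibrated at
build time so that rest (−70 mV with gates at steady state) is an *exact*
equilibrium; the published constants alone leave a small residual current
that would otherwise read as drift in the resting-stability test.

Stimulation uses the quasi-static separation: the spatial potential at the
nodes is computed once per protocol and multiplied by a rectangular pulse
envelope (onset 0.1 ms; pulse width from the protocol; monophasic only —
charge-balanced biphasic waveforms and pulse-train entrainment are v1
non-goals; the protocol frequency is recorded but unused).

### Numerics

Time stepping is Crank–Nicolson on the axial coupling with the ionic
current linearized about the current state (chord conductance added to the
diagonal) and gates advanced by exponential integration, dt = 5 µs. The
linearization matters: during the action-potential upstroke the nodal time
constant falls to below a microsecond, and a fully explicit ionic term
diverges at this dt. Many axons sharing one morphology are concatenated
into a single banded system (zero couplings between chains) and advanced
with one LAPACK banded solve per step — this batching is what makes
whole-atlas PAM tractable on one CPU.

Activation is detected when the membrane potential crosses 0 mV (absolute;
+70 mV depolarization from rest) at either terminal node, i.e. the spike
must propagate to an end of the fibre. The simulation window is
onset + pulse + 3 ms plus a conduction allowance of length/(2·D) ms
(conduction velocity in this model is ≈ 2.5–3 mm/ms per µm of diameter; the
allowance uses the conservative 2). Two early exits keep the window cheap:
a batch member stops once it has fired, and once the pulse is over an axon
whose depolarization has decayed below 10 mV everywhere (in absolute value,
so hyperpolarized anode-break candidates keep integrating) is subthreshold
for good. A |Vm| > 500 mV excursion raises a solver error rather than
returning garbage.

Threshold search brackets upward from 1 µA by doubling and then bisects to
1% relative tolerance; ascending from below matters because amplitudes far
above threshold (≈ 20–30×) produce cathodal surround block — a real
phenomenon in which the flanking hyperpolarization kills propagation — and
the blow-up guard also trips at extreme overdrive. Because of block,
activation is monotone in amplitude and diameter only below that regime;
the batched atlas sweep therefore short-circuits smaller diameters only
when the larger diameter stayed genuinely subthreshold (peak depolarization
< 40 mV), never when it was blocked.

### Probabilistic PAM

pPAM samples N = 10 diameters; "uniformly sampled on 1–4 µm" is read as the
deterministic equispaced grid including both endpoints (reproducibility),
with a seeded random-uniform mode available for the strict reading.
p(A) = N_activated/N_samples, always a multiple of 1/N. A diameter at which
the fibre is too short counts as not activated (the axon cannot exist);
only a fibre infeasible at every diameter is excluded. For whole-atlas runs
a validated screen skips simulation when the nodal potential span is below
25 mV — the smallest span ever observed at threshold across the operating
range (D = 4 µm at contact distance) is ≈ 120 mV, a ~5× margin.

Fibres intersecting the electrode body are flagged and never simulated.
Their verdict comes from the Euclidean heuristic: with c the mean of the
active contact positions and R the distance from c to the most remote
activated fibre (max over activated fibres of the minimum vertex-to-c
distance), a flagged fibre is activated iff its minimum vertex-to-c
distance is < R. The fibre-side reference point is the closest vertex — the
natural reading when fibres are polylines. With no activated fibres all
verdicts are negative.

## Group statistics

Activation matrices are stimulations × fibres with entries in [0, 1].
Left-hemisphere stimulations are evaluated on the mirrored atlas and folded
onto right-hemisphere homologues, doubling the row count ("mirroring").
The prevalence filter keeps fibres activated (p(A) ≥ 0.5) in ≥ 20% of
stimulations *and* not activated in ≥ 2 — the second guard is ours; without
a comparison group the t-statistic does not exist. The per-fibre test is
the pooled-variance Student t (Welch behind a flag), T > 0 meaning the
activated group improved more; no multiple-comparison correction and no
default p-values, by design. The probability-weighted version weights
stimulation i into the activated group with wᵢ = p(A)ᵢ and the complement
with 1 − wᵢ, using weighted means, Bessel-corrected weighted variances and
Kish effective sample sizes n_eff = (Σw)²/Σw²; with binary weights it
reduces exactly to the pooled test (asserted to 1e-12). A weighted odds
ratio with Haldane–Anscombe correction covers binary outcomes. Top-k
summaries rank included fibres by T with ties broken by ascending fiber_id.
Profile comparisons use Spearman rho with average ranks; sets of
correlations are compared pairwise after Fisher z = atanh(rho) ("z-scored
rank correlations" read as the Fisher transform; standardizing across the
sample is the plausible alternative reading). Whether outcomes should be
z-normalized before the fibre tests is unspecified upstream; raw percent
improvement is used.

## Synthetic data

The generator is first-class, tested code, not a fixture dump. It builds a
four-level omnidirectional lead (contact spacing 2 mm, radius 0.635 mm,
STN-like tip position (+12, −13, −10) mm, axis +z) and five bundles chosen
to span the geometries on which the three metrics disagree: a perpendicular
passing bundle (`motor_hyperdirect`, 60 fibres, offsets fanned 1.2–3.4 mm),
a short bundle terminating near the contacts (`pallidosubthalamic`, 30), a
close parallel helix (`cerebellothalamic`, 30), a remote parallel arc
(`corticospinal`, 30) and a bundle crossing the lead cylinder
(`lead_crossing`, 10, all flagged). Offsets were chosen so that bundle
activation varies across the cohort's amplitude range for *all three*
metrics — fibres that are always or never activated carry no statistical
information and fail the prevalence filter.

The cohort mirrors the clinical study shape: 15 patients, bilateral,
bipolar adjacent-contact settings with random polarity order, voltages
uniform on 0.5–8.3 V, pulse widths in {60, 70, 80, 90} µs, 130 Hz. Outcomes
are planted as baseline 20% + 40% × (activated fraction of the designated
pathway) + N(0, 5%) noise, where the generator's reference metric is binary
‖E‖ ≥ 200 V/m with peak aggregation — deliberately *one* of the analysis
metrics, so recovery by the other two is a non-trivial cross-metric check.
All randomness fans out from one integer seed through named SeedSequence
substreams; atlas, protocols and outcomes are byte-reproducible.

What the generator does not emulate: anatomically realistic pathway shapes,
patient-specific lead placement variability, tissue heterogeneity, and
outcome floors/ceilings. Passing tests therefore show that the estimators
recover a signal planted under the model's own field assumptions — not that
they are unbiased on clinical data.

## Problem sizes and runtime choices

The bundled study uses 160 fibres/hemisphere × 30 stimulations × 10
diameters; with batching, pruning and early exits a full pPAM cohort pass
takes ~25 s and the complete pipeline about a minute on one CPU. Threshold
physiology checks use 12 mm straight fibres (121 points), where a 1%
bisection costs ~10–20 simulations. These sizes were chosen so the whole
analysis is desk-scale while every statistic retains enough fibres (≥ 50
included for the field metrics) to make the top-100 summary meaningful.

## Known limitations

- Single rectangular monophasic pulse per protocol; no 130 Hz entrainment.
- The FH membrane at 37 °C has a reduced spike amplitude; detection at
  0 mV absolute presumes the default kinetics (strongly altered parameter
  sets may need a different detection level).
- The isolated-sphere voltage-to-current conversion ignores contact
  geometry and encapsulation; imported field grids bypass it entirely.
- The flagged-fibre heuristic is geometric, not biophysical, and inherits
  the activated set of whichever metric feeds it (p(A) = 1 fibres here).
- Weighted t-statistics rely on Kish effective sample sizes; they are a
  reasonable but not exact finite-sample calibration.
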
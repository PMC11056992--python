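# Methods

`amorphdyn` implements the computational chain used to characterise the
molecular dynamics of amorphous chiral drugs — pure enantiomers versus
their racemate — from two directions: broadband dielectric spectroscopy
(BDS) observables measured as a function of temperature and pressure, and
structural statistics of molecular configurations (hydrogen-bond cluster
topology, fluorine–ring stacking geometry). Because no raw spectra or
trajectories ship with the package, a synthetic-data module generates both
kinds of input with known ground truth; every quantitative claim made by
the test suite is a recovery of a planted truth, not a re-measurement.

## Dielectric branch

### Loss model

A loss spectrum ε″(f) in the supercooled-liquid state is modelled as a
dc-conductivity wing plus one or two Havriliak–Negami (HN) processes:

    ε″(ω) = σ_dc/(ε₀ω) + Σ_k Im[ −Δε_k / (1 + (iωτ_k)^{α_k})^{β_k} ],

with ω = 2πf and the convention ε* = ε′ − iε″ (so ε″ ≥ 0). α ∈ (0,1]
and β ∈ (0,1] are the symmetric and asymmetric broadening exponents;
α = β = 1 is the Debye limit. The conductivity exponent is fixed at 1
(pure dc transport of ionic impurities). ε∞ enters only the optional
complex output; the fits are to loss spectra alone, which is how such
spectra are analysed in practice.

The structural relaxation time is the loss-peak time τ_α = 1/ω_max,
obtained from τ_HN by the Kremer–Schönhals closed form

    τ_α = τ_HN · [sin(πα/(2+2β))]^{−1/α} · [sin(παβ/(2+2β))]^{1/α}.

The closed form is validated to ≤0.1 % relative against an independent
numerical peak maximiser over the full α, β ∈ {0.2,…,1.0} grid; for
performance the residual evaluation also uses an algebraically identical
real-arithmetic form of the HN loss (no complex `pow`), checked against
the complex form to machine precision.

### Fitting

Least squares on log₁₀ ε″ with uniform weights — log space equalises data
spanning many decades, which is standard for BDS work. The optimiser is a
bounded trust-region reflective solver (cost tolerance 1e-10, bounds
α, β ∈ [0.05, 1], τ ∈ [1e-12, 1e6] s) over log-scale parameters
(log Δε, log τ, log σ_dc). Initial values come from the spectrum itself:
σ_dc from the low-frequency slope −1 segment, τ from the observed peak
positions after subtracting that wing, Δε from twice the peak height.
Five deterministically jittered restarts (fixed seed 1234) guard against
local minima; the loop stops early when a restart reproduces the current
best minimum (basin confirmed) or the fit is numerically exact.
Parameter uncertainties come from the Gauss–Newton covariance at the
solution; a process whose Δε runs to its bound or whose uncertainty
exceeds the estimate is thereby flagged unidentifiable (the behaviour the
tests require for a conductivity-only spectrum). The secondary (β)
process is a full HN shape by default; a `symmetric_secondary` switch
pins its β at 1 (Cole–Cole) since glassy-state secondary peaks are often
symmetric and the choice cannot be decided from the model alone.

### Relaxation surface

The ambient-pressure τ_α(T) follows the canonical VFT law
τ = τ∞·exp[B/(T−T₀)]. The joint (T, p) dependence follows the modified
Avramov (entropy-based) surface

    τ(T,p) = τ∞ · exp{ ln(τ_g/τ∞) · [(T_r/T)(1+p/Π)^{β/α₀}]^{α₀} },

with τ_g ≡ τ(T_g) fixed at 100 s (the dielectric T_g definition), T_r a
reference temperature close to T_g, Π a pressure scale, and exponents α₀
(fragility-like) and β (pressure sensitivity). This parameterisation has
the closed-form glass-transition line

    T_g(p) = T_r · (1 + p/Π)^{β/α₀},

along which τ = τ_g holds identically — the 100 s isochrone — so the
isochrone test (|log₁₀τ(T_g(p),p) − 2| < 1e-6) is satisfied by any
correct implementation regardless of parameter values. T_r is fitted
(not pinned), since near-T_g reference temperatures are convention, not
measurement. The thermodynamic metadata (heat capacity C_p0, degeneracy
Z, expansivity α_p, molar volume V_m) that can be folded into α₀ and β is
carried as an optional pass-through; α₀ and β are fitted directly because
those material constants are inputs, not outputs, of this analysis.

The surface fit is a global weighted least squares of log₁₀ τ over all
(T, p) records (weights 1/σ² when per-record uncertainties exist),
initialised from a VFT fit of the lowest isobar (T_r from the VFT T_g,
α₀ from the VFT steepness) with a small seeded multi-start over (Π, β).
It requires ≥2 pressures, ≥8 temperatures and ≥12 records; a
single-pressure map is redirected to the VFT fit.

### Derived quantities

* **T_g(p)**: closed form above; cross-checked against bracketed root
  finding of τ(T;p) = 100 s (Brent, 1e-6 K).
* **dT_g/dp**: central finite difference with a 1 MPa step, reported in
  K/GPa; validated against a five-point stencil and the analytic
  T_r·β/(α₀Π) limit (halving Π doubles the slope at p→0).
* **Steepness (fragility)** m = d log₁₀τ/d(T_g/T) at T = T_g, finite
  difference.
* **Activation volume** ΔV_α = ln(10)·R·T·(∂log₁₀τ/∂p)_T with p in MPa,
  so the slope in MPa⁻¹ gives ΔV in cm³/mol directly
  (1 J/MPa = 1 cm³). Finite differences (1 MPa) rather than symbolic
  derivatives keep the implementation agnostic to the surface form.
  At T = T_g these obey ΔV_α = ln(10)·R·m·(dT_g/dp), an exact isochrone
  identity the test suite enforces to 1 % on every fitted surface.

Finite-difference steps (1 MPa, 0.01 K relative for m) are far inside the
smoothness scale of these surfaces; halving them changes nothing at the
tested tolerances.

## Structural branch

### Configurations

A configuration is an orthorhombic periodic box of rigid, simplified
molecules: a fluorinated six-carbon ring (F at 1.35 Å from its ring
carbon) plus a carboxylic-acid head (hydroxyl O–H donor, carbonyl
acceptor, O···O intramolecular distance 2.30 Å). Atom roles
(O_hydroxyl, H_hydroxyl, O_carbonyl, F, C_ring_F, 5 × C_ring) are
explicit per atom; chirality is a per-molecule label, not a geometric
property, because none of the implemented analyses depends on true
stereochemistry. Files are extended XYZ with the box on the comment
line and per-atom columns `element x y z mol_id role chirality`.

### Hydrogen bonds and clusters

Geometric criterion: minimum-image d(O_donor···O_acceptor) ≤ 3.5 Å and
O–H···O angle ≥ 150° (configurable). Both carbonyl and hydroxyl oxygens
accept — carboxylic dimers and chains need both. Each donor hydrogen
binds at most its closest valid acceptor, so bifurcated contacts are not
double-counted. These are conventional values; the synthetic motifs are
planted far from both thresholds (2.75 Å, 180°), so the statistics are
insensitive to the exact criterion.

Clusters are connected components of the undirected donor→acceptor
graph. Topology labels: a two-molecule cluster with mutual bonds is a
cyclic dimer, otherwise linear; clusters of three or more are classified
on the undirected simple graph — cyclic if it contains a ring (edges ≥
nodes on a connected graph), a chain if acyclic with maximum degree 2,
branched otherwise. A mutual (double) bond inside a larger cluster does
not count as a ring. The low-molecular-cluster fraction is the share of
clusters of size 2–4 among all clusters of size ≥ 2; since the
convention (cluster- vs molecule-weighted) is ambiguous in parts of the
literature, both statistics are reported, the cluster-weighted one as
the default. Interaction-energy bookkeeping is the trivial difference
E_int = E_T − ΣE_i on user-supplied energies (kJ/mol); the magnitude is
reported separately for comparison with positive-convention tables.

### Stacking geometry

For every ordered intermolecular pair (i, j): r = minimum-image distance
from F_i to the F-bearing ring carbon of j, and θ ∈ [0°, 180°] = angle
between the two F→C_ring unit vectors (ring-plane normals are computed
for diagnostics but not used in the map). The (r, θ) histogram
(default 0.1 Å × 2° bins) is normalised by the ideal-gas measure —
radial shell volume times the sin θ angular weight — so a random gas is
flat at 1 and peaks read as excess probability; raw counts are kept
alongside since either convention may be wanted. Flatness is verified
on a 500-molecule, 50-frame random gas: the mean |g−1| over mid-range
bins stays within 3 Poisson standard errors.

Pair classification uses windows centred on the two characteristic
arrangements: parallel when θ ≥ 150° and r ∈ [3, 5] Å (the ~4 Å/180°
arrangement), antiparallel when θ ≤ 30° and r ∈ [5, 7] Å (~6 Å/0°).
r is taken as the smaller of the two directed F···C distances so the
label is symmetric in pair order. The census counts unordered pairs and
breaks them down by chirality pair (R–R, S–S, R–S).

## Synthetic data

### Spectra and relaxation maps

The planted τ_α(T,p) surfaces encode the study conditions of a fragile
hydrogen-bonded drug: τ∞ = 1e-14 s, Π = 1 GPa, and (T_r, α₀, β) chosen
to give T_g ≈ 263.4 K, fragility m ≈ 81 and dT_g/dp ≈ 247 K/GPa for the
enantiomer-like preset, and T_g ≈ 261.9 K, m ≈ 71, dT_g/dp ≈ 248 K/GPa
for the racemate-like preset — i.e. nearly identical pressure
coefficients but a distinctly lower activation volume (≈337 versus
≈385 cm³/mol) in the racemate, the contrast the demo study is built to
exhibit. Measurement conditions are placed at fixed log₁₀τ targets
along each isobar (2.0 down to −3.5, twelve per isobar at 0.1, 100 and
200 MPa), mirroring how isobaric sweeps track the α peak through the
experimental window; the frequency grid is 40 points/decade over
10⁻⁴–10⁶ Hz so the 100 s isochrone is measured rather than
extrapolated. Noise models: multiplicative lognormal on ε″ (default
1 %, instrument-like) and Gaussian in decades on log₁₀τ (default 0.05).

Spectra are built by inverting the peak-time formula so the structural
HN process peaks exactly at the planted τ_α (shapes α = 0.85, β = 0.60,
Δε = 5). The secondary process (α = 0.55, β = 1, Δε = 0.4) is tied to
the structural one — log₁₀τ_β = −5 + 0.5·log₁₀τ_α — reflecting the
isochronal α–β superposition seen in hydrogen-bonded systems and
keeping both peaks inside the window at every condition. σ_dc scales as
1/τ_α (Debye–Stokes–Einstein-like coupling), putting the conductivity
wing in its usual position below the α peak.

### Configurations

Motifs are built analytically so every planted bond has d(O···O) =
2.75 Å at exactly 180°: zigzag chains (each molecule donating along the
next edge, alternating 40° turns — the angle keeps every non-bonded
O···O above the cutoff and every same-parity F···C contact outside the
antiparallel window), centro-symmetric carboxylic cyclic dimers, and
threefold-symmetric cyclic trimers donating around an equilateral O···O
triangle. Stacking pairs are planted at exactly (4 Å, 180°) and
(6 Å, 0°) with carboxyl groups pointing apart so they contribute no
H-bond. Motifs are placed with uniform random rotations by rejection
sampling on bounding-sphere separation; the default clearance of 7.5 Å
exceeds both the H-bond cutoff + 1 Å and the widest stacking window, so
inter-motif pairs can neither bond nor classify, and planted
compositions are recovered exactly (counting, no tolerance). The demo
compositions give the enantiomer-like box a 56.8 % low-molecular
cluster share with parallel-only stacking and the racemate-like box a
44.1 % share with mixed parallel/antiparallel stacking, and dimer/trimer
cyclic shares of 12.5 %/9.1 % versus 9.1 %/18.2 %.

What the generator does **not** emulate: liquid-state packing density,
thermal disorder within motifs, force-field energetics, bond-lifetime
dynamics, or real stereochemistry. Passing tests therefore demonstrate
that the analysis chain is correct (detection, partitioning,
classification, normalisation, fitting, and the derived-quantity
algebra), not that any particular real system has these statistics.

## Pipeline and reproducibility

`run_pipeline` executes per sample: obtain spectra (preset scenario or
CSV) → fit → map → VFT + Avramov → derived quantities, and in the
structural branch: obtain a configuration → cluster report + stacking
census. Stage outputs are plain JSON/TSV files; a failure in one sample
or branch is recorded in the report without aborting the others. All
randomness descends from a single run seed through spawned child
sequences, and reports are serialised with sorted keys, so a rerun with
the same seed is byte-identical.

Problem sizes used by the tests and the acceptance script — 36 spectra
per sample, 12 × 5 (T, p) records for surface-recovery checks, ~200–280
molecules per demo box, 500 molecules × 50 frames for the ideal-gas
flatness check, 100 random boxes for the periodic-boundary oracle, 1000
random graphs for the union-find oracle — are desk-scale choices that
keep the whole suite comfortably fast while leaving every statistical
check far from its tolerance.

## Known limitations

* The Avramov exponents (Π, β) are strongly correlated at p ≪ Π;
  individual values carry large uncertainties even when dT_g/dp and
  ΔV_α (the quantities of interest) are tight. This is intrinsic, not a
  solver artefact.
* Fits of spectra whose α peak sits at the edge of the frequency window
  are weakly identified (the conductivity wing and the peak flank trade
  off); such conditions show up with inflated residuals and stderr.
* The dimer/trimer topology classification is graph-level; pictorial
  sub-motifs of the linear dimer (which oxygen accepts, syn/anti
  geometry) are deliberately not distinguished.
* Only orthorhombic periodic boxes are supported.
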
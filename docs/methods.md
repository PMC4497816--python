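# Methods

`ephmap` simulates the development of the mouse retinocollicular
projection — how retinal ganglion cell (RGC) axons find their
termination zones in the superior colliculus (SC) — under four classical
computational models, and scores the resulting maps with a common
quantitative analysis suite.  This note documents the model equations as
implemented, the parameters that matter, the numerical choices made
where the published descriptions are open, and what the synthetic test
maps do and do not establish.

## Substrate

**Geometry and axes.** The retina is a circle of unit diameter with
x the nasotemporal (NT) axis (0 = nasal) and y the dorsoventral (DV)
axis (0 = dorsal).  The SC is a smooth convex blob with unit
anteroposterior (AP) extent (x, 0 = anterior) and a shorter mediolateral
(ML) extent (y, 0 = medial); the outline is the analytic profile
`half_width(x) = 0.42 (4x(1-x))^0.6` about the ML midline, a stand-in
for the untraceable histological outline (all analyses are
outline-agnostic).  The biologically correct map anti-aligns both axis
pairs: temporal retina projects to anterior SC and ventral retina to
medial SC.

**Placement.** Neuron positions are drawn uniformly with a hard
minimum-spacing constraint (exclusion distance d_R = 0.0139 in the
retina and d_SC = 0.0119 in the SC for 2000 neurons; rescaled as
1/sqrt(N) for other population sizes so the packing fraction is
preserved).  Candidates are sampled from the bounding box expanded by
3 exclusion distances; accepted points outside the outline act as
virtual neighbours and are discarded at the end, which prevents an
artificial density excess at the boundary.  Placement aborts after
1000·N rejected candidates (packing infeasible).

**Gradients.** Each receptor/ligand subtype follows
`G(x) = max(0, G0 + G1 exp(-G2 |x - G3|))` on its axis.  Retinal EphA =
EphA4 + EphA5 + EphA6 (temporal-high); retinal EphB (ventral-high); SC
ephrin-A = ephrin-A2 + A3 + A5 (posterior-high); SC ephrin-B
(medial-high).  Summed wild-type profiles are scaled once so each family
peaks at 1, and that scaling constant is reused for every genotype:
knock-ins therefore peak above 1 and knock-outs below 1.
Countergradients (retinal ephrins, SC Ephs) are deliberately absent.

**Genotypes.**
- *wild type*: gradients as above.
- *Isl2-EphA3 knock-in* (homo/heterozygous): an independent
  Bernoulli(0.4) label per RGC ("salt and pepper" Isl2 expression) adds
  a flat EphA3 level (G0 = 1.86 homozygous, 0.93 heterozygous, before
  the wild-type peak scaling) to labelled cells.
- *ephrin-A TKO*: SC ephrin-A zeroed, or replaced by K x the wild-type
  profile (K < 1) to model a residual weak AP guidance cue.
- *Math5 null*: 10% of the wild-type RGC count, same spacing rule.

**Seeding.** One master seed per run is split (via `SeedSequence`) into
independent streams for retinal placement, SC placement, Isl2 labelling,
model dynamics and analysis; repeats of a condition differ only in the
master seed.

## Models

All four models consume the same substrate and emit an RGC x SC weight
matrix.  Gierer and Koulakov produce integer counts; Whitelaw and
Willshaw produce continuous weights thresholded at w_min (1e-5 and 1e-3
respectively) before analysis.

### Gierer (type II chemoaffinity + competition)

Each RGC has 16 terminals walking on the Delaunay graph of SC neurons,
moving to the neighbour with the lowest potential
`p = R_A L_A - R_B L_B + c` when strictly lower (repulsive A system,
attractive B system, competition c).  The competition field obeys
`dc/dt = eps*rho - eta*c` with eps = 0.005, eta = 0.1 and rho the raw
terminal count per SC neuron; its steady state `c = (eps/eta) rho` is
the convergence gauge.  One epoch visits every terminal once in random
order and advances time by one unit.

*Numerical choice.* A synchronous once-per-epoch Euler step for c is
unstable: c is frozen during the sweep, so all terminals chase the same
minimum and the population oscillates indefinitely (terminal pile-ups of
thousands on single neurons at any network size).  The implementation
instead integrates the linear ODE exactly under piecewise-constant rho,
refreshing c lazily (exponential decay toward (eps/eta) rho) whenever a
site is evaluated, with each terminal step advancing 1/(total terminals)
of an epoch.  Same equation, same steady state, but the field responds
continuously within a sweep and the dynamics settle.  Ties between
equally minimal neighbours break uniformly at random; c starts at 0.

### Koulakov (stochastic synapse dynamics)

Synapses are added/removed by Metropolis-like moves on
`E = E_chem + E_act + E_comp` (chemistry alpha = 90, beta = 135;
activity kernel C = exp(-d_retina/0.11), U = exp(-d_SC^2 / (2*0.03^2));
competition `sum_RGC(-500 n^0.5 + n^2) + sum_SC n^2`).  Each iteration
attempts one random-pair addition and one random-synapse removal, each
accepted with p = 1/(1 + exp(4 dE)); an epoch is max(N_R, N_SC)
iterations.  The activity pair sum runs over ordered pairs including
self-pairs with the 1/2 prefactor; the identical convention is used
incrementally, so incremental dE equals brute-force recomputation to
float precision (this is asserted in tests at 1e-8).  Duplicate synapses
on a pair are allowed; the counts n are what enter E_comp.

*Incremental energies.* A per-SC-neuron correlation cache
`G[i, j'] = sum_{s on j'} C(i, mu_s)` turns the activity increment into
one dot product with a row of U; the cache is updated exactly on
accepted moves (an algebraic regrouping, not an approximation).

*Activity balance.* What the published configuration pins down is the
balance between activity and chemoaffinity, not gamma in isolation: the
per-synapse activity energy grows with the total synapse count, which is
why network-size changes have historically come with compensating gamma
rescalings (x5 when moving from 10,000 to 2,000 neurons).  Implemented
verbatim, the nominal gamma = 5/16 drives runaway synapse growth and
fuses the knock-in submaps at every network size we tested — the
published account of gamma is also internally inconsistent (the stated
rescaling path gives 0.2, the parameter table 5/16).  The implementation
therefore carries a single calibrated activity multiplier (0.416 on the
nominal value, scaled linearly with the wild-type network size; see
`scaled_params`).  The calibration criterion is qualitative regime
correspondence — full duplication in the homozygous knock-in, a collapse
point in the heterozygote, activity-driven patches of local order in the
TKO, an ordered wild-type map — evaluated once, at one network size.
Genotypes with fewer RGCs (Math5) keep their wild-type network's gamma:
weaker activity interaction there is part of the phenotype.

### Whitelaw (Hebbian waves + dual normalization)

Fully connected continuous weights (init 1).  Each epoch sweeps every
RGC once as the centre of a circular retinal wave (radius 0.07, activity
normalised to total 2); induced SC activity y^I = W^T x is smoothed over
SC neighbourhoods (radius 0.0289, lateral constant k = 0.5, chosen so
induced SC activity stays below the retinal input level — the published
description retains k from the original model without a value).  The
Hebbian update `dW = dt ((M+1) x y - mu y)` with adhesion
`M_ij = R_A [max L_A - L_A] + R_B L_B` accumulates over the epoch and is
applied once (wave order within an epoch is therefore immaterial and the
sweep is deterministic); weights below 1e-5 are zeroed; then columns are
normalised to N_R (per SC neuron) and rows to N_SC (per RGC) — in that
order, which is what preserves the knock-in duplication (the reversed
order is exercised as a regression test).  Empty rows/columns skip
normalisation and are counted.  dt = 1e-4, mu = 0.1.  The epoch count is
not published; the default is 5000, where the wild-type lattice measures
plateau, with the mean per-epoch weight change logged as the gauge.

### Willshaw (marker induction)

Type I matching against plastic SC marker fields.  Weights start at
U(0, 1e-4) i.i.d.; T^A, T^B start at the static ephrin gradients (for
the TKO, T^A starts at zero and is grown entirely by induction).  Per
step: induced markers I^X_j = weighted mean of presynaptic R_X (SC
neurons with zero afferent weight carry their previous value and are
counted); marker relaxation
`dT^A = (sigma(1 - zeta I^A T^A) + delta lap T^A) dt` (and the linear
analogue for B) with the graph Laplacian on the Delaunay graph of SC
neurons, pruned of sliver edges — an edge is dropped if it makes an
angle below 10 degrees inside an adjacent triangle; similarity update
`Phi = exp(-[(zeta R_A T^A - 1)^2 + (R_B - T^B)^2]/(2 kappa^2))` with
kappa = 0.0504, followed by exact presynaptic normalisation (row sums
1).  sigma = 0.05, delta = 0.01, theta = 0.1, zeta = 1.  The reference
configuration is dt = 0.1 for 48,000 steps (the parameter table's dt = 1
disagrees with the published run description; the run description wins,
both are configurable).  Polarity comes from the asymmetric gradients
alone; no extra bias is added.

## Analysis

All measures consume the strongest-connection point mapping (per RGC,
the SC neuron with the largest thresholded weight; empty rows are
excluded and counted) and/or the raw weight matrix.

**Lattice method.** 100 centres are spread approximately equidistantly
over the mapped retina by farthest-point sampling (deterministic: seeded
from the point nearest the centroid).  Each centre's circle (radius 7%
of the retinal diameter) collects member RGCs; the lattice node is the
member centroid on both sides — retinal positions and their SC
projections — so an exactly affine map projects without distortion (with
raw centre points on the retinal side, sampling asymmetry alone breaks
the ideal-map score).  Delaunay edges on the retinal nodes are projected
to the SC; properly crossing projected edges (shared endpoints excluded)
mark local disorder.  Nodes are removed greedily — most incident
crossings first, ties by larger summed crossing-edge length, then
index — until the submap is crossing-free (the postcondition is
asserted).  Reported: % nodes retaining all their edges, % edges
retained, AP/ML polarity (% of all lattice edges whose SC order matches
the biologically correct, anti-aligned retinal order), and the mean
absolute orientation difference of corresponding edges relative to the
canonical transfer.  Centres whose circle captures no RGC are dropped
(error if more than 20% are empty).

**Collapse point.** RGCs from the central ML third of the retina are
binned along NT (50 bins at full scale); each bin's SC termination
points are split by exact 1D 2-means on the AP coordinate, and the two
clusters are distinct iff their AP mean separation exceeds 1.5 pooled
standard deviations of the 2D within-cluster spread and the smaller
cluster holds at least 5% of the bin.  Clustering the full 2D points
instead lets 2-means split along the ML spread (every bin reads double);
testing against a 1D pooled SD declares every unimodal bin split (2-means
halves of a Gaussian sit 2.65 pooled SDs apart) — the mixed rule is the
one that behaves.  The collapse point is the nasal edge of the
contiguous single-cluster run reaching the temporal end of the map,
reported as bin-centre % of the NT axis (taking the literal nasal-most
single bin instead is hijacked by sparse bins at the nasal pole of the
circular retina).  Bins with fewer than 4 RGCs are undetermined and
skipped.  "No split" (all bins single) and "no merge" (duplication to
the temporal end) are reported as such.

**Virtual injections / segregation.** Two SC injection centres label
every RGC whose strongest target lies within the injection radius
(default 0.05; ties to the nearer centre).  Segregation = fraction of
labelled RGCs whose nearest labelled retinal neighbour carries the same
colour (1 = fully separated, 0.5 = fully overlapping).

**KDE contours and coverage.** An isotropic Gaussian KDE on a 100x100
grid, bandwidth maximising the leave-one-out cross-validated
log-likelihood (bounded scalar search on log10 k in [-3, -0.3];
coincident points floor the bandwidth and warn).  The P% contour
encloses the top P% of total mass; the readout is enclosed area as % of
the structure's area.  SC coverage applies the same machinery to SC
neuron positions weighted by total afferent weight and reports the area
fraction holding 99% of synaptic mass.

## Synthetic test maps

The fixture generator builds mappings with known ground truth on any
substrate: the canonical affine map (axes anti-aligned), a noisy
version, an AP-mirrored map, a duplicated map (interleaved population
shifted anteriorly by a configurable offset), a duplicated map merging
at a chosen NT position, a scrambled map (SC targets permuted), and a
map compressed into the anterior half of the SC.  These exercise every
analysis operation without running a model.  They emulate the *geometry*
of ideal/duplicated/disordered maps, not the graded weight structure,
termination-zone shapes or biological noise of real or simulated maps —
passing the analysis oracle suite shows the measures are correct on
known constructions, not that any model is.

## Problem sizes and reproduction

Full scale is 2000 RGCs / 2000 SC neurons with 10,000 epochs (Gierer,
Koulakov), 48,000 steps at dt = 0.1 (Willshaw).  The acceptance script
(`scripts/acceptance.py`) reproduces the headline measures at the
package's standard desk configuration, averaging each measure over five
independent seeds per condition:

- Koulakov knock-in and wild type: N = 1000, 10,000 epochs, activity
  balance scaled as described above; Math5 at the full 200-RGC /
  2000-SC-neuron geometry with 2500 epochs (the rejection fraction
  plateaus above 0.99 well before these counts).
- Gierer: full scale (N = 2000, 10,000 epochs for the knock-in; 8000
  for Math5, past the point where coverage stops changing) — the exact
  integrator makes this cheap.
- Whitelaw: N = 400, 4000 epochs (the wild-type lattice measures
  plateau by ~5000 at N = 500).
- Willshaw: N = 400, 14,400 steps at dt = 1/3 (the same total
  integration time as the reference 48,000 x 0.1; the explicit steps
  remain stable at this dt).
- Collapse detection uses 50 NT bins at N = 2000 and 20-25 bins at
  desk sizes, keeping roughly ten central-third RGCs per bin.

Stochastic spread at these sizes is larger than at full scale, and two
measures are known to sit away from their full-scale values here: the
wild-type Koulakov lattice-node percentage (a single local defect costs
several "all-edges-retained" nodes, and defect frequency grows as the
per-circle RGC count falls) and the Gierer Math5 coverage (the occupied
basin's area fraction depends on the SC outline geometry, for which
this package ships an analytic stand-in).  The per-seed values printed
by the script carry the spread.

## Known limitations

- The SC outline is an analytic stand-in; absolute coverage percentages
  depend mildly on its shape.
- The Koulakov activity balance is calibrated, not derived; the
  published parameter path could not be reproduced verbatim (see above).
- Willshaw maps rotate slowly on very long runs (the plastic gradients
  are not locked to the axes); orientation-sensitive measures are
  meaningful only at the reference step count.
- The collapse detector's distinctness rule is scale-aware but
  heuristic; positions within ~1 bin width of the true merge are the
  realistic resolution.
- No activity-perturbed genotypes, no countergradients, no 3D fiber
  ordering: out of scope by design.
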
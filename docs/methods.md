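# Methods

This note documents the models and conventions implemented in `poreform`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Units and coordinate conventions

All internal lengths are Å, times ps, temperatures K, energies kcal/mol
(R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹); conversions happen only at I/O
boundaries. Boxes are orthorhombic; triclinic input is rejected with a
clear error — the supported systems are flat bilayer patches. The
membrane normal defaults to z and is configurable. The bilayer midplane is
defined per frame as the lipid centre of mass along the normal and moved
to 0 by `recenter_frame`; recentering is a pure translation, so all
minimum-image distances are preserved.

## Oligomer census

Two peptides are in contact when the minimum over all heavy-atom
(non-hydrogen) pairs of their minimum-image distances is strictly below
the contact cutoff (default 3.5 Å). Maculatin contains no sulfur, so "all
non-hydrogen" coincides with N/C/O heavy atoms for this system. An
oligomer of order *n* is a connected component of size *n* ≥ 2 of the
contact graph. The transitive (component) reading, rather than a clique
reading, is deliberate: ring-shaped hexa- to octameric pores have
non-adjacent members that never touch, so a clique criterion would deny
the existence of exactly the structures of interest. A clique mode exists
behind a flag for comparison. Contact search uses minimum-image distances
throughout; pores sitting on a periodic boundary are found correctly.

Aggregates larger than 8 peptides are reported as-is and additionally
decomposed by re-running the component search within the aggregate at a
tighter cutoff (default 3.0 Å), reflecting the observation that such
aggregates are lower-order pores in lateral contact rather than giant
pores.

Occupancy of order *n* in a frame is *n*·(number of order-*n*
oligomers)/N, the fraction of peptide mass concentrated in that state;
monomers are order 1, so each frame's occupancies sum to exactly 1 — an
invariant asserted in the tests.

## Permutation-invariant clustering

Because the peptides are identical, two instances of "the same" pore may
consist of entirely different peptides, or the same peptides in a
different ring order. The similarity between two order-*n* observations
is therefore the minimum over all *n*! member correspondences of the
least-squares superposition RMSD; within one correspondence the
atom-to-atom mapping is fixed by sequence. Superposition uses the SVD
(Kabsch) solution restricted to proper rotations (determinant sign
correction), so mirror images do not superpose to zero. "Backbone" means
N, CA, C (carbonyl O excluded); the choice is configurable and recorded
in output metadata. Permutations are enumerated with Heap's algorithm and
capped at n = 8 (40,320 comparisons) by default because the cost is
factorial.

Clustering is deterministic leader (founder) clustering: observations are
scanned in chronological order, each joining the first cluster whose
founder is within the 4 Å cutoff, else founding a new cluster. This makes
results reproducible and order-stable; the cutoff applies founder↔member.
Representatives minimise the mean permutational RMSD to co-members.
Clustering is invariant to peptide relabelling and rigid motion of any
observation (asserted in tests). An optional centroid lower-bound
prefilter can skip correspondences provably unable to beat the current
minimum (for any rigid transform, the mean squared deviation of member
centroids never exceeds that of all atoms); it is off by default and
oracle-identical when on.

Ring orientation schemes label each member N or C by the sign of its
helix axis (oriented N→C) on the membrane normal, read in angular order
around the ring and canonicalised under ring rotation, reflection and the
global up/down flip — so NCNC and CNCN are one scheme, and an all-parallel
ring has a single canonical form regardless of which leaflet it points
to. The antiparallel fraction of a set of observations is the fraction of
ring-adjacent pairs with opposite labels.

## Insertion states and free energy

The helix axis is estimated from cross products of successive second
differences of the CA trace, which is exact for an ideal helix of any
length (a plain principal-component axis is biased by up to ~1.5° on
fractional helical turns); a principal-component fall-back covers straight
traces. Tilt is folded to [0°, 90°].

S/TM classification: TM requires tilt < 50° and |COM depth| < 8 Å; S
requires tilt > 70° or |depth| > 12 Å; between the thresholds the previous
state persists (hysteresis), suppressing single-frame flicker; the first
frame in the dead band is assigned by the nearer threshold. These
thresholds are not dictated by any measurement — they are chosen so that
ideal surface helices (tilt ≈ 90°, |z| ≈ 15 Å) and ideal TM helices
(tilt ≲ 30°, z ≈ 0) classify unambiguously; all four are configurable and
logged.

The two-state free energy is ΔG(S→TM) = −RT ln((1−p_S)/p_S), positive
when the surface state dominates. The temperature must be supplied by the
user (simulated ensembles are commonly run far above ambient); the
default 373 K is logged with a warning. A fully one-sided split has
infinite ΔG and is reported as censored rather than a number.

Density maps histogram peptide mass along the normal (1 Å bins) per
frame, then smooth with a 10-frame moving average along time, shrinking
the window symmetrically at the edges. Column mass before smoothing
equals the total peptide mass — asserted in tests.

Standard errors of time averages use block averaging over 10 contiguous
equal blocks (remainder truncated): s.e.m. = sd(block means)/√10. Block
averaging is the appropriate estimator for correlated time series, where
naive i.i.d. errors are underestimates.

## Conduction counting

A crossing is scored by a three-region state machine per particle: below
(z < z_lo − b), above (z > z_hi + b), slab in between, with buffer b
(default 2 Å) providing hysteresis against thermal rattling at the slab
faces. An event is recorded only when a particle that last committed to
one outer region commits to the opposite one; excursions returning to the
starting side count nothing. Slab boundaries default to the mean lipid
leaflet planes; an optional pore-axis filter keeps only events whose
particle stayed within a lateral radius of the pore centre of mass while
inside the slab. Event counts are invariant to finer time resampling, and
reversing a track reverses all directions while preserving counts. Applied
voltage is metadata only — this toolkit analyses trajectories, it does not
impose fields. Water flux is additionally reported as volume flux at
29.9 Å³ per water molecule (bulk value, stated in output metadata).

## Pore lifetimes and Arrhenius extrapolation

Pore stability is tracked as backbone RMSD to the initial pore structure
with the identity peptide correspondence (the same physical pore is
followed, so no permutation search). Dissolution (τ) is the first time
the RMSD exceeds a threshold (default 6.0 Å, above the typical ~3.5 Å
equilibrated baseline) and stays above it for a persistence window
(default 50 frames); single-frame spikes do not count, and series that
never sustain the excursion are censored at their run length. Both
parameters are configurable and echoed in output; τ is monotone
non-decreasing in the threshold.

The Arrhenius model is τ(T) = A·exp(Ea/RT), fitted as ln⟨τ⟩ against
1/(RT): replicates are averaged per temperature first (each fitted point
is a replicate mean), censored replicates are excluded with a logged
count, and the line is fitted by least squares weighted by replicate
count — with equal replicates this reduces to ordinary least squares. The
parameter covariance is scaled by the residual variance with k−2 degrees
of freedom (k temperatures), and confidence intervals use Student-t
quantiles, which gives honest coverage at the small k typical of a
temperature ladder (simulation study in the test suite: 95 % intervals
cover the true Ea ~95 % of the time at k = 5, 8 replicates, lognormal
noise σ = 0.3). Extrapolated lifetimes carry multiplicative intervals via
the delta method on ln τ. Mean-then-log (rather than mean-of-logs) is
used because the plotted quantity is the average of replicate
simulations; a survival-analysis treatment of censoring is out of scope.

## Bench-top calculators

Peptide masses use a standard average (not monoisotopic) residue-mass
table plus one water for the termini; C-terminal amidation substitutes
NH₂ for OH (−0.98 Da). Computed values for amidated maculatin and its
P15A and P15A+E19Q mutants agree with the mass-spectrometry reference
values within ±0.1 g/mol (small residue-table provenance differences
remain below that).

CD titrations are analysed in the two-state mole-fraction convention: the
folded fraction f = (θ−θ_U)/(θ_F−θ_U) follows f = K_X[L]/([W]+K_X[L])
with [W] = 55.3 M; K_X is fitted by least squares and ΔG = −RT ln K_X.
Noiseless curves recover K_X exactly (asserted).

The pore-sizing estimate treats the dye as a sphere of its molecular
volume (partial specific volume 0.73 cm³/g) and the pore as a ring of n
helices of effective diameter d (default 10 Å) with centres on the ring
circumference: lumen radius = n·d/2π − d/2. The smallest n with a
positive lumen at least the dye radius is reported; for a ~427 Da dye
(radius ≈ 5 Å) this gives n = 7, and n ≥ 4 always (a smaller ring has no
lumen). This is explicitly an order-of-magnitude estimator and is
labelled as such in output.

The cuvette thermometer calibration T_actual = 0.766·T_setting + 4.715 °C
is implemented exactly as printed. Note the published figure caption that
pairs 74 °C with setting 95 °C is inconsistent with this line (which gives
77.5 °C at 95); the formula is implemented as stated and the discrepancy
is documented here rather than resolved.

## Synthetic data: what it emulates and what it does not

The generator produces ideal backbone-only α-helices (1.5 Å rise, 100°
twist per residue, CA radius 2.3 Å; N and C atoms placed on the same
helical path at fractional offsets), assembled into ring bundles with a
chosen orientation scheme, or laid flat at the leaflet surfaces on a
lateral grid. The bilayer is a coarse placeholder: one pseudo-atom plane
per leaflet at ±17.5 Å, sufficient for recentering, depth measurement and
slab detection, not for any lipid-scale analysis. Frames carry Gaussian
positional noise (default σ = 0.1 Å) — kept deliberately small relative to
the ~0.7 Å contact-decision margins of the constructed geometry, so the
generated labels remain the unambiguous truth under any seed; real
thermal fluctuations are larger and would blur the labels themselves.
Ring bundles use an adjacent-axis spacing of 6.2 Å, placing neighbouring
backbones well inside the 3.5 Å contact cutoff and non-adjacent ring
members well outside it; grid spacing keeps free monomers ≥ ~9 Å apart.
Default frame spacing is 100 ps, mirroring multi-μs trajectories at
reduced scale. Ion tracks are one particle per true crossing (traversing
the slab in 10 ns) plus non-crossing distractor excursions; lifetime
tables are exact Arrhenius values with multiplicative lognormal noise.
All generators are bit-reproducible under a fixed seed.

Consequently, passing tests demonstrate the correctness of the analysis
algorithms on systems whose truth is known — they do not demonstrate that
any particular biological system behaves this way, and quantities that
depend on real sampling (equilibrium S/TM fractions, antiparallel
preference percentages, absolute conductances, absolute lifetimes) are
not reproduced at desk scale.

## Problem sizes used in the checks

The census-recovery check runs 16 peptides over 200 frames with a
scripted schedule covering orders 2–8; the clustering oracle compares 100
random pairs per order n = 2–5 against exhaustive enumeration; conduction
recovery uses 100 seeds at 0/5/10 events per μs over 2 μs; the Arrhenius
study uses 200 synthetic studies of 5 temperatures × 8 replicates. These
sizes were chosen so the whole suite completes in well under a minute per
check while keeping the statistical assertions (median error, CI
coverage) meaningful.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- Homo-oligomers only: all peptide chains must share one residue count
  and atom layout. Sequence-heterogeneous assemblies are out of scope.
- The permutational search is exact and therefore factorial; orders above
  8 require the (lossless) prefilter or thinning, not approximations.
- Censored lifetimes are excluded from the Arrhenius fit, which biases τ
  downward if censoring is heavy; a survival model is not provided.
- The S/TM thresholds and the unfolding trigger are conventions, not
  measurements; all are configurable and recorded in output so results
  are interpretable.
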
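# Methods

This note documents the models, numerical choices and limitations behind
`ensa`.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

Ensembles are ordered lists of frames (coordinates in Å, timestamps in
ps, one trajectory id per frame) over a shared topology; residues are
numbered from 1, so F4 is the fourth residue.  Topologies store per-atom
masses and van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å,
overridable).  Hydrogens carry no radius and never enter surface areas —
the package assumes a united-atom provenance of the conformations;
where an amide hydrogen is needed (hydrogen-bond energies) it is placed
geometrically.  Multi-model PDB is the interchange format (read/written
through biotite); frame k of a file receives time k × interval (default
100 ps, the conventional saving interval for this kind of data) unless
explicit `REMARK ... TIME=<ps>` lines are present.

## Equilibration trimming

Frames earlier than a cut (default 200 ns) are discarded per trajectory,
the boundary frame inclusive.  The default reflects the time such
peptides need to lose memory of their starting structure; it is a plain
parameter.

## Contact-map spectral clustering

A contact is declared when the mass-weighted centres of the main-chain
atoms (N, CA, C, O) of two residues lie strictly closer than 4.5 Å.
Pairs closer than 3 in sequence are excluded: chain connectivity keeps
their centres permanently near the cutoff, so those bits carry no
information (in an ideal helix the separation-3 centre distance is
5.0 Å, separation-2 is 4.6 Å — both straddle the cutoff under thermal
jitter).  The exclusion and the cutoff are configurable.

Fingerprint dissimilarity is the normalised Hamming distance h (pdist
`hamming`), which for binary vectors equals the squared Euclidean
distance divided by the vector length.  The affinity is the Gaussian
radial-basis kernel A = exp(−h/2σ²) — positive semidefinite precisely
because h is a squared Euclidean distance; exponentiating h² instead
would give an indefinite kernel.  σ² defaults to the median h over a
deterministic subsample of at most 2000 pairs.  If all fingerprints
coincide the affinity degenerates to all-ones and a warning is issued.
A raw-similarity mode (1 − h) is available.

Frames are embedded by the top singular vectors of A (7 by default,
capped at the numerical rank), each scaled by its singular value, with
the sign of each vector fixed so its largest-magnitude entry is
positive — making the embedding deterministic.  Clustering is k-medoids
in that embedding: k-means++-style seeding on the distance matrix,
followed by alternating assignment and an *exhaustive* medoid update
(each medoid is the member minimising the within-cluster distance sum),
best of 10 seeded restarts.  The exhaustive update was chosen over
PAM-style swap chains because it directly guarantees the reported
medoid-optimality property at convergence, and medoids must be actual
frames (cluster representatives are inspected as structures).  The
elbow scan reports the best within-cluster sum per candidate k and
suggests the k of maximum discrete curvature; the suggestion is
advisory — for heterogeneous disordered ensembles a fixed k (default
10) is a legitimate override.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-section spiral lattice
(default 960 points/atom) on each probe-expanded sphere (probe 1.4 Å).
A test point is buried iff strictly inside a neighbouring expanded
sphere; the strict inequality is applied with a 10⁻¹⁰ relative margin so
that a point lying exactly on a neighbour's sphere (e.g. coincident
atoms) remains exposed despite floating-point rounding.  The burial
loop is JIT-compiled when numba is available; a pure-numpy path produces
bit-identical results and is covered by a test.

Two properties trade off against each other and the fixed lattice picks
a side deliberately: monotonicity (removing an occluder never decreases
any area) and translation invariance are **exact**, while rotation
invariance holds only to quadrature resolution (totals to ~0.1%,
individual atoms to a few Å²), because rotating the molecule re-samples
a space-fixed lattice.  Doubling the point count halves the quadrature
error; the defaults resolve the ~300 Å² state separation that matters
here by two orders of magnitude.

The collapse coordinate is the summed SASA of all atoms of a hydrophobic
residue set (default F4, V18, F20, A21, I31, L34, V36 — side-chain stubs
included, since residue exposure, not backbone exposure, is what a
collapse buries).

## State classification

CS iff SASA < `cs_max`, ES iff SASA > `es_min`, INT otherwise; both
thresholds are read strictly, so a value exactly at 550 or 650 Å² is
intermediate.  The absolute defaults (550/650 Å²) are meaningful only
relative to a force field and SASA convention; **for synthetic data the
thresholds must be recalibrated** — `calibrate_thresholds` puts them at
the midpoint of the two generated populations (optionally with a gap).
State probabilities are frame fractions; they are independent of
clustering and invariant to trajectory concatenation order.

Appearance time of a cluster (in ns) defaults to the mean timestamp of
the cluster's frames within each trajectory containing it, averaged over
those trajectories; a first-occurrence mode is provided for onset-style
questions.  The per-trajectory-then-average convention keeps long
trajectories from dominating the statistic.

## Secondary structure

Hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, with the amide
H placed 1.01 Å from N opposite the bisector of the C(i−1)–N and CA–N
bonds (for residue 1 the own-residue C substitutes for the missing
preceding carbonyl), and the standard −0.5 kcal/mol acceptance cutoff.
Sequence separation < 2 is never scored.  The assignment is a
three-letter collapse of the usual eight classes: two consecutive
i→i+4 turns mark α-helix (H); residues in parallel or antiparallel
bridges mark strand (E, isolated bridges included, matching the usual
{E, B} pooling); everything else — turns and bends included — is C.
π/3₁₀ helices and β-bulges are deliberately out of scope: the contract
is robust H/E/C occupancy, not 8-class fidelity.  Labels from an
external DSSP run can be imported and collapsed with
`collapse_dssp_codes`.  Occupancy profiles are per-residue fractions
over frames and always sum to 1.

## NMR validation

³J(HN−Hα)(φ) = a·cos²(φ−60°) + b·cos(φ−60°) + c, the standard −60°
phase.  The default coefficients (7.7, −1.9, 0.06 Hz) are the set that
fits disordered-peptide ensembles best in our hands; two classical
alternatives are selectable by name.  Ensemble couplings are arithmetic
means of per-frame values.  Fitting averages the two trigonometric
basis terms per residue over the ensemble *first* (motional averaging)
and then solves a single linear least-squares system across residues; a
design matrix of rank < 3 (e.g. all φ identical) is rejected.
Agreement statistics are the RMSD between observed and calculated
values and the Pearson correlation coefficient.  Residual dipolar
couplings are not back-calculated (that requires an external alignment
model); RDC tables computed elsewhere feed the same two statistics.

## Synthetic data

All generators are pure functions of (specification, seed).

*Backbone builder.*  NeRF chain extension with ideal internal
coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329 Å; N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°); carbonyl O and a Cβ stub are
placed from standard geometry.  Requested dihedrals are recovered by the
measurement code to 10⁻⁵ degrees (round-trip property).

*Two-state ensembles.*  The compact template is an N-terminal 6+2+6
antiparallel β-hairpin followed by an α-helix; the extended template is
a straight strand (−139°, 135°).  The hairpin-plus-helix choice is
deliberate: a helix alone gives a large, jitter-robust SASA gap
(~310 Å² for the default 42-residue chain and hydrophobic set) but *no*
main-chain-COM contacts under the 4.5 Å definition, whereas pure sheets
give contacts but a jitter-fragile gap; the hybrid provides both a
robust exposure gap and ~5 long-range contact bits per compact frame,
so the planted states are separable on both axes the pipeline uses.
Gaussian dihedral jitter (default sd 8°) perturbs both templates; the
mixing fraction (default 0.7) is allocated exactly and shuffled in
time.  The generator verifies a ≥200 Å² mean SASA separation on a
subsample and redraws (bounded retries) otherwise.  These templates are
abstractions: they plant the *statistical* structure the analysis needs
and make no claim about real side-chain packing.

*Markov trajectories.*  A two-state chain per trajectory (default 2%
switching per 100 ps frame, i.e. ~5 ns dwells) with frames drawn from
the matching template; the true state path is returned.  For validating
the first-arrival statistic against the geometric closed form
E[T] = interval/p, the check uses a fast-switching chain (p = 0.97) and
50 trajectories: the relative standard error of the mean first arrival
is √(1−p)/√50 ≈ 2.5%, chosen by power analysis so the 5% comparison
band sits at ≈2 standard errors.  The late-vs-early ordering check uses
a persistent chain instead.

*J-coupling tables.*  Per-residue φ basins cycle through centres
(−150°, −60°, 0°, 60°, 150°) — spanning cos(φ−60°) from −0.87 to 1,
including 0 — with 15° within-residue spread, so both basis terms vary
strongly across residues and the three coefficients are identifiable:
under the 0.1 Hz noise / 30 residue conditions the largest per-seed
coefficient error across 100 noise draws stays within ±0.2.  Observed
values are exact ensemble means plus Gaussian noise; the noiseless fit
recovers the generating coefficients to 10⁻⁸ (inverse-problem
identity).

*What passing synthetic tests does not show:* realism of side-chain
packing, force-field accuracy, absolute SASA thresholds, or convergence
of real sampling.  They establish that each statistic computes what it
claims on data whose truth is known.

## Pipeline and determinism

`run_pipeline` executes, per group: trimming → fingerprints → affinity →
embedding → elbow scan and k-medoids → SASA states, probabilities,
per-cluster SASA and appearance times → secondary-structure occupancy →
(optionally) J-coupling/RDC comparison statistics.  All randomness
derives from one seed; tables are written with fixed formats so a rerun
is byte-identical, which the test suite checks by hashing the outputs of
two runs over two 1000-frame groups.  Problem sizes in the shipped
tests and in `scripts/acceptance.py` (hundreds to a few thousand
frames, 42 residues) were chosen as the smallest at which every
statistic is statistically meaningful; all scale linearly in frames
except the affinity/embedding stage (quadratic in frames per group).

## Known limitations

* The SASA rotation non-invariance discussed above (quadrature-level).
* The simplified assigner ignores π/3₁₀ helices and β-bulges; helix
  content is slightly conservative at chain ends.
* k-medoids optimises a local objective; restarts mitigate but do not
  eliminate dependence on seeding for poorly separated data.
* Absolute CS/ES thresholds transfer across force fields and SASA
  conventions only qualitatively.
* The multi-model PDB reader assumes a consistent atom order across
  models (violations are rejected, not repaired).
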
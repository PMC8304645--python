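# Methods

`ifacedyn` analyses the stability of the binding interface in a two-chain
protein complex — the model system is the microsomal triglyceride transfer
protein (MTP), a heterodimer of the large lipid-transfer α subunit and
protein disulfide isomerase (PDI), with or without the small-molecule
ligand 17β-estradiol bound at PDI's b′ domain.  Three families of metrics
are implemented: geometric interface metrics on static conformations,
distance-fluctuation statistics on trajectories, and free-energy
estimation from steered-pulling work records.  A synthetic-data module
supplies every input with known ground truth, so each stage is testable
without running molecular dynamics.

## Interface definitions

Two complementary definitions are used throughout, both with inclusive
cutoffs:

* **Interface atom pair** — two atoms, one per binding partner, within
  5 Å in a given conformation.  Hydrogens participate if present; a
  `heavy_only` switch removes them.
* **Interface contact** — a residue pair, one per partner, whose Cα–Cα
  distance is ≤ 7 Å in *at least one* analysed conformation.  Over a
  trajectory this is the union of per-frame contact sets, and contact
  sets from several trajectories and a crystal structure can be unioned
  further.

Counts and areas are decomposed by the PDI-side residue's domain:
N-terminal (18–25), a (26–133), b (137–232), b′ (235–349), x (350–368),
a′ (369–479) and C-terminal (480–508), in author numbering.  Residues in
the inter-domain gaps (134–136, 233–234) are tallied under a separate
"unassigned" row rather than silently inflating a named region.  Contacts
carry the coarser region labels used for the stability comparison:
region 1 (a), region 2 (b′), region 3 (a′) and region 3′ (C-terminal);
anything else is "other".

## Interface area

The headline area metric is **buried solvent-accessible surface area** of
the PDI partner: per atom, SASA in the isolated partner minus SASA in the
complex (probe 1.4 Å, Bondi-type radii, unknown elements fall back to
1.7 Å with a warning), summed and region-decomposed.  SASA is computed
with biotite's Shrake–Rupley implementation.  Because one point set is
shared by all atoms, a sparse set makes the buried total orientation
dependent; the default of 10,000 points per atom keeps rigid-rotation
drift below about 0.35% on dense fixtures (at 960 points it is ~1%).
Point count is exposed as a parameter.

An alternative **voronoi-contact** method reports the shared
power-diagram (Laguerre) facet area between inter-partner atom pairs
within r_i + r_j + 2·probe: the radical-plane disc of each close pair is
sampled with a deterministic sunflower layout and points claimed by any
third atom's power cell are discarded.  This is a facet estimator, not a
full 3-D tessellation; it satisfies the contract the pipeline relies on
(non-negative, region-decomposable, exactly zero for separated partners).
Neither method is claimed to reproduce areas computed by external
Voronoi-polyhedra tools.

## Mean-square fluctuation of distance (MSFD)

For contact (i, j) with per-frame Cα–Cα distance R_ij,k over N frames,

    MSFD_ij = (1/N) · Σ_k (R_ij,k − R̄_ij)²    [Å²]

i.e. the population variance with divisor N, following the defining
formula exactly; at N > 350 frames the difference from N−1 is negligible,
but the convention is applied uniformly (including in the work-variance
term below).  High MSFD marks a flexible, unstable contact.  A
frame-stride parameter (default 1: all stored frames) stands in for
"representative conformation" selection, which is otherwise
under-specified.

Two decision rules operate on MSFD tables:

* **C-terminal exclusion** — a contact is dropped iff its α-subunit
  residue lies in the flexible C-terminal tail (default interval 886–894,
  configurable) *and* its MSFD exceeds 14 Å² (strictly) in at least one
  of the supplied trajectories.  Both conditions are required; the
  partition and the triggering trajectory labels are reported.
* **Pairwise comparison** — between two conditions, a contact counts for
  a condition only when its MSFD there exceeds the other's by strictly
  more than 1 Å²; deltas of exactly 1 Å² fall in the neutral band.  The
  margin is configurable.

Region averages are arithmetic means over member contacts.  The pooled
four-region mean ("all_four") averages over all contacts in regions 1, 2,
3 and 3′; since the defining text does not disambiguate pooled mean vs
mean of region means, pooled is the default and a flag exposes the
alternative.  Empty regions are reported as absent, never as 0.

## Steered pulling and Jarzynski estimation

A constant-velocity steered simulation drags the α subunit with a
harmonic trap (stiffness k = 10 kcal/mol/Å², velocity v = 10 Å/ns by
default, 2 ns duration, 300 K) along a unit direction; the convention for
the direction is the vector from the Cα of α-subunit residue 595 to that
of residue 591.  The trap force is F = k·(x₀ + v·t − x) and the external
work is the trap work W(t) = ∫ F·v dt, integrated by trapezoidal
quadrature on the stored grid (the exact quadrature used upstream of the
records is not prescribed anywhere; trapezoid on the stored grid is the
package's convention, and work columns absent from input CSVs are
recomputed this way).

Free energy along λ = v·t comes from Jarzynski's equality
⟨e^(−βW)⟩ = e^(−βΔF) over replicas started from the same initial
conditions (β = 1/k_BT, k_B = 0.0019872041 kcal/(mol·K)).  Two estimators
are reported at every λ:

* **second-cumulant** (headline): ΔF ≈ ⟨W⟩ − β·Var(W)/2, population
  variance; exact in expectation for Gaussian work distributions;
* **exponential** (cross-check): ΔF = −(1/β)·ln⟨e^(−βW)⟩ via log-sum-exp.

Fewer than 10 replicas triggers a warning (not an error).  A
`lambda_max` truncation confines curves to the early pulling phase where
dissipation is modest; force–distance profiles report the replica-mean
trap force against the replica-mean displacement of the Cα midpoint of
the two marker residues from its t = 0 position (Euclidean magnitude by
default; projection on the pull direction via a flag).  The Cα spring
network builder (all α-subunit Cα pairs ≤ 7 Å in the initial structure,
springs of 10 kcal/mol/Å², rest length = initial distance) is provided as
a static construction; no dynamics engine consumes it here.

## Synthetic generators

All generators are pure functions of (spec, seed); identical inputs give
bit-identical outputs.

* **Toy complexes** place Cα atoms (plus one dummy sidechain atom per
  residue) in two tight clusters: a contact cluster geometrically
  guaranteed within 7 Å of every partner Cα and a far cluster beyond any
  cutoff.  The exact contact ground truth is re-derived by exhaustive
  enumeration on the generated coordinates, so it is correct whatever the
  random scatter did.
* **Fluctuation trajectories** move designated PDI-side residues along
  the contact axis so the pair distance is d₀ + δ_k with δ i.i.d.
  Gaussian (true MSFD = σ²) or sinusoidal over whole periods (true
  MSFD = A²/2, exact for sampled full cycles).  The default baseline
  distance d₀ = 20 Å keeps distances safely positive at the noise levels
  used; fixtures that must register as contacts use d₀ ≈ 6 Å with small
  σ.
* **Brownian pulling** integrates the overdamped Langevin equation
  γ·dx = (−U′(x) + F_trap)·dt + √(2k_BTγ)·dW (Euler–Maruyama, default
  dt = 10⁻⁵ ns, stability guard k·dt/γ < 0.1) from an equilibrium start
  sampled by grid inverse-CDF.  This is a deliberate scale reduction: a
  1-D process produces exactly the mathematical object the Jarzynski
  machinery consumes, with closed-form truth — ΔF(λ) = 0 for a flat
  potential, κkλ²/(2(κ+k)) for a harmonic well κ under trap k, and a
  numerical log-partition-function quadrature for the quartic double
  well.  Work is accumulated at full integration resolution and recorded
  at a stride.

What the generators do *not* emulate: real sidechain packing, hydrogen
bonding and ligand chemistry, correlated multi-residue motions, and the
3-D many-body dissipation of an explicit-solvent pull.  Passing tests
therefore validate the *estimators and decision rules*, not any claim
about the biological system; the published trajectory-derived numbers for
the MTP complex are not reproducible because those trajectories are not
deposited.

## Verification conditions and numerical choices

* Gaussian MSFD recovery is checked at N = 10⁵ frames, σ = 1.5 Å, within
  3 standard errors of a variance estimate (σ²√(2/N)); the sinusoidal
  limit at N = 10⁴ within 1%.
* Jarzynski estimators are checked on 10⁵ Gaussian work samples with
  σ² = 2k_BT (both estimators within 0.05 kcal/mol of μ − 1), on
  zero-variance ensembles (exact), and on a two-point ensemble against
  hand-evaluated closed forms.
* PMF recovery uses the quasi-static condition v = 0.1 Å/ns over 20 ns
  (dt = 2·10⁻⁴ ns, 100 replicas): dissipated work stays small enough that
  the second-cumulant estimate of ΔF(2 Å) = 20/11 kcal/mol lands within
  10%, and the flat potential recovers 0 within 3 standard errors of the
  cumulant estimator (SE² = Var(W)/n + β²Var(W)²/(2(n−1))).
* Brute-force equivalence (atom pairs, contacts, unions, spring networks,
  exclusion partitions, comparison counts) runs over ≥ 20 seeded fixtures
  per rule against plain-loop enumeration.
* Integer by-region counts must sum exactly; per-region areas must sum to
  the total within 10⁻³ Å².
* Degenerate inputs: single-frame trajectories are valid for contacts but
  rejected for MSFD (N ≥ 2); empty or overlapping partner selections,
  non-monotone time grids and mismatched replica grids raise errors
  naming the offender.

## Known limitations

* The crystal-structure contact count (43 inter-chain Cα ≤ 7 Å pairs in
  RCSB entry 6I7S) is asserted in the test suite but requires the user to
  supply the coordinate file at `tests/data/6i7s.pdb`; it is not
  redistributed.  The count is computed on the raw crystal coordinates —
  residues missing from the deposited model are not reconstructed.
* Whether published atom-pair counts include hydrogens, and whether
  published interface areas are per-side or summed over both partners, is
  not recoverable; both atom-pair modes are provided and neither is
  claimed to match the printed tables.
* Hydrogen-bond detection is out of scope; no distance-only proxy is
  offered as a substitute.
* The voronoi-contact method's facet areas depend mildly on the disc
  sampling density (96 points per facet, deterministic), adequate for the
  contract above but not for high-precision tessellation work.
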
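# Methods

## The torso model

The HCDR3 torso comprises positions T1–T3 (the first three loop residues,
immediately after the conserved V-gene Cys) and T4–T7 (the last four,
immediately before the J-gene Trp of the W-G-x-G framework-4 motif). Each
position carries a φ and a ψ backbone dihedral; φ(T1) needs the C atom of
the preceding framework residue and ψ(T7) the N atom of the first
framework-4 residue, so a torso fragment stores those flanking atoms
explicitly. All 14 angles are measured with an atan2-form dihedral under
the IUPAC sign convention (trans = +180°), reported in degrees on
(−180°, 180°].

The two torso classes, bulged and non-bulged, are summarized as
per-position circular means and approximate standard deviations. The
discriminating measurement is ψ(T6): ≈ −30° in bulged torsos versus
≈ +129° in non-bulged. ψ(T4) is bimodal *within* both classes (modes
~180° apart), so it is excluded from restraint derivation and from
classification distances; the apparent class difference in a pooled T4 ψ
summary is an artifact of sub-conformation sample sizes, not a usable
discriminator.

## Circular statistics

Mean direction: atan2(Σ sin αₙ, Σ cos αₙ). Dispersion: with R̄ the mean
resultant length of the unit vectors, σ ≈ √(2(1 − R̄)) (radians, converted
to degrees). The asymptotically equivalent √(−2 ln R̄) is available via
`circ_std_approx(..., method="log")`; for the dispersions seen in torso
data (σ ≤ ~60°) the two differ by under a few percent. A sample whose
resultant length is below 1e−9 has no meaningful mean direction and raises
an explicit error rather than returning an arbitrary angle. Angles offset
by full turns are accepted and equivalent, since every statistic passes
through sin/cos.

## Restraint derivation

For a target HCDR3 at sequential start *s* with length *L* ≥ 8, T1–T3 map
to residues *s*..*s*+2 and T4–T7 to the last four loop residues. φ(i) uses
atoms C(i−1), N(i), CA(i), C(i); ψ(i) uses N(i), CA(i), C(i), N(i+1).
Targets are class circular means; widths are class standard deviations
floored at `min_sigma` (default 1°) so a degenerate single-member class
cannot emit a zero-width restraint. x₀ and σ are rounded to 6 decimal
places in radians — the serialized precision — making write → parse an
exact identity. The penalty is Σ (Δ/σ)² with Δ the wrapped difference,
continuous across the ±180° branch cut. Non-bulged restraints can be
derived with the same machinery but have not been validated in modelling
benchmarks; only the bulged profile has.

## Classification

New torsos are labeled with a closed-form rule rather than by
re-clustering: the distance to each class is the std-scaled circular RMS
deviation over all non-excluded measurable angles, and the nearer class is
accepted only if the observed ψ(T6) lies within `sigma_mult` (default 3)
standard deviations of that class's ψ(T6) mean; otherwise the call is
indeterminate. This honors ψ(T6) as the class discriminator while using
the full profile for ranking. The base pseudo-angles α101 (pseudodihedral
over Cα of T5, T6, T7, FR4₁) and τ101 (planar angle over Cα of T6, T7,
FR4₁) support a window test against externally supplied reference
means/σ; no defaults are invented for those reference values, and τ101's
atom triple is anchored at the torso base consistently with the α101
quadruple. The closed-interval window uses a circular comparison for α101.

## Clustering

One greedy center-based algorithm serves both fragment separation and
decoy grouping: the item with the most neighbours within the radius
(ties → lowest input index) seeds a cluster; it and its neighbours are
removed; repeat. Fragment clustering operates on the concatenated T1–T3 +
T4–T7 backbone (N, CA, C, plus O when present on every residue) after
optimal superposition, radius 2 Å. Decoy clustering operates on loop Cα
coordinates, threshold 2 Å, and drops clusters smaller than
ceil(min_fraction·N) (default 1 %; for N = 1000 this keeps clusters of 10
or more — exactly 1 % is retained). Clustering is deterministic given input
order; tie behaviour is documented order-dependence.

## Evaluation metrics

RMSD16 adopts the Carugo–Pongor logarithmic length normalization rescaled
to reference length 16: RMSD/(1 + ln √(L/16)). It is the identity at
L = 16, strictly increasing in RMSD, and exposed as a pluggable formula
since no single convention is universal. Loop RMSD superposes model onto
native on framework Cα atoms (every residue outside the loop) and measures
loop Cα RMSD without re-fitting; loop-local superposition would hide
hinge-like displacement of an internally correct loop. Counting thresholds
follow the conventions of the metrics they feed: "models below 2 Å" is
strict (< 2.0); the blue funnel label uses RMSD16 ≤ 2 Å together with a
score rank within the top ceil(0.10·N). Cluster reports use dense 1-based
ranks; the "correct" cluster is the lowest-average-score survivor, the
operational choice when no native structure exists. A single surviving
cluster is flagged; zero survivors yield an explicit N/A report.

## Synthetic data

The fixture generator builds backbones from internal coordinates (NeRF
chain extension) with standard ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°), so
measured dihedrals reproduce requested ones to ~1e−6°. Class-conditional
torsos draw each non-excluded angle independently from a wrapped normal at
the profile's (mean, std) — adequate for σ ≤ 60° — and ψ(T4) from a 50/50
mixture of the two modes 180° apart; fragments are realized as 18-residue
chains (one flanking residue, T1–T3, a 9-residue extended head, T4–T7, one
framework-4 residue). Decoy sets perturb loop dihedrals by wrapped-normal
noise and assign scores a·RMSD16 + b + N(0, σ_s), recording true RMSD16
per decoy.

What this emulates — and does not. Synthetic torsos have ideal bond
geometry, uncorrelated angles and a fixed extended head; real structures
have correlated backbone angles, varied head conformations, side chains
and coordinate error. Consequences worth noting: independent-angle
sampling at full class dispersion is geometrically *more* diverse than
real class members, and the bimodal ψ(T4) necessarily splits each
synthetic class into sub-conformation clusters at the 2 Å radius — so
end-to-end tests assert partition and majority-composition properties of
the clustering rather than an exact two-cluster split. Passing tests
demonstrate correctness of the measurement, statistics, restraint and
metric machinery, not PDB-scale curation behaviour.

## Problem sizes and determinism

Tests and the acceptance script use the curated sample sizes where they
are the point (n = 218 bulged, n = 38 non-bulged draws for parameter
recovery; 200 torsos for classifier recovery; 100-seed sweeps for metric
oracles) and small decoy sets (30–100 models) elsewhere, keeping the full
suite under a minute on one CPU. All randomness flows through
`numpy.random.default_rng` with explicit seeds; per-target sub-seeds in
the acceptance script derive from a single `--seed` via `SeedSequence`.

## Known limitations

HCDR3 auto-location is anchor-motif based (last Cys before a W-G-x-G),
not a full IMGT numbering engine; curated definition tables are the
authoritative input, and ambiguous anchors produce an explicit no-call.
Multiple Fv copies per asymmetric unit must be disambiguated by the
definitions file. The classifier is a deterministic extension, not a
reproduction of cluster-taxonomy assignment. The greedy clustering matches
the common semantics of center-based decoy clustering tools but not any
specific tool's pruning heuristics.
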
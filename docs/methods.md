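# Methods

## The model and the matching rule

A pharmacophore model is an ordered list of spherical features, each with
a boolean type expression over five primitive feature kinds (aromatic
center, hydrophobic center, H-bond acceptor, H-bond donor, metal ligator),
a centroid in Å, a tolerance radius in Å, and an essentiality flag. The
built-in dual hIDO1/hTDO2 inhibitor model hard-codes the published
coordinates, radii, expressions and essential set; it does not infer
essentiality from data. In feature-type expressions `&` binds tighter
than `|` (so `ML|Acc|Don` is a flat OR) and parentheses override — the
convention consistent with both published expressions.

A candidate conformer is reduced to a feature set: typed 3D points.
Matching asks for an injective assignment of perceived features to model
features that

1. is type-compatible (the model feature's expression is satisfied by the
   perceived feature's kind set),
2. covers every essential feature and at least `min_match` features, and
3. after a rigid superposition, places every assigned feature inside the
   scaled tolerance sphere of its model feature.

Radius containment after least-squares superposition is the central
approximation of this package: commercial suites do not document their
internal acceptance rule, and the tolerance radii are the only tolerances
the model itself carries. Mirror images are rejected (proper rotations
only) because a 3D pharmacophore is chiral: an enantiomeric arrangement
should not be scored as a fit.

The angle convention for the geometry audit places the apex at the named
feature (the angle "at F1 with F3 and F4" is the angle F3–F1–F4); with
this convention every published distance and angle is reproduced from the
published coordinates to 0.01 Å / 0.1°. Full precision is kept
internally; rounding (2 dp for distances, 1 dp for angles) happens only at
presentation.

## Enumeration and superposition

Assignments are enumerated by backtracking over model features in order,
with pairwise-distance pruning: a pair (i, j) of assigned features
survives only if |d_perceived − d_model| ≤ radius_scale·(rᵢ + rⱼ) +
pair_slack. The default slack of 1.0 Å is deliberately generous — pruning
exists for speed, and the unit tests compare the enumeration against an
exhaustive brute-force oracle on instances with up to 8 perceived features
to guard against over-pruning. Maximal assignments are evaluated first;
ties among accepted fits break by lowest RMSD, then lowest conformer
index, making screening output deterministic.

Superposition uses the closed-form Kabsch/quaternion solution
(`scipy.spatial.transform.Rotation.align_vectors`) constrained to proper
rotations. Inside the matcher the least squares are weighted by
1/radius²: a feature's tolerance radius is read as a positional
uncertainty, so the inverse-variance weighting is the statistically
natural estimator and keeps tight features (the 0.4 Å metal-ligator
anchor) from being sacrificed to loose ones (the 1.5 Å aromatic centers)
during alignment. The acceptance test (containment) and the reported RMSD
are always unweighted. `superpose()` itself defaults to uniform weights.
One- and two-point sets return the translation-optimal (and for two
points, rotationally non-unique but valid) transform rather than erroring.

## Feature perception

The perception rules are this package's own documented SMARTS
approximation; the typing rules of commercial software are proprietary,
so per-compound fitting scores are not expected to transfer across
implementations. Defaults: aromatic rings (5/6-membered, ring-centroid
placement); hydrophobes as small aliphatic carbocycles (cyclopropyl
included), halogens on carbon, and chains of ≥ 2 non-polar sp³ carbons
(centroid placement); donors as N–H/O–H; acceptors as O and N with an
available lone pair excluding amide/sulfonamide N; metal ligators as
carboxylic-acid/carboxylate oxygens, pyridine/imidazole-type aromatic
nitrogens, thiol(ate) sulfur and phenol oxygen. Matches of different
kinds within 0.5 Å merge into one composite feature (union of kinds) —
the merge radius sits below the smallest model radius and prevents
double-counting sites like a carboxylate oxygen that is simultaneously
acceptor and metal ligator. Inputs get explicit hydrogens added before
perception (with coordinates when a conformer exists); there is no
tautomer enumeration or pKa-dependent ionization sampling. SDF 3D
coordinates are used as-is; SMILES input is embedded with seeded ETKDG
(10 conformers by default; the packaged drug fixtures use 3 for speed).
Users can replace the rules wholesale via a JSON rules file.

Because of all this, every quantitative guarantee in the test suite runs
on synthetic point-feature inputs; molecule-level perception is validated
qualitatively (known features of known molecules, and the ten packaged
drugs).

## Consensus model derivation

Input is an ensemble of ≥ 2 feature sets assumed to share one coordinate
frame — the product of a flexible-alignment step this package does not
implement (conformational search and alignment optimization are
proprietary, stochastic, and orthogonal to the consensus logic).
Features are clustered greedily in deterministic order (ligand index,
then feature index): a feature joins the first cluster whose running kind
intersection it overlaps, whose running centroid lies within the
clustering tolerance (1.15 Å by default, interpreted as Å — the value's
unit is otherwise undocumented, and Å is consistent with the feature radii
magnitudes), and which does not yet contain a feature of the same ligand.
Centroid linkage was chosen over complete linkage deliberately: at
realistic jitter (≈ 0.3 Å per coordinate) the probability that *every*
pair in a 12-member cluster stays within 1.15 Å is negligible, so complete
linkage shatters clusters that centroid linkage recovers cleanly.

Clusters supported by **more than** `threshold × M` distinct ligands
(default 50%) become features: center = mean position, expression = OR
over the kind intersection, radius = max(member deviation, 0.4 Å floor —
the smallest radius a published feature carries, preventing zero-radius
features from degenerate clusters). A feature is essential when its
support reaches `essential_threshold × M` (default 90%), and `min_match`
is the number of essential features (at least 1). Support counts ligands,
not conformers. AND-structure in expressions (like the metal-ligator
anchor's "must also H-bond") cannot be recovered from kind sets alone; a
re-derived model is honest about that and reports the OR of observed
kinds.

## Drug-likeness filtration

Lipinski (MW ≤ 500 g/mol, logP ≤ 5, donors ≤ 5, acceptors ≤ 10; pass with
at most one violation, per the rule's original formulation — configurable
down to strict all-pass) and Veber (rotatable bonds ≤ 10 and TPSA ≤ 140 Å²,
both inclusive). Descriptors are standard 2D RDKit values; logP is the
Crippen atom-contribution estimate and is implementation-defined, which is
why every threshold is a parameter.

## Synthetic benchmark

The validation design being emulated screens 56 actives against 207
decoys whose structures were never published, so the generator produces
abstract point-feature stand-ins with the failure structure the
validation is meant to detect, not molecules:

- **actives** — one point per model feature at centroid + isotropic
  Gaussian jitter (default sd 0.2 Å), kinds drawn uniformly from the
  minimal satisfying kind sets of each feature's expression, the
  non-essential feature dropped with probability 0.3, the whole set under
  a random rigid motion;
- **decoys** — round-robin over three modes by default: `type_scramble`
  (correct geometry; only two aromatic/hydrophobic-capable points and no
  metal ligator, so the essential features cannot all be assigned),
  `geometry_inflate` (correct kinds; all pairwise distances scaled ×3
  about the centroid mean), `feature_deficit` (two essential features
  deleted). Each mode guarantees no acceptable assignment under the
  default matcher, which the unit tests assert per mode.

Defaults (56/207, jitter 0.2 Å, dropout 0.3, inflation ×3) are the
package's standing benchmark conditions. Everything derives from one
integer seed and regenerates bit-identically from the recorded
provenance. What passing these tests shows: the matcher, validator and
plumbing are correct under a controlled noise model. What it does not
show: performance on real chemistry, where perception ambiguity,
conformational flexibility and decoys that are near-misses rather than
constructed failures all matter. Gaussian jitter is a modeling choice,
not an observed noise law; the sensitivity-vs-jitter sweep (monotone
non-increasing, tested at 0/0.5/1/2 Å) characterizes it.

## Validation statistics

The six screening statistics are computed exactly as ratios of confusion
counts and reported both as raw fractions and as percentages to 2 dp.
Metrics with zero denominators (e.g. specificity when validating against
actives only, as in an internal re-screen of a training set) are reported
as undefined rather than coerced to 100% — the distinction matters when a
report template expects all six.

## Problem sizes and determinism

The test suite runs the full 56/207 benchmark over 10 seeds (a few
seconds), the consensus recovery over 12-ligand ensembles, and brute-force
oracle comparisons on ≤ 8 perceived features, where exhaustive enumeration
is still cheap. Property tests are derandomized/seeded. All screening
output is deterministic given a seed; output files carry a provenance
header (version, config hash, seed).

## Known limitations

- No flexible fitting: conformational variety must come from the input
  ensemble; torsions are never optimized during matching.
- Perception is rule-based and shallow (no charge model, no tautomers);
  fitting scores for real molecules are qualitative.
- Consensus cannot recover AND-expressions or essentiality semantics
  beyond support frequency.
- The matcher's acceptance rule (radius containment after weighted
  superposition) is an approximation to an undocumented commercial rule;
  absolute hit rates on real libraries will differ between
  implementations even for the same model.
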
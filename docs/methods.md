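# Methods

This note documents the model behind `shapealign`, the parameters that
matter, the synthetic-data generator, and the design choices made where the
procedure was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and site selection

All coordinates are 0-based, half-open (BED convention). A width-*w* window
on a peak maximum *p* is `[p - w//2, p - w//2 + w)`; for odd *w* the peak is
the exact centre. Strand is ignored throughout — shape features are
computed from reverse-complement-symmetrized pentamer tables, so both
orientations of a site give mirror-image profiles (a documented
limitation: any genuinely strand-asymmetric signal is averaged away).

*Unique sites* at width *w* are those whose windows overlap no other site's
window, all classes pooled (the default; a single shared base pair
disqualifies both sites — the strict reading of "disjoint"). Because every
window has the same width, only neighbours in sorted order can overlap, and
the selection is order-invariant and non-increasing in *w*. Sites whose
201-bp shape window would leave the chromosome are dropped (never clipped)
with a warning.

*Null intervals* are placed by rejection sampling, uniform over all valid
start positions, with a hard cap of 1000 × n attempts; exhausting the cap
raises instead of silently returning fewer intervals. Null intervals avoid
every excluded window but may overlap one another.

## Shape features

Four features per base: MGW (Å, strictly positive), ProT, HelT, Roll
(degrees). Each interior position takes its values from the pentamer
centred on it; the two outermost positions per flank, and positions within
2 bp of an N, are undefined and imputed by copying the nearest defined
value (leftward on ties). Sites with more than 10% imputed positions are
excluded from alignment — a conservative default for a case the original
procedure does not address. HelT and Roll are base-pair-step quantities in
the underlying structural model; tables consumed here carry one value per
pentamer per feature, understood as the mean of the two steps flanking the
central base. Whether the original analysis used per-base or per-step
vectors is not stated anywhere we know of; the averaging convention is this
package's documented choice, and it is what makes a single per-position
vector of all four features possible.

The shipped default table (`toy_pentamer_table`) is **synthetic and
non-biological**: a deterministic function of pentamer A/T content plus a
fixed pseudo-random perturbation, symmetrized and kept within plausible
unit ranges. It exists so the package runs end to end with no external
data. For biological use, supply a real pentamer table as a
`(pentamer, feature, value)` TSV; the loader symmetrizes and completes
reverse complements.

## Alignment

`AlignmentConfig` defaults, shared by every site class:

| parameter          | default | meaning                                        |
|--------------------|---------|------------------------------------------------|
| `max_shift`        | 25 bp   | largest shift scanned (exhaustive, integer)    |
| `align_window`     | 90 bp   | interval centred on the peak maximum           |
| `center_exclusion` | 5 bp    | positions around each site's own peak excluded |
| `standardize`      | true    | per-feature z-scoring before cosine            |
| `recentre`         | true    | zero-mean the recovered shift distribution     |

The centre exclusion exists because free MNase cleaves A/T-rich DNA
preferentially, so the few bases at the cleavage point carry a shared
nuclease artifact rather than factor-specific shape. The mask travels with
each site's *own* peak: when two sites are compared at shift *s*, the
retained positions are the alignment interval minus the union of both
sites' masked centres; both comparison vectors then cover identical
positions, which is what makes a noiseless pair exactly recoverable. (The
single-site `site_vector` API returns the fixed-length 4 × 85 = 340
concatenation with only the site's own mask dropped, for serialization and
inspection.) Per-feature z-standardization puts Å and degrees on one scale
before concatenation; a zero-variance feature contributes zeros, and a
fully zero-variance vector is assigned similarity 0.

Tie-break: the scan runs 0, −1, +1, −2, +2, … with strict improvement, so
ties resolve to the smallest |shift|, negative before positive. Sign
convention: a positive shift moves the site's sampling window rightward to
match the reference.

The **centroid** is the member minimizing the sum of squared cosine
distances Σ(1 − cos)² to all other members under shift-optimized
similarity, ties broken lexicographically by site id. The phrase this
implements is sometimes rendered as "smallest sum of squared cosine
similarities", which read literally selects the *least* similar member;
`centroid_objective="similarity"` exposes that literal reading, but the
default is the central-member reading, which is the only one that makes an
alignment anchor.

**Recentring.** The centroid's own offset from the underlying signature is
arbitrary, so an alignment anchored on it is only defined up to that
offset. Since class averages are later compared *without* shifting them
against each other, all classes must share a frame; the only frame they
have in common is the peak maximum. Subtracting the rounded mean shift
restores it (the mean planted offset is the estimator of the frame, and its
error is below half a position for realistic class sizes). With
`recentre=False` the raw centroid frame is kept, in which the centroid's
shift is exactly 0 and every |shift| ≤ `max_shift`; with recentring those
two invariants hold up to the (small, integer) anchor offset, which is
recorded on the result. There is no iterative refinement: alignment is a
single pass against the centroid.

Aligned matrices keep raw feature units over the 90-bp interval, with each
site's excluded centre flagged rather than removed, so class averages are
physically interpretable; the exclusion positions are dropped again (and
features re-standardized) inside `compare_class_averages`.

## Shape profile and scoring

The profile is built from the reference (fast) class:

* **Background**: per site, either the underlying window sequence is
  mononucleotide-shuffled and its shape recomputed (sequence mode), or —
  for track-only inputs, where no sequence exists — the site's aligned
  values are permuted across interval positions per feature, a documented
  approximation. Default 100 shuffles, seeded.
* **Information gain**: per feature, values are binned into 10 equal-width
  bins spanning the pooled observed+background range; gain at a (feature,
  position) is the KL divergence, in bits, of the observed aligned-site
  distribution from the background distribution there, with a pseudo-count
  of 0.5 per bin. Gain is clipped at 0 against floating-point noise.
* **Regions**: positions with gain above the 90th percentile of all pooled
  gain values form runs per feature; runs separated by fewer than 3
  positions merge (bridging base-resolution texture dips inside a real
  region), runs shorter than 5 positions drop (suppressing isolated
  noise hits). All five constants (bins, pseudo-count, top fraction, merge
  gap, minimum run) are config-exposed; none is prescribed by the original
  procedure, and the defaults are deterministic and scale-free. The
  permissive top-10% budget means a few weak background runs can accompany
  the real regions; scoring is dominated by the strong ones.
* **Scoring**: both the stored profile values and the site being scored are
  z-standardized per feature over the full interval (otherwise the
  correlation across concatenated features is dominated by the baseline
  offsets between Å and degree scales and every site scores alike); the
  score is 1 − Pearson *r* over the profile regions, in [0, 2], with
  zero-variance sites scoring 1.

## Class statistics

* Pearson on class averages: exclusion positions dropped, per-feature
  z-scoring, flattened 4-feature vector, two-tailed *p* from the *t*
  distribution with n − 2 df; constant input reports r = NaN rather than 0.
  A per-feature mode reports the four individual correlations.
* Mann–Whitney on scores: exact enumeration when both samples are ≤ 8
  without ties, otherwise the tie-corrected normal approximation with
  continuity correction; fully tied data reports U = n₁n₂/2, p = 1. The
  normal approximation tracks exact enumeration closely for moderate
  p-values but, like any normal tail approximation, degrades in the extreme
  tails even at small n.
* Gene assignment: distance from the peak maximum to the nearest gene
  boundary (0 inside a gene body), threshold 1 kb, ties to the leftmost
  gene start; a TSS-only mode is a flag, since "closest gene" is ambiguous.
* Fisher's exact (two-sided) on associated/not 2×2 tables per test class
  versus each control class, flagging p < 0.1; "documented" and "proposed"
  evidence are pooled by default, with a flag to split. No multiple-testing
  correction by default (raw two-tailed p-values are reported); a
  Benjamini–Hochberg helper exists but is opt-in.

## The synthetic-data generator

The generator provides ground truth for every stage. Defaults
(`SimulationSpec`): 1 Mb genome over 2 chromosomes at GC 0.40; 200 sites
per class; fast/slow/free-MNase peaks placed with pairwise-disjoint 201-bp
windows; the random class drawn as null intervals avoiding all peak
windows.

**Signature.** Fast and slow sites share a planted deformation spanning
21 bp, centred 15 bp right of the peak maximum, with per-feature peak
amplitudes MGW −1.5 Å, ProT −4.0°, HelT +1.0°, Roll −2.0° — the sustained,
plateau-like distortion of a poly(dA:dT) tract (progressive minor-groove
narrowing, strongly negative propeller twist, reduced roll, slightly
over-wound helix), not a smooth bump. On the plateau sits a fixed aperiodic
±0.6 base-resolution texture (3-bp edge tapers), one pattern per feature,
shared by every site carrying the signature: pentamer-predicted shape
varies base to base, and it is precisely this fine structure that makes the
alignment identifiable to single-base precision — a smooth deformation has
near-unity lag-1 autocorrelation, and *no* estimator can localize it
exactly under realistic noise, while a *periodic* texture creates spurious
secondary alignment optima at multiples of its period. The aperiodic
pattern is part of the signature's identity and does not vary with the
simulation seed.

**Offsets.** Each fast/slow site's signature is displaced by an integer
offset, a random permutation of a balanced multiset over ±10 bp: every
offset value appears (nearly) equally often and the multiset sums to zero.
Marginally each site's offset is uniform over the range, but the class mean
carries no sampling error, so the peak-maximum frame is exactly
identifiable and recovered shifts can be compared to planted offsets
absolutely rather than up to a random ±1 anchor.

**Noise.** Per-position Gaussian noise with sd = `noise_sd` × the feature's
peak amplitude (default 0.25); slow sites get twice that sd
(`slow_noise_factor=2`), encoding "slow sites are noisier". All MNase-cut
classes (fast, slow, free-MNase) additionally carry a fixed A/T
cleavage-bias dip (MGW −1.0 Å, ProT −2.0° over the central 5 bp) at their
unshifted peaks — the artifact the centre exclusion exists to remove; the
random class does not, since its "peaks" are not cleavage sites.

**What it does not emulate.** Read-level cleavage data and peak calling;
sequence–shape covariation in track mode (the default track is baseline +
noise + plants, not sequence-derived; the optional `at_tract` mode embeds
literal poly(dA:dT) runs and computes tracks through the pentamer table so
the sequence and track paths can be exercised jointly); biological
heterogeneity of signature span, amplitude, or multi-factor site
composition; strand asymmetry. Passing tests therefore demonstrate that
the pipeline recovers what it assumes — a shared localized signature under
additive noise — not that any particular biological dataset contains one.

## Problem sizes

The defaults used by the test suite and the acceptance script are the study
conditions themselves: 200 sites per class, 1 Mb genome, 100 background
shuffles, 2,000 null replicates for the Mann–Whitney calibration and 1,000
for the Pearson p-uniformity check. Unit tests run a smaller instance
(25 sites per class, 150 kb) of the same generator.

## Known limitations

* Alignment is single-pass against one centroid; a noisy centroid degrades
  every comparison, and no profile-refinement iteration is attempted.
* Cosine similarity between two sites is exactly symmetric only up to edge
  content (swapping the pair negates the shift but samples slightly
  different window columns); the property tests assert symmetry of the
  shift and near-equality of the similarity.
* The value-permutation background destroys positional structure but keeps
  each site's value marginal; it is a stand-in for sequence shuffling, not
  an equivalent.
* Score distributions and profile regions inherit the arbitrary constants
  of the information-gain construction; conclusions should be robust to
  them, and they are exposed in the configuration for sensitivity checks.
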
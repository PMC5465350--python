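# shapealign

Motif-independent alignment, profiling and class statistics for DNA shape
features at protein binding sites.

## The problem

Whether a transcription factor recognizes its sites through base readout
(hydrogen bonds to the edges of the base pairs) or through shape readout
(the local three-dimensional geometry of the double helix) is hard to settle
*in vivo*, because sequence and shape covary: any analysis that centres
binding sites on their best motif match has already conditioned on sequence,
and the shape features it recovers are partly an echo of the motif itself.

`shapealign` implements the alternative: align binding sites using **only**
their DNA shape feature vectors — minor groove width (MGW, in Å), propeller
twist (ProT), helix twist (HelT) and roll (all in degrees), predicted per
base from the pentamer centred on it — and then ask whether different classes
of sites (e.g. strongly-bound "fast" and weakly-bound "slow" ChEC-seq sites,
versus free-nuclease and random controls) share a common shape signature.
In budding yeast, the signature of interest is the sustained minor-groove
narrowing that a binding-site-proximal poly(dA:dT) tract imprints on the
helix.

## The method

For each site class, with one shared parameter set for every class:

1. **Unique-site selection.** A site survives at disjointness width *w*
   (100–500 bp) if its *w*-bp window centred on the peak maximum overlaps no
   other site's window, any class included; larger *w* is more stringent.
   A null class of 1,500 random intervals avoiding all peaks is drawn.
2. **Shape windows.** Each surviving site gets a 4 × 201 feature matrix
   centred on its peak maximum, from precomputed tracks or from sequence via
   a pentamer lookup table.
3. **Shift search.** For two sites *a*, *b* and an integer shift
   *s* ∈ [−25, +25], each site's 90-bp alignment interval is extracted
   (*b*'s displaced by *s*), the 5 positions around each site's own peak are
   excluded (free MNase cleaves A/T-rich DNA preferentially, biasing shape
   right at the peak), each feature is z-standardized, and the four features
   are concatenated. The best shift maximizes the cosine similarity
   cos(**u**<sub>a</sub>, **u**<sub>b</sub>(s)); ties go to the smallest
   |s|, negative first.
4. **Centroid anchoring.** The class centroid is the member minimizing
   Σ<sub>j</sub> (1 − cos<sub>ij</sub>)², the sum of squared cosine
   distances to all other members. Every site is shifted to the centroid
   and the per-position class average ± s.e.m. is computed; the shift
   distribution is recentred to zero mean so that all classes share the
   peak-maximum frame.
5. **Class comparison.** Pearson's *r* (two-tailed *p*) between
   z-standardized class averages, without any relative shifting.
6. **Shape profile.** Positions whose aligned-site value distributions have
   the largest information gain (Kullback–Leibler divergence, in bits,
   against mononucleotide-shuffled backgrounds) define the profile regions;
   sites are scored by correlation distance (1 − Pearson *r*) to the
   profile, and score distributions are compared by two-sided Mann–Whitney
   *U*.
7. **Regulatory associations.** Sites map to their closest gene within
   1 kb; the proportions with a documented-or-proposed TF–gene association
   are compared between classes by Fisher's exact test.

A fully synthetic data generator plants a tract-like shape signature at
known per-site offsets with controlled noise, so every stage has exact
ground truth. See `docs/methods.md` for the model, parameter defaults and
design choices.

## Worked example

```python
import numpy as np
from shapealign import (
    AlignmentConfig, SimulationSpec, align_class, compare_class_averages,
    compare_score_distributions, define_profile, extract_shape_window,
    information_gain, score_class, shuffled_background, simulate_dataset,
)

spec = SimulationSpec(seed=1)          # 200 sites/class on a 1 Mb genome
data = simulate_dataset(spec)
config = AlignmentConfig()             # 25 bp max shift, 90 bp interval, 5 bp exclusion

results = {}
for label, sites in data.sites_by_class().items():
    windows = [extract_shape_window(s, data.track, spec.shape_window) for s in sites]
    results[label] = align_class(windows, config)
```

Comparing the aligned class averages and scoring every class against the
fast-site profile prints:

```text
fast-class shift recovery: 100.0% (centroid fast_00191)
fast vs slow        Pearson r = +0.979   p = 7.71e-236
fast vs free_mnase  Pearson r = +0.072   p = 0.185
fast vs random      Pearson r = -0.052   p = 0.343
profile regions: [('MGW', 54, 68), ('ProT', 51, 64), ('HelT', 51, 58), ('Roll', 51, 67)]
median correlation distance, fast       0.103
median correlation distance, slow       0.309
median correlation distance, free_mnase 1.000
median correlation distance, random     1.020
fast vs random scores: Mann-Whitney U = 0, p = 4.83e-67
```

Read this as: the shape-only alignment recovered every planted per-site
offset; the fast and slow classes — which share the planted signature —
have nearly identical average shape features (r ≈ 0.98), while the controls
do not; and the information-gain profile picks out the planted deformation
(interval positions ~51–68, i.e. the 21-bp plant centred 15 bp right of the
peak), against which fast sites score near 0 (shape match) and random sites
near 1 (uncorrelated).

The same analysis runs from the shell:

```sh
shapealign simulate --seed 1 --out run/data --write-track
shapealign pipeline --data run/data --out run/results --widths 100,300,500
```

which writes per-width shift tables, class averages, profiles, scores and a
machine-readable `summary.json`.

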
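# Methods

## Problem and model

ChIP-seq peak summits approximate the single base pair of a protein's
DNA contact, but individual summit calls scatter by tens of base pairs.
The package's premise is that this scatter is largely unbiased: if many
sites carry the same protein complex anchored by an oriented motif, the
*median* summit position relative to the motif middle — measured in
motif orientation — converges on the protein's true contact offset.
For CTCF/cohesin the measurable is a per-protein signed offset
distribution around the CTCF recognition site (CTS), and the question
is whether the per-protein medians are distinct, serially ordered, and
geometrically consistent with a specific complex topology.

### Coordinate and sign conventions

All internal coordinates are 0-based half-open (BED). The reference
point of a CTS of span `[s, e)` is its mathematical middle
`(s + e − 1)/2`, which is strand-independent and half-integer for
even-length motifs; it is never rounded, so that flipping a CTS strand
negates every offset exactly. The oriented offset of a summit at `p` is
`p − center`, negated on "−"-strand motifs. Under this convention a
negative offset is 5′ of the motif in motif orientation. Multi-bp peak
intervals presented as summits collapse to the floored inclusive
midpoint — deterministic and strand-independent. 1-based input dialects
are never auto-detected; at single-bp resolution a silent off-by-one is
the dominant failure mode, so conversion must be explicit.

## Pipeline stages and parameters

| stage | parameter | default | meaning |
|---|---|---|---|
| consensus | `max_span` | 50 bp | max gap to previous member AND max total chain span |
| consensus | `min_samples` | 2 | distinct samples required per consensus summit |
| co-peak | `pair_window` | 50 bp | max CTCF–cohesin consensus distance ("closer than 51 bp") |
| motif scan | `pwm_threshold` | 6 (natural-log odds) | minimum motif score |
| CTS choice | `cts_window` | 50 bp | candidate window around the CTCF consensus |
| shift table | `pairing_window` | 50 bp | max summit-to-CTS-center distance |
| smoothing | `smooth_window` | 5 bp | rolling-mean width for histograms/profiles |
| helix | `period`, `rise` | 10.5 bp/turn, 0.34 nm/bp | ideal B-DNA geometry |

Notes on deliberately resolved ambiguities:

* **"Closer than 51 bp"** is implemented as distance ≤ 50 with a strict
  inequality at 51; both windows are parameters, not constants.
* **Chain clustering** caps the *total* span of a chain at `max_span`
  in addition to the consecutive gap, preventing chained drift in which
  summits 200 bp apart end up in one cluster through intermediates. The
  consensus position is the floor of the unweighted mean of member
  positions (heights are not used as weights).
* **Nearest-neighbor co-peak pairing is not bijective**: one cohesin
  consensus may anchor several CTCF summits; ties at equal distance
  resolve to the smaller genomic coordinate.
* **CTS assignment rules**, in order: no candidate → none; one
  candidate → it; mutually overlapping candidates (≥1 bp genomic
  overlap, strand-blind) collapse to the best score; among disjoint
  candidates those whose orientation places the cohesin consensus
  downstream of the motif win, then best score; if none does, best
  score among all. Score ties break by higher score, then "+" strand,
  then lower start. "Downstream" for a "−"-strand motif means lower
  genomic coordinates.
* **Motif scores** are natural-log odds against a uniform background.
  The threshold's numerical meaning depends on the log base and
  background, so both are configurable; an equivalent log2 reading of
  the same cutoff is obtained by passing a rescaled threshold.
* **Per-site summit pairing** takes the nearest summit of each
  (protein, sample) group within the pairing window — the
  minimal-assumption rule when one peak group must be matched to one
  reference point; distance ties resolve to the smaller position.
* **Summaries**: quartiles by linear interpolation, median of an even
  group as the midpoint of the central pair, sd with `ddof=1` (0 for
  singleton groups). Rolling means shrink their window at the edges
  rather than padding, so no data are invented outside the profile.
* **Subpeak splitting** (`split_subpeak_summits`) is this package's own
  valley-depth criterion for discriminating merged peaks: candidate
  local maxima (plateau centers) are admitted highest-first, and a
  candidate is rejected if the profile between it and an already
  accepted maximum never drops below `min_valley_frac` (default 0.5)
  times the lower of the two heights. It is a simple, fully specified
  stand-in for external subpeak callers and its thresholds are exposed.

## Statistics

Three tests address the conservation of the shift ordering:

* **Paired Wilcoxon signed-rank** on per-site offset differences
  between two proteins. Zero differences are dropped (Wilcoxon
  convention). For n ≤ 25 non-zero differences the two-sided p is exact,
  computed from the full null distribution of the positive-rank sum by
  dynamic programming over doubled midranks (doubling keeps tied
  midranks integral); this matters because tied |differences| are the
  norm for integer offsets, and tie-compatible exact enumeration is
  what the small-n tests verify against. For larger n the normal
  approximation with tie correction is used.
* **Friedman chi-square** across k ≥ 3 proteins on complete sites
  (within-site midranks, standard tie correction). The tie-corrected
  statistic is computed directly so that a fully tied dataset returns
  statistic 0 and p = 1 instead of a division by zero; on tie-free data
  it agrees with the standard implementation to floating precision.
  With unanimous rankings at n sites and k = 3 the statistic is 2n.
* **Permutation ("simulation") ordering test.** The statistic is the
  sum over adjacent protein pairs, in the hypothesized order, of the
  difference of their median offsets. The null permutes protein labels
  independently *within each site*, conditioning on the observed
  per-site offset multisets and testing protein exchangeability only.
  The p-value uses the +1 correction,
  `p = (1 + #{T_perm ≥ T_obs}) / (1 + n_permutations)`, so it is never
  0 and its floor is `1/(n_permutations + 1)`. The default hypothesized
  order is the observed order by median; passing an a-priori order
  makes the test exact at its nominal level, which is how the
  calibration check is run. An alternative null (shuffling whole sites)
  was considered and rejected because it would also test site
  heterogeneity, not just protein order.

All three tests are invariant to adding a constant to every offset, and
the permutation test is bit-reproducible for a fixed seed.

## Helix projection

Offsets are mapped to an ideal B-DNA cylinder: azimuth
`((d − d_ref) · 360/period) mod 360` with period 10.5 bp/turn, rise
0.34 nm/bp. The face boundary sits at ±90° from the reference azimuth,
giving the binary front/back reading of a circle diagram; the
quantitative angles are always reported alongside so the binarization
loses no information. Sequence-dependent curvature is out of scope: the
ideal-helix approximation is appropriate for sites that are not
inherently curved, and the period is configurable over the B-DNA range
(10.0–10.6). With medians {CTCF −4, SMC3 +1, RAD21 +6, STAG1 +7} and
CTCF as reference, SMC3 lands 171.4° around the cylinder — opposite
face — while RAD21 (342.9°) and STAG1 (308.6°) share CTCF's face.

## Loop anchors

Replicate ChIA-PET interactions (paired-anchor "junction BED") are
intersected by reciprocal overlap on both anchors (default fraction
1.0, i.e. identical anchors), deduplicated on anchor coordinates.
CTS assignment per interaction considers only CTSs fully inside each
anchor, ranks them by distance to the anchor midpoint, and selects the
convergent pair (5′ anchor "+", 3′ anchor "−") minimizing the summed
midpoint distances; when no convergent pair exists the closest CTSs
are still reported with `convergent = false`. The search does not
extend beyond anchor boundaries: an anchor without a CTS gets none.

## Synthetic data: what it emulates and what it does not

The generator plants exact-consensus motif instances (a sharp 19-bp
CTCF-like PWM, consensus probability 0.97) at non-overlapping loci with
independent random strands on a random-uniform genome, then emits, per
protein × sample × site, a summit at
`round(center + strand_sign · (true_offset + N(0, sd)))` and a pileup
of fragments jittered around that summit. Defaults encode the study
conditions: true offsets CTCF −4, SMC3 +1, RAD21 +6, STAG1 +7 bp; noise
sd 10 bp; two samples per protein; equal strand fractions. The 10 bp
noise scale is chosen so that a few hundred sites recover a median to
within one base pair (the standard error of a median is
≈ 1.253·sd/√n ≈ 0.56 bp at n = 500), consistent with how many good
co-peaks the approach needs in practice; it is configurable.

Not emulated: sequence-composition bias, variable occupancy and peak
width, composite/overlapping peaks, mappability artifacts, correlated
noise between subunits of one complex, and read-level effects. Passing
recovery tests therefore demonstrate estimator correctness and
convergence behavior under the stated noise model, not performance on
any real dataset.

## Problem sizes and determinism

The shipped checks use 300 sites (noise-free exactness, per strand),
20 × 500 sites (1 bp recovery under 10 bp noise), 1000 sites with 10⁵
permutations (ordering significance), 200 × 50 sites with 199
permutations (null calibration at α = 0.05), and 250 sites for the
strand-antisymmetry suite — sizes at which the Monte-Carlo margins are
comfortable while a full run stays in the tens of seconds. All
randomness flows through explicit seeds; deterministic stages are
bit-reproducible across reruns (verified by output checksums).

## Known limitations

* Consensus clustering is greedy left-to-right; for pathological summit
  spacings near the span cap, chain boundaries are order-of-scan
  dependent (the mirrored genome can split a chain differently). The
  oriented offsets themselves are unaffected.
* One cohesin consensus class pools all cohesin subunits; proteins with
  strongly divergent offsets (> span cap apart) would fragment the
  cohesin cluster.
* `intersect_replicates` is quadratic in the replicate sizes; adequate
  for consensus interaction sets of up to ~10⁴ loops, not for raw PET
  collections.
* The exact-score PWM scan loads one chromosome string at a time;
  genome-scale scans are feasible but not optimized (no suffix
  indexing).
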
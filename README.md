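# summitshift

Strand-specific, base-pair-resolution analysis of ChIP-seq peak-summit
shifts between a sequence-specific anchor factor (CTCF) and the proteins
of its co-complex (the cohesin subunits RAD21, SMC1/3, STAG1/2), with
projection of the measured shifts onto B-DNA helical geometry and
annotation of convergently oriented loop anchors in ChIA-PET data.

## Who this is for

Epigenomics groups that already have peak/summit calls (MACS2-style BED)
and fragment intervals for CTCF and one or more cohesin subunits across
several samples, and who want to ask a structural question the standard
peak-overlap toolchain cannot answer: *where, to the base pair and in
motif orientation, does each protein of a complex contact the DNA
relative to the anchor motif — and on which face of the double helix?*

## The method

1. **Consensus summits.** Raw single-bp summits observed in at least two
   samples within 50 bp are averaged into consensus summits, separately
   for CTCF and for the cohesin class.
2. **Co-peaks.** Each consensus CTCF summit within 50 bp of a consensus
   cohesin summit becomes a co-peak — a locus where the complex is
   jointly bound.
3. **Oriented reference points (CTSs).** The genome is scanned with a
   CTCF position weight matrix (natural-log odds against a uniform
   background, threshold 6). Each co-peak receives at most one CTCF
   recognition site (CTS) by explicit selection rules (single hit;
   best score among overlapping hits; among disjoint hits, those whose
   orientation puts cohesin downstream of the motif, then best score).
4. **Oriented offsets.** For every protein, sample and assigned CTS, the
   nearest summit within 50 bp yields the signed offset

   `d = summit − center(CTS)`, negated on "−"-strand motifs,

   where `center = (start + end − 1)/2` is the mathematical middle of
   the motif. This makes offsets comparable across sites on both strands.
5. **Statistics.** Per-protein offset medians; paired Wilcoxon
   signed-rank and Friedman tests plus a within-site label-permutation
   test of the serial protein ordering.
6. **Helix projection.** Each median offset `d` maps to an azimuth
   `(d · 360/10.5) mod 360` degrees and a rise `d · 0.34` nm on an ideal
   B-DNA cylinder; angles within 90° of the reference azimuth are
   classified as one helical face, the rest as the other.
7. **Loop anchors (optional).** ChIA-PET replicate interactions are
   intersected by reciprocal anchor overlap, and each anchor is assigned
   the CTS closest to its midpoint, preferring the convergent
   configuration (5′ anchor "+", 3′ anchor "−").

## Worked example

Everything runs on a synthetic fixture generated by the package itself
(no downloads):

```
summitshift generate --n-sites 40 --noise-sd 0 --seed 2 --out fixture/
summitshift shift --summits fixture/manifest.tsv --genome fixture/genome.fa \
    --pwm fixture/ctcf.pwm --out run/
```

prints the per-protein offset summary (noise-free, so the medians equal
the planted truth exactly):

```
protein  n  mean  median   q1   q3   sd
   CTCF 80  -4.0    -4.0 -4.0 -4.0  0.0
  RAD21 80   6.0     6.0  6.0  6.0  0.0
   SMC3 80   1.0     1.0  1.0  1.0  0.0
  STAG1 80   7.0     7.0  7.0  7.0  0.0
```

A median of −4.0 for CTCF means its summit sits 4 bp 5′ of the motif
middle in motif orientation; RAD21 (+6), SMC3 (+1) and STAG1 (+7) sit
downstream. Projecting those medians onto the helix:

```
summitshift helix --shifts run/shift_summary.tsv --out helix.tsv --reference CTCF
back: SMC3
front: CTCF, RAD21, STAG1
```

CTCF, RAD21 and STAG1 fall on one helical face and SMC3 on the
opposite face (SMC3 is 171.4° around the cylinder from CTCF) — the
geometric signature that the SMC head domains contact DNA from the
other side of the duplex than the CTCF/RAD21/STAG subcomplex.

Ordering significance on a noisy dataset (`--noise-sd 10`):

```
summitshift stats --records run/shift_records.tsv --out stats.tsv \
    --permutations 100000 --seed 1
```

reports the permutation p-value of the serial order CTCF → SMC3 →
RAD21 (at 1000 sites it reaches the resolution floor 1/100001), the
Friedman p, and all pairwise Wilcoxon p-values.

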
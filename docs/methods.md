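# Methods

## The mechanism being modeled

A replication fork stalled at an interrupted inverted repeat (IIR) can
switch templates: the 3' end of the nascent leading strand, carrying one
arm of the repeat, anneals to the reverse-complementary arm exposed in the
single-stranded gap on the lagging-strand template. Ligation to the
adjacent Okazaki fragment covalently joins the nascent leading and lagging
strands. At a centromere-proximal fork this expels a hairpin-capped linear
spanning the locus to the telomere; after replication it persists as an
inverted linear duplex carrying a single centromere-proximal junction
(CJ). A second, independent switch at a telomere-moving fork adds a
telomere-proximal junction (TJ); recombination back into the chromosome
yields an interstitial triplication with an inverted middle copy. The
package implements this as explicit string constructions (`simulate`), a
detector for the junctions the mechanism leaves in short reads (`caller`),
and the two physical constraints that shape which IIRs are usable
(`fork`), plus the aCGH signature of the palindromic junctions (`acgh`).

## Coordinates and conventions

All coordinates are 0-based, half-open. An IIR is (l1, l2, r1, r2) with
arms S[l1:l2] and S[r1:r2] = revcomp(S[l1:l2]), arm length a = l2−l1,
spacer s = r1−l2 ≥ 0. The canonical junction position is the midpoint of
the spacer interval, `(l2 + r1) // 2`. Loop side LEFT means the hairpin
loop (the unpaired spacer at the fold) faces lower coordinates; with the
centromere at lower coordinates, a productive CJ has loop LEFT and a
productive TJ loop RIGHT.

## Synthetic data

`build_genome` draws an i.i.d. uniform ACGT background and plants each
requested IIR as a random (or supplied) arm plus its reverse complement.
Two boundary bases are resampled so the planted arm is *maximal* at
exactly the requested length — without this, one time in four the spacer
edge would chance-extend the arm and the planted (a, s) would really be
(a+1, s−2). Background IIRs arise spontaneously (they are extremely
common in random sequence, as in real genomes) and are deliberately left
in place: recovery tests assert that planted junctions are found, not
that nothing else exists. Optional telomeric ends are tandem C{1,3}A /
G{1,3}T repeats of ≥ 100 bp.

Molecule constructions (S = contig, E = its length):

* inverted linear: `revcomp(S[r2:E]) + S[l1:E]` — telomeric flank twice,
  arms and spacer once at the fold. The fold retains both arms and the
  spacer exactly once, matching the observed read anatomy; a convention
  with the spacer on one strand only was rejected for that reason.
* triplication: `S[0:t_r2] + revcomp(S[c_r2:t_l1]) + S[c_l1:E]` —
  amplified segment three times, middle inverted, IIR blocks twice,
  flanks once.
* inverted dimeric circle: `Jc + mid + Jt + revcomp(mid)`, circular; read
  sampling uses sequence doubling for wraparound.

The doubly inverted linear's exact end structure (telomere status) is not
specified by the mechanism's description, so it is not modeled; inverted
linear, circle, and integrated triplication cover the observable junction
repertoire.

Read simulation is single-end by default: junction evidence lives inside
a single 150 bp read, so a mate adds nothing to detection and the
single-end model keeps fragment signatures simple. Defaults are the study
conditions: 150 bp reads, ~125× coverage, 10⁻³ per-base substitution
rate, no indels, flat quality. Per-molecule coverage is
depth × subclone frequency. `simulate_population` additionally injects
`artifact_rate × N` chimeric foldback reads, each from a distinct random
blunt junction, so every artifact junction is supported by exactly one
fragment — the situation the two-fragment filter must reject.

What the generator does **not** emulate: sequencing indels, quality decay,
GC/replication-timing coverage bias, real repeat families (Ty elements,
tRNAs), or mismatch-containing arms. Passing tests therefore show the
pipeline's correctness on the mechanism's sequence logic, not robustness
to every artifact of real libraries.

## Split-read calling

Reads are mapped by exact anchor-and-extend against a k-mer index
(k = 20) of both reference strands: the maximal exact prefix match and
maximal exact suffix match are found, and a read is a split read when the
two cannot be explained by one contiguous match but jointly cover the
read. No scoring matrix or gapped alignment: the junctions of interest
are exact sequence features, and the references are small. The overlap of
the two matches in read coordinates — the breakpoint homology — *is* the
IIR arm; the gap between the two arm copies' inner boundaries on the
reference is the spacer. Chance homology beyond the arm is trimmed
symmetrically with the odd base biased toward the lower coordinate, so
reads entering the junction at different offsets collapse to one
canonical (contig, position, arm, spacer, loop side) tuple.

Classification into the five junction categories uses precedence:
telomere-motif/interval checks before the repeat-annotation fallback;
INVERTED/DIRECT require both segments uniquely mapped to one contig.
Support is counted in unique fragments — reads sharing (contig, outer 5'
coordinate, strand) are PCR copies of one fragment — and junctions with
fewer than 2 unique fragments are dropped. Junctions with spacer > 1 kb
are flagged as probable secondary deletions and excluded from spacing
statistics.

`binned_depth` anchors each read by its first uniquely mapping k-mer
(trying a few offsets to step over errors), accumulates coverage, and
normalizes per-bin means by the genome-wide median.

## aCGH waterfall model

Labeling fragments of fixed length L with the junction at uniform phase:
a point at distance d from the palindromic junction is unlabeled exactly
when its fragment contains the fold and d ≤ min(a, b) (a, b the fold's
distances to the fragment ends), which happens with probability
max(0, 1 − 2d/L). With c_far copies distal of which k meet at the
palindrome,

    c(d) = c_far − k · max(0, 1 − 2d/L),

so c(0) = c_far − k and the ramp completes at d = L/2 — 10 kb for the
20 kb fragments of the shear-after-labeling protocol, and ≤ 250 bp when
DNA is sheared to 500 bp *before* labeling (the diagnostic contrast).
The fixed-length uniform-phase fragment model is what gives the linear
ramp; k defaults to 2 (a 1→3 triplication junction) and is exposed
because neochromosome geometries differ. Signals are on the linear
copy-number scale with a log2 convenience transform.

`detect_waterfall` least-squares fits the four-parameter family
(junction position, ramp half-width L/2, c_near, c_far) with
`scipy.optimize.least_squares`, initialized from the profile's dynamic
range and midpoint crossing. A fitted rise below 0.3 copies (or a flat
profile) returns a "no junction" result rather than raising.

## Fork constraints

`classify_switch` partitions (spacer s, gap g): s below a hairpin
threshold t_h self-hybridizes; s > g finds its partner already duplexed;
otherwise productive (both boundaries inclusive on the productive side).
t_h defaults to 40 bp — the observed lower edge of productive spacings —
because no mechanistic formula for hairpin propensity is available; it is
exposed as a parameter. With the gap uniform on [0, okazaki_len = 165],
integrating the classifier gives
`density(s) = 1[s ≥ t_h] · max(0, 1 − s/165)`: support [40, 165], mode at
40, non-increasing.

`fork_direction` uses a deterministic nearest-active-origin rule (equal
speeds, simultaneous firing; firing-efficiency differences are out of
scope). Conventions: a position at an origin is covered by its rightward
fork; exact inter-origin midpoints break LEFTWARD. CJs are compatible
only with leftward forks, TJs with rightward ones.

## Statistics

`mann_whitney` uses midranks; for n_a + n_b ≤ 12 the two-sided p is exact
by enumerating all C(n, n_a) group assignments, otherwise a
tie-corrected, continuity-corrected normal approximation. `chi_squared`
is the Pearson statistic on 2 × k tables with df = k − 1. Usage tables
stratify by arm length or 20 bp spacer bins (the bin width is exposed);
strata with zero potential are reported missing, and secondary-deletion
junctions are excluded. No multiple-testing correction is applied — each
comparison is a single planned test.

## Problem sizes and numerical choices

The round-trip suite uses ten populations on 80 kb contigs at 125×
coverage with three subclones (wild type 0.5, inverted-linear 0.3,
triplication 0.2) and 1% singleton artifacts, chosen as a realistic
population-scale exercise that the suite completes in about a minute.
Monte-Carlo labeling uses 10⁵ fragments, giving standard errors of ~0.005
copies, and agreement with the closed form is asserted at 3 SE. Scanner
correctness is property-checked against a naive quadratic oracle on
random sequences up to 3 kb.

## Known limitations

* Exact-match calling cannot place junctions whose flanks fall in long
  genomic repeats (both-segment uniqueness is required for
  INVERTED/DIRECT), and arms with internal mismatches are not detected —
  by design, since junction arms are exact inverted repeats.
* The scanner reports only maximal arms; an enrichment analysis that
  wanted sub-arms would need a different convention.
* The fork model is descriptive: it states which spacings and positions
  are mechanistically available, and is not fitted to junction counts.
* PCR-artifact injection models singleton chimeras only; systematic
  library chimeras that repeat would defeat a support threshold, as they
  would in real data.
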
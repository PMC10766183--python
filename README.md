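# odira

Foldback-junction discovery and replication template-switch modeling for
inverted copy-number amplicons.

## The problem

Interstitial inverted triplications — a segment present in three copies
with the middle copy inverted (DUP-TRP/INV-DUP in human genetics) — arise
in budding yeast under selection (e.g. *SUL1* amplification in
sulfate-limited chemostats) and in human disease loci. The ODIRA model
(origin-dependent inverted repeat amplification) explains them by a
template switch at a replication fork: the nascent leading strand anneals
to the lagging-strand template at a short **interrupted inverted repeat**
(IIR) — two reverse-complementary arms of a few bp separated by a spacer of
tens of bp — expelling a hairpin-capped linear molecule that, after a
second switch and recombination, becomes the triplication.

This package provides the computational side of testing that model on
short-read population sequencing:

* **`odira.simulate`** — synthetic chromosome-end contigs with planted
  IIRs; construction of the mechanism's products (inverted linears,
  inverted dimeric circles, triplications); 150 bp read simulation for
  subclonal populations with PCR-artifact foldbacks.
* **`odira.irscan`** — enumeration of all maximal-arm IIRs
  (arm 2–14 bp, spacer ≤ 250 bp by default): the "potential" baseline.
* **`odira.caller`** — split-read detection (exact anchor-and-extend),
  five-way junction classification, foldback characterization (arm =
  breakpoint homology, spacer, loop side), the two-independent-fragment
  artifact filter, CJ/TJ orientation relative to a focal locus, and
  binned copy-number depth.
* **`odira.acgh`** — forward model of the aCGH "waterfall": fragments
  spanning a palindromic junction snap back during labeling, producing a
  linear copy-number ramp `c(d) = c_far − k·max(0, 1 − 2d/L)` that
  completes at half a fragment length from the junction; plus a
  least-squares waterfall fitter.
* **`odira.fork`** — the mechanistic constraints: spacer productivity
  under the lagging-strand (Okazaki) gap, and fork-direction
  compatibility of CJ/TJ junctions given an origin map.
* **`odira.stats`** — used-vs-potential IIR enrichment, Mann-Whitney
  rank-sum (exact for small n), Pearson chi-squared, and per-population
  CJ/TJ balance accounting.

## Worked example

Plant the classic junction — a 4 bp inverted repeat (TGGC/GCCA) whose
copies are separated by a 61 nt interruption — build the hairpin-derived
inverted linear, simulate error-free reads across the fold, and call the
junction:

```python
from odira import simulate, caller

genome = simulate.build_genome(seed=101, length=20_000,
                               iir_specs=[(4, 61, 8_000, "TGGC")])
(iir,) = genome.truth["chrR"]
il = simulate.make_inverted_linear(genome, iir)
reads = simulate.simulate_reads(simulate.MoleculeSet([(il, 1.0)]),
                                depth=60, read_len=150, error_rate=0.0,
                                seed=102)
(j,) = caller.call_junctions(reads, genome.contigs, min_support=2)
print(j.arm_len, j.spacer_len, j.loop_side.value)
```

prints

```
4 61 LEFT
```

i.e. the caller recovers the planted anatomy exactly: a 4 bp arm
(the breakpoint homology shared by the two read segments), the 61 nt
spacer between the two arm copies on the reference, and a hairpin loop on
the left — the productive orientation for a centromere-proximal junction.

The same stages are scriptable from the shell:

```sh
odira simulate --seed 7 --length 80000 --iir 4,61,40000 --out-prefix pop
odira scan --fasta pop.fasta --out iirs.tsv
odira call --fasta pop.fasta --fastq pop.fastq --locus 55000 --out junctions.tsv
```

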
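# bestop

Design toolkit for **STOP-codon knockouts with cytosine base editors (CBEs)**
in bacterial genomes, with genome-wide targeting-space modelling, bulge-aware
off-target search and multiplex sgRNA array assembly.

It is written for microbial engineers using Target-AID-style editors
(nCas9–deaminase fusions) in organisms where double-strand-break repair is
unreliable — e.g. acetogenic clostridia — and for anyone who needs to answer,
before touching a culture: *which genes can I knock out with this editor,
which guides are safe, and what will the off-target landscape look like?*

## The model

A CBE converts C→T on the protospacer strand inside a PAM-relative editing
window (default −19..−16, the PAM-proximal protospacer base being −1). A
protospacer qualifies as a knockout guide when some non-empty subset of its
window cytosines, once edited, creates an in-frame premature stop:

* **sense** guides (same strand as the CDS) exploit CAA→TAA, CAG→TAG,
  CGA→TGA;
* **antisense** guides edit the template strand — G→A on the coding strand —
  so TGG (Trp) is the productive codon: its CCA image on the protospacer
  strand yields TTA, TCA or CTA, i.e. TAA, TGA or TAG in frame.

Genome-wide, the **targeting space** of a PAM is the number of qualifying
protospacers whose stop codon falls in the first 75 % of its CDS, and the
**genomic coverage** is the percentage of CDSs with at least one such guide —
the two numbers that decide whether an editor with a relaxed PAM (NG, NAA)
is worth the trouble over canonical NGG.

The off-target module searches both strands for spacer matches with up to a
chosen number of mismatches plus one DNA bulge (extra target bases) or RNA
bulge (skipped spacer bases), PAM-adjacent, and associates candidate sites
with observed variants (VCF) within a configurable distance (default 50 nt,
inclusive). A Smith–Waterman fallback against the 41-nt context around each
variant catches associations the seed-limited search misses.

The array module assembles msgRNA (one transcriptional unit per guide),
mCRISPR (native-style repeat-spacer array + tracrRNA) and mtRNA (tRNA–sgRNA
fusion) cassettes, and screens candidate pre-tRNAs with sequence-level
criteria (no poly-U trailer, weak A/U-rich stem-loop near the CCA end,
high-usage decoded codon).

Everything is testable without downloads: the `simulate` module generates
circular annotated genomes and *plants* protospacers, off-target sites and
SNPs with exactly known properties, recorded in a ledger.

## Worked example

```bash
$ bestop simulate --genes 10 --seed 4 --plant-protospacers 3 --plant-offtargets 2 --out simdir
genome of 10076 nt, 10 CDSs, 3 planted protospacers, 2 planted off-targets -> simdir/

$ bestop design --genome simdir/genome.gb --pam NGG --out hits.tsv --bed hits.bed
12 hits covering 5 CDSs -> hits.tsv

$ bestop coverage --genome simdir/genome.gb --pams NGG,NG,NAA --union NG+NAA --out cov.tsv
                       pam pattern  targeting_space  covered_cds  total_cds  coverage_pct
                Target-AID     NGG               12            5         10          50.0
             Target-AID-NG      NG               60            9         10          90.0
              Cas9-iSpymac     NAA               39           10         10         100.0
Target-AID-NG+Cas9-iSpymac   union               99           10         10         100.0
```

`targeting_space` counts qualifying (protospacer, CDS) pairs; `coverage_pct`
is the share of CDSs with ≥ 1 guide. Here the NGG editor can reach only half
the genes of this toy genome while the NG editor reaches 9 of 10 — the
pattern-subsumption inequality (every NGG site is an NG site) guarantees NG
rows always dominate NGG rows.

The same steps from Python:

```python
from bestop import read_genome, design_knockouts, PAM_PRESETS

genome = read_genome("simdir/genome.gb")
hits = design_knockouts(genome, PAM_PRESETS["NG"])
clean = [h for h in hits if h.quality == "clean"]   # one C, at -18/-19
```

Guides are labelled `clean` (a single window C at −18/−19 — the positions
the deaminase edits reliably), `multi_C` (co-edit risk, mixed colonies) or
`window_edge` (single C at −17/−16, rarely edited): prefer `clean` ones.

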
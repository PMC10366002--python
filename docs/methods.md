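# Methods

This note records the model, the conventions the implementation fixes where
the underlying procedure is under-specified, the synthetic-data assumptions,
and the numerical choices. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Editing model

A cytosine base editor deaminates C→U on the single strand displaced by the
Cas9–sgRNA R-loop — the *protospacer strand* — within a window of positions
counted from the PAM (position −1 is the PAM-proximal protospacer base).
Resolution through mismatch repair fixes the edit as C→T on that strand,
equivalently G→A on the opposite strand. The design scan treats every
non-empty subset of window cytosines as a possible outcome, because
sequencing of edited loci shows both single and multiple co-edits within one
window; a `single_only` mode restricts qualification to single-C edits for
sensitivity analysis.

A premature stop can arise two ways, and the code handles them symmetrically:

* sense guides (protospacer strand = coding strand): C→T at codon position 0
  of CAA/CAG/CGA gives TAA/TAG/TGA;
* antisense guides: G→A on the coding strand, so only TGG can become a stop
  (TAG, TGA, or TAA when both Gs are edited). On the protospacer strand this
  reads as the CCA→{CTA, TCA, TTA} conversions.

A stop edit is only counted when its codon lies wholly inside the CDS;
window cytosines outside the CDS may join an edit subset but cannot
themselves produce a stop. A hit is a (protospacer site, CDS) pair — a site
overlapping two annotated genes yields two hits, and the site-level
deduplicated count is available as an alternative counting mode.

### Window and qualification conventions

The window defaults to −19..−16. Source material for this family of editors
quotes both −20..−16 and −19..−16; the genome-wide counts this package is
designed to reproduce were computed with the −19..−16 rule, so that is the
default and the window is a first-class parameter (`EditingWindow`).

"First 75 % of the CDS" is anchored, by default, on the first base of the
would-be stop codon: it must lie within `floor(0.75 × CDS length)` (1-based).
An alternative anchoring on the protospacer's 5'-most in-CDS base is
selectable. Because neither the anchoring, the window bounds, nor the
site-vs-pair counting is fully pinned down by the published description, a
**convention grid runner** (`coverage.find_matching_convention`) evaluates
all 16 combinations (2 windows × 2 anchors × 2 countings × any/single-C) and
reports which reproduce a given set of target numbers; the package default is
the combination stated above.

Guide quality follows the empirical editing profile: `clean` = exactly one
window C at −18 or −19 (edited reliably); `window_edge` = a single C at −17
or −16 (rarely edited); `multi_C` = two or more window Cs (risk of unwanted
co-edits and mixed colonies).

PAM patterns are IUPAC strings; `NG` is treated as a literal 2-nt PAM
immediately 3' of the protospacer (an `NGN` 3-nt preset exists). Ambiguous
(N) genome bases never match any PAM position and never count as editable
cytosines. The genetic code is the bacterial table (stops TAA/TAG/TGA);
CDS features with compound (join) locations, a `pseudo` qualifier or a
length not divisible by three are flagged pseudo and excluded from design
scans, since codon arithmetic is undefined for them.

## Off-target search

The search reimplements bulge-aware spacer matching with the same semantics
as Cas-Offinder: the spacer is expanded into gapped query variants — the
ungapped spacer, RNA-bulge variants (one contiguous interior run of 1..b
spacer bases skipped) and DNA-bulge variants (one contiguous interior run of
1..b wildcard positions inserted) — and each variant is slid along both
strands counting mismatches, with the PAM checked immediately 3' of the
aligned target. Terminal bulges are excluded (they are equivalent to shorter
or shifted ungapped matches), DNA and RNA bulges are never combined in one
alignment, and identical patterns arising from different gap placements are
deduplicated.

Two counting modes exist because they answer different questions. `primary`
keeps one best alignment per (position, strand) — fewest mismatches, then
smallest bulge, then bulge type none < RNA < DNA — and is the default for
reporting. `raw` keeps every (position, strand, variant) combination, which
is the convention of the original tool's site totals and is provided for
count parity with them.

The genome is held as a uint8 code array; one variant/strand pass is ~20
whole-genome numpy comparisons, so a six-spacer search at (9 mismatches,
2-nt DNA, 2-nt RNA) over a 4–5 Mb chromosome completes in about a minute on
one CPU (measured ~1.4 s per spacer-Mb in raw mode).

Variant association: a VCF-derived SNP is associated with every candidate
site whose occupied interval is within 50 nt (inclusive; distance 0 inside
the site). The local-alignment fallback aligns the spacer, both
orientations, against the 41-nt wild-type context around a variant
(Smith–Waterman via Biopython's `PairwiseAligner`; match +1, mismatch −1,
gap −2 — the interactive tool originally used for this step publishes no
scheme, so a simple symmetric one is fixed and configurable) and reports
only alignments with ≥ 11 matching bases.

Deletion-region analysis is the containment query `genes_in_region(start,
size)` (annotated features wholly inside the interval) plus a region-
restricted site search; read-coverage computation itself is out of scope.

## Multiplex arrays and pre-tRNA screening

`build_array` assembles three architectures from a parts registry:
msgRNA = (promoter, spacer, scaffold, terminator) per guide; mtRNA = one
promoter + sgRNA units joined by tRNAs (spacers − 1 junction tRNAs, optional
terminal tRNA) + one terminator; mCRISPR = one promoter + (DR, 30-nt
spacer)… + DR + terminator plus a separate tracrRNA unit. The legacy
mCRISPR spacer is a 6-nt restriction site + 4 seeded-random nt + the 20-nt
spacer; the recommended mode takes 30-nt fully target-homologous spacers.
The registry ships with placeholder promoter/terminator/tRNA sequences (the
published constructs' exact parts live on plasmids and are not printed), so
assembled lengths are structural: the package asserts the mtRNA < msgRNA
cassette-length *ordering*, which is architecture-determined (one
promoter/terminator total versus one pair per guide), not the absolute
published lengths.

The pre-tRNA screen is deliberately sequence-level: thermodynamic folding is
replaced by a base-pair-maximization hairpin scan (stem ≥ 4 bp, loop 3–8 nt,
Watson–Crick plus G·T/G·U wobble), with a `fold_hook` to plug in an external
folding engine. "A weak A/U-rich stem-loop approximately 16 nt from the CCA
end" is operationalized as: the hairpin's span overlaps the interval 10–22 nt
downstream of the mature CCA end, and its stem A/U fraction is ≥ 0.75; the
poly-U terminator check is ≥ 4 consecutive U/T in the 20-nt trailer. All
thresholds are parameters. Codon-usage rank comes from the genome's CUSP-style
usage table (counts, synonymous-family fractions, per-1000 frequencies).

## Synthetic data

The generator emulates the substrate the pipeline runs on — a circular
bacterial chromosome with non-overlapping, strand-mixed, in-frame CDSs — not
its biology. Defaults: 50 genes; gene length ~N(900, 300²) nt floored at
90 and rounded to a codon multiple; intergenic gaps ~N(150, 80²) floored at
30; GC 0.31 (the AT-rich composition typical of acetogenic clostridia);
half the genes on the minus strand. Intergenic sequence is i.i.d.; coding
sequence is ATG + random non-stop codons + stop. It does **not** model
operon structure, realistic codon bias, repeats or mobile elements, so
passing tests demonstrate correctness of the scanning logic, not performance
on repeat-rich real genomes.

Planting is constructive with verification and rejection sampling (budget
100, then a hard error — no silent degradation):

* `plant_stop_protospacer` rewrites whole codons inside a CDS: a C-free
  filler codon (default GAA sense / AAA antisense, configurable), the
  stop-source codon (CAA sense; TGG antisense), and the literal PAM; in-frame
  stops created by PAM overlap are repaired at unprotected positions. The
  rewritten genome is re-inspected directly (frame intact, start/stop intact,
  no internal stop, exactly the intended window cytosines, every expected
  edit subset produces its stop by literal substitution) before the ledger
  entry is emitted.
* `plant_offtarget_site` writes a mutated target + PAM at an intergenic
  position with ≥ spacer-length clearance (plus caller-supplied avoid
  intervals) and validates that the *best* alignment at that position, under
  the full bulge-aware search space it will be tested in, has exactly the
  requested mismatch/bulge profile — placements that a different gap
  placement explains more cheaply are re-sampled.
* `generate_variants` emits SNPs at controlled distances from site intervals
  (including the 50/51 boundary pair) plus background SNPs ≥ 500 nt from any
  site, as a minimal valid VCF.

The A/T-only CDS mode (`cds_alphabet="AT"`) makes background qualification
impossible (window cytosines require a coding-strand C or G), giving exact
planted coverage fractions for the coverage-model tests.

All randomness uses `numpy.random.RandomState(seed)`; identical spec + seed
gives byte-identical genomes, annotations and VCFs.

## Numerical and interface choices

* Coordinates: external formats keep native conventions (GenBank/GFF3/VCF
  1-based inclusive, BED 0-based half-open); internal arithmetic is 0-based
  half-open; all user-facing positions print 1-based.
* Circular genomes are scanned across the origin (protospacer, PAM and
  off-target windows may wrap). Origin-wrapping CDS annotations are
  supported in the container; real-genome wrapped CDSs arrive as compound
  locations and are therefore pseudo-flagged.
* Deterministic ordering everywhere: sites by forward protospacer start with
  '+' before '−'; stop edits by codon index, subset size, then offsets; hits
  by genome start; off-target sites by position.
* Coverage percentages are reported to 2 decimals.
* Problem sizes in the test suite: oracle-equality checks run on ≤ 20 kb
  synthetic genomes (exhaustive brute-force enumeration stays exact and
  fast there); scanner scaling was spot-checked at 1 Mb.

## Known limitations

* Editing *efficiency*, allele frequencies and colony purity are wet-lab
  outcomes; the package classifies guides by sequence features only and
  predicts substitution outcomes, not insertion-containing alleles.
* The hairpin heuristic is a screening proxy, not a folding engine; use the
  `fold_hook` for thermodynamic stringency.
* The local-alignment fallback's scoring scheme is a fixed convention; its
  match-count threshold (11) trades recall against noise and is exposed as a
  parameter.
* Cassette lengths depend on the placeholder parts registry; only
  architecture-determined relations are asserted.
* The off-target search targets exact Cas-Offinder-style semantics, not
  scoring models (CFD/MIT are out of scope).
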
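"""Bulge-aware off-target search and variant association.

The search follows Cas-Offinder semantics: a spacer is expanded into gapped
query variants — the ungapped spacer, RNA-bulge variants (a contiguous run of
1..max spacer bases skipped, i.e. an extra base on the RNA side) and DNA-bulge
variants (a contiguous run of 1..max wildcard bases inserted, i.e. extra
target bases) — and each variant is slid along both genome strands counting
mismatches, with the PAM checked immediately 3' of the aligned target. The
genome is held as a uint8 code array so one variant/strand pass is a handful
of whole-genome numpy comparisons.

Off-target *candidates* become putative off-target *mutation sites* when they
lie within a fixed distance (default 50 nt) of an observed variant; a
Smith-Waterman fallback against the 41-nt context around a variant catches
associations the seed-limited search misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import Align

from ._seq import encode, iupac_match_table, revcomp, validate_dna
from .genome import AnnotatedGenome, CdsRecord

__all__ = [
    "OffTargetQuery",
    "QueryVariant",
    "OffTargetSite",
    "VariantRecord",
    "VariantAssociation",
    "LocalAlignmentReport",
    "generate_query_variants",
    "search_offtargets",
    "associate_variants",
    "local_align_fallback",
    "read_variants",
    "variant_context",
    "genes_in_region",
]

_BULGE_ORDER = {"none": 0, "RNA": 1, "DNA": 2}


@dataclass(frozen=True)
class OffTargetQuery:
    label: str
    spacer: str
    pam_pattern: str = "NGG"
    max_mismatches: int = 9
    max_dna_bulge: int = 2
    max_rna_bulge: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", validate_dna(self.spacer, allow_n=False,
                                                        what=f"spacer {self.label}"))
        if len(self.spacer) < 10:
            raise ValueError("spacer length must be >= 10")
        if min(self.max_mismatches, self.max_dna_bulge, self.max_rna_bulge) < 0:
            raise ValueError("limits must be >= 0")


@dataclass(frozen=True)
class QueryVariant:
    """One gapped form of a spacer: the pattern actually slid along the genome."""

    pattern: str            # concrete bases plus N wildcards at DNA-bulge positions
    bulge_type: str         # none | RNA | DNA
    bulge_size: int
    bulge_pos: int          # spacer index where the bulge sits (0 for none)


def generate_query_variants(query: OffTargetQuery) -> list[QueryVariant]:
    """Deduplicated gapped query patterns in deterministic order.

    RNA bulge of size b: one contiguous run of b spacer bases skipped
    (interior runs only — a terminal bulge is just a shorter match).
    DNA bulge of size b: one contiguous run of b wildcard positions inserted
    between two spacer bases. DNA and RNA bulges are never combined.
    """
    s = query.spacer
    L = len(s)
    out = [QueryVariant(s, "none", 0, 0)]
    seen = {s}
    for b in range(1, query.max_rna_bulge + 1):
        if b >= L - 1:
            break
        for i in range(1, L - b):  # deleted run [i, i+b), both ends interior
            pattern = s[:i] + s[i + b:]
            if pattern not in seen:
                seen.add(pattern)
                out.append(QueryVariant(pattern, "RNA", b, i))
    for b in range(1, query.max_dna_bulge + 1):
        for i in range(1, L):  # insertion between s[i-1] and s[i]
            pattern = s[:i] + "N" * b + s[i:]
            if pattern not in seen:
                seen.add(pattern)
                out.append(QueryVariant(pattern, "DNA", b, i))
    return out


@dataclass(frozen=True)
class OffTargetSite:
    query_label: str
    genome_position: int     # 1-based leftmost base of the aligned target (forward)
    strand: str
    mismatches: int
    bulge_type: str
    bulge_size: int
    aligned_target: str      # strand-oriented target with '-' at RNA-bulge positions
    aligned_query: str       # spacer with '-' at DNA-bulge positions

    @property
    def target_span(self) -> int:
        """Number of genomic bases the site occupies."""
        return len(self.aligned_target) - self.aligned_target.count("-")

    def interval(self) -> tuple[int, int]:
        """1-based inclusive (start, end) of the occupied genomic interval."""
        return self.genome_position, self.genome_position + self.target_span - 1


def _aligned_pair(variant: QueryVariant, spacer: str, target: str) -> tuple[str, str]:
    """(aligned_query, aligned_target) with gap characters for the bulge."""
    if variant.bulge_type == "RNA":
        i, b = variant.bulge_pos, variant.bulge_size
        return spacer, target[:i] + "-" * b + target[i:]
    if variant.bulge_type == "DNA":
        i, b = variant.bulge_pos, variant.bulge_size
        return spacer[:i] + "-" * b + spacer[i:], target
    return spacer, target


def _mismatch_profile(codes_ext: np.ndarray, pattern: str, lo: int, hi: int) -> np.ndarray:
    """Mismatch count of ``pattern`` at every start position in [lo, hi)."""
    mism = np.zeros(hi - lo, dtype=np.int16)
    enc = encode(pattern)
    for i, (ch, code) in enumerate(zip(pattern, enc)):
        seg = codes_ext[lo + i: hi + i]
        if ch == "N":
            mism += (seg == 4)  # wildcard: only an ambiguous genome base mismatches
        else:
            mism += (seg != code)
    return mism


def search_offtargets(
    genome: AnnotatedGenome,
    query: OffTargetQuery,
    mode: Literal["primary", "raw"] = "primary",
) -> list[OffTargetSite]:
    """Genomic loci matching a spacer within mismatch/bulge limits, PAM-adjacent.

    ``primary`` keeps the single best alignment per (position, strand): fewest
    mismatches, then smallest bulge, then bulge type none < RNA < DNA.
    ``raw`` reports every (position, strand, query-variant) combination within
    the limits — the counting convention of Cas-Offinder, whose totals include
    each bulge variant separately.
    """
    n = len(genome)
    variants = generate_query_variants(query)
    pam_table = iupac_match_table(query.pam_pattern)
    k = pam_table.shape[0]
    strands = {
        "+": encode(genome.sequence),
        "-": encode(revcomp(genome.sequence)),
    }
    max_lt = max(len(v.pattern) for v in variants)
    results: list[OffTargetSite] = []
    for strand, codes in strands.items():
        if genome.circular:
            pad = max_lt + k - 1
            ext = np.concatenate([codes, codes[:pad]])
        else:
            ext = codes
        # PAM match mask over all possible PAM start positions
        pam_hi = n if genome.circular else n - k + 1
        pam_ok = np.ones(max(pam_hi, 0), dtype=bool)
        for i in range(k):
            pam_ok &= pam_table[i][ext[i: pam_hi + i]]
        for variant in variants:
            lt = len(variant.pattern)
            lo = 0
            hi = n if genome.circular else n - lt - k + 1
            if hi <= lo:
                continue
            mism = _mismatch_profile(ext, variant.pattern, lo, hi)
            ok = mism <= query.max_mismatches
            pam_pos = np.arange(lo, hi) + lt
            if genome.circular:
                pam_pos %= n
            ok &= pam_ok[pam_pos]
            for p in np.nonzero(ok)[0]:
                p = int(p) + lo
                target = _strand_slice(ext, p, lt)
                if strand == "+":
                    pos1 = p % n + 1
                else:
                    pos1 = (n - p - lt) % n + 1
                aq, at = _aligned_pair(variant, query.spacer, target)
                results.append(OffTargetSite(
                    query.label, pos1, strand, int(mism[p - lo]),
                    variant.bulge_type, variant.bulge_size, at, aq,
                ))
    if mode == "primary":
        best: dict[tuple[int, str], OffTargetSite] = {}
        for site in results:
            key = (site.genome_position, site.strand)
            rank = (site.mismatches, site.bulge_size, _BULGE_ORDER[site.bulge_type])
            cur = best.get(key)
            if cur is None or rank < (cur.mismatches, cur.bulge_size,
                                      _BULGE_ORDER[cur.bulge_type]):
                best[key] = site
        results = list(best.values())
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    results.sort(key=lambda s: (s.genome_position, s.strand, s.mismatches,
                                s.bulge_size, _BULGE_ORDER[s.bulge_type]))
    return results


def _strand_slice(codes_ext: np.ndarray, start: int, length: int) -> str:
    from ._seq import decode

    return decode(codes_ext[start:start + length])


# ---------------------------------------------------------------------------
# variants and association


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    annotation: str = ""


def read_variants(path: str, genome: AnnotatedGenome | None = None) -> list[VariantRecord]:
    """Read SNP records from a VCF; checks REF against the genome when given."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            ann = dict(rec.info).get("ANN", "")
            if isinstance(ann, tuple):
                ann = ann[0]
            variant = VariantRecord(rec.chrom, rec.pos, rec.ref, alt, str(ann or ""))
            if genome is not None:
                expected = genome.fetch(variant.pos - 1, variant.pos - 1 + len(variant.ref))
                if expected != variant.ref.upper():
                    raise ValueError(
                        f"VCF REF {variant.ref} at {variant.pos} does not match "
                        f"genome base {expected}"
                    )
            out.append(variant)
    return out


@dataclass(frozen=True)
class VariantAssociation:
    variant: VariantRecord
    site: OffTargetSite
    distance: int
    query_label: str


def associate_variants(
    sites: Sequence[OffTargetSite],
    variants: Sequence[VariantRecord],
    max_distance: int = 50,
) -> list[VariantAssociation]:
    """Pair each variant with every off-target site within ``max_distance`` nt.

    The distance is the minimum over the site's occupied interval (0 when the
    variant falls inside the site); the threshold is inclusive.
    """
    out = []
    for variant in variants:
        for site in sites:
            start, end = site.interval()
            if start <= variant.pos <= end:
                dist = 0
            else:
                dist = min(abs(variant.pos - start), abs(variant.pos - end))
            if dist <= max_distance:
                out.append(VariantAssociation(variant, site, dist, site.query_label))
    out.sort(key=lambda a: (a.variant.pos, a.site.genome_position, a.site.strand))
    return out


def variant_context(genome: AnnotatedGenome, variant: VariantRecord,
                    flank: int = 20) -> str:
    """The wild-type sequence centred on a variant with ``flank`` nt each side."""
    start = variant.pos - 1 - flank
    end = variant.pos - 1 + flank + 1
    if not genome.circular:
        start, end = max(start, 0), min(end, len(genome))
    return genome.fetch(start, end)


# ---------------------------------------------------------------------------
# local-alignment fallback


@dataclass(frozen=True)
class LocalAlignmentReport:
    spacer_label: str
    strand: str              # orientation of the spacer in the reported alignment
    score: float
    matches: int
    mismatches: int
    gaps: int
    context_start: int       # 0-based half-open span of the context involved
    context_end: int
    aligned_spacer: str
    aligned_context: str


def local_align_fallback(
    spacer: str,
    variant_context: str,
    *,
    label: str = "",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    min_matches: int = 11,
) -> LocalAlignmentReport | None:
    """Best local alignment of a spacer (both orientations) against a context.

    This is the manual-inspection step that catches protospacer/variant
    associations the seed-limited search misses. Returns ``None`` when the
    best alignment has fewer than ``min_matches`` matching bases.
    """
    spacer = validate_dna(spacer, allow_n=False, what="spacer")
    variant_context = validate_dna(variant_context, what="context")
    if len(variant_context) < len(spacer):
        raise ValueError("context shorter than spacer")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    best = None
    for strand, seq in (("+", spacer), ("-", revcomp(spacer))):
        alns = aligner.align(variant_context, seq)
        if len(alns) == 0:
            continue
        aln = alns[0]
        tgt, qry = _expand_alignment(aln)
        n_match = sum(a == b for a, b in zip(tgt, qry) if a != "-" and b != "-")
        n_mismatch = sum(
            a != b for a, b in zip(tgt, qry) if a != "-" and b != "-"
        )
        n_gap = tgt.count("-") + qry.count("-")
        rep = LocalAlignmentReport(
            label, strand, float(aln.score), n_match, n_mismatch, n_gap,
            int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]), qry, tgt,
        )
        if best is None or (rep.score, rep.matches) > (best.score, best.matches):
            best = rep
    if best is None or best.matches < min_matches:
        return None
    return best


def _expand_alignment(aln) -> tuple[str, str]:
    """Gapped (target, query) strings of a Bio.Align alignment."""
    text = str(aln).splitlines()
    # Bio.Align pretty-printer: rows 'target', pipes, 'query'; robust fallback:
    try:
        return aln[0], aln[1]
    except Exception:
        return text[0].split()[-1], text[2].split()[-1]


# ---------------------------------------------------------------------------
# deletion-region analysis


def genes_in_region(genome: AnnotatedGenome, start: int, size: int,
                    include_pseudo: bool = True) -> list[CdsRecord]:
    """Annotated CDS features wholly contained in [start, start+size) (1-based).

    Used to enumerate the genes removed by a coverage-zero deletion region.
    """
    end = start + size - 1
    out = []
    for rec in genome.features:
        if rec.pseudo_flag and not include_pseudo:
            continue
        if rec.end >= rec.start and rec.start >= start and rec.end <= end:
            out.append(rec)
    return out


def region_offtargets(
    genome: AnnotatedGenome,
    queries: Iterable[OffTargetQuery],
    start: int,
    size: int,
    mode: Literal["primary", "raw"] = "primary",
) -> list[OffTargetSite]:
    """Off-target sites whose occupied interval lies within a genomic region."""
    end = start + size - 1
    out = []
    for query in queries:
        for site in search_offtargets(genome, query, mode=mode):
            s, e = site.interval()
            if s >= start and e <= end:
                out.append(site)
    return out
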
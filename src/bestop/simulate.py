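"""Synthetic circular bacterial genomes with planted, ledgered ground truth.

The generator emulates the substrate of the design pipeline — a circular
prokaryotic chromosome with non-overlapping, strand-mixed CDS annotations —
and then *plants* features with exactly known properties: STOP-capable
protospacers (a single editable window cytosine whose C->T conversion creates
a premature stop), off-target sites at a chosen mismatch/bulge distance from
a spacer, and SNPs at chosen distances from those sites. Every planted
feature is recorded in a ledger so pipeline stages can be tested for exact
recovery without any external data.

The background model is deliberately simple: intergenic sequence is i.i.d.
with a configurable GC content (default 0.31, the AT-rich composition typical
of acetogenic clostridia) and CDSs are random non-stop codons between an ATG
start and a stop. A ``cds_alphabet="AT"`` mode builds coding sequences from
A/T-only codons, which makes STOP-capable protospacers impossible anywhere
except where they are planted (window cytosines require a C or G on the
coding strand) — useful for exact-coverage fixtures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from types import SimpleNamespace
from typing import Literal, Sequence

import numpy as np

from ._seq import STOP_CODONS, iupac_matches, revcomp
from .design import EditingWindow, PamSpec, classify_hit, scan_pam_sites
from .genome import AnnotatedGenome, CdsRecord
from .offtarget import OffTargetQuery, VariantRecord, search_offtargets

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedLedger",
    "PlantedProtospacer",
    "PlantedOffTarget",
    "PlantedVariant",
    "generate_annotated_genome",
    "plant_stop_protospacer",
    "plant_offtarget_site",
    "generate_variants",
    "write_genbank",
    "write_fasta_gff3",
    "write_vcf",
]

RETRY_BUDGET = 100


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_genes: int = 50
    gene_length_mean: float = 900.0
    gene_length_sd: float = 300.0
    min_gene_length: int = 90
    intergenic_mean: float = 150.0
    intergenic_sd: float = 80.0
    min_intergenic: int = 30
    gc: float = 0.31
    circular: bool = True
    minus_fraction: float = 0.5
    cds_alphabet: Literal["ACGT", "AT"] = "ACGT"

    def __post_init__(self) -> None:
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.n_genes < 0 or self.min_gene_length < 3:
            raise ValueError("invalid gene settings")


@dataclass
class PlantedProtospacer:
    cds_id: str
    genome_start: int          # 1-based leftmost protospacer base
    strand: str
    orientation: str
    protospacer_seq: str
    pam_seq: str
    window_c_offsets: tuple[int, ...]
    stop_offsets: tuple[tuple[int, ...], ...]  # edit subsets expected to give stops
    expected_quality: str
    cds_fraction: float


@dataclass
class PlantedOffTarget:
    query_label: str
    spacer: str
    genome_position: int       # 1-based leftmost base of the aligned target
    strand: str
    mismatches: int
    bulge_type: str
    bulge_size: int
    pam_seq: str


@dataclass
class PlantedVariant:
    pos: int
    ref: str
    alt: str
    site_label: str            # "" for background SNPs
    site_position: int         # 0 for background SNPs
    distance: int              # -1 for background SNPs


@dataclass
class PlantedLedger:
    protospacers: list[PlantedProtospacer] = field(default_factory=list)
    offtargets: list[PlantedOffTarget] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "protospacers": [asdict(e) for e in self.protospacers],
                "offtargets": [asdict(e) for e in self.offtargets],
                "variants": [asdict(e) for e in self.variants],
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "PlantedLedger":
        with open(path) as fh:
            raw = json.load(fh)
        led = cls()
        for d in raw["protospacers"]:
            d["window_c_offsets"] = tuple(d["window_c_offsets"])
            d["stop_offsets"] = tuple(tuple(t) for t in d["stop_offsets"])
            led.protospacers.append(PlantedProtospacer(**d))
        led.offtargets = [PlantedOffTarget(**d) for d in raw["offtargets"]]
        led.variants = [PlantedVariant(**d) for d in raw["variants"]]
        return led


# ---------------------------------------------------------------------------
# genome generation


def _random_bases(rng: np.random.RandomState, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _random_cds(rng: np.random.RandomState, length: int, gc: float,
                alphabet: str) -> str:
    """ATG + random non-stop codons + stop, of the requested total length."""
    n_internal = length // 3 - 2
    if alphabet == "AT":
        codons = []
        while len(codons) < n_internal:
            c = "".join("AT"[i] for i in rng.randint(0, 2, size=3))
            if c not in STOP_CODONS:
                codons.append(c)
        return "ATG" + "".join(codons) + "TAA"
    codons = []
    while len(codons) < n_internal:
        c = _random_bases(rng, 3, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    stop = ("TAA", "TAG", "TGA")[rng.randint(0, 3)]
    return "ATG" + "".join(codons) + stop


def generate_annotated_genome(
    spec: SyntheticGenomeSpec, seed: int
) -> tuple[AnnotatedGenome, PlantedLedger]:
    """Deterministically generate an annotated genome (and an empty ledger)."""
    rng = np.random.RandomState(seed)
    chunks: list[str] = []
    features: list[CdsRecord] = []
    pos = 0
    for i in range(spec.n_genes):
        gap = max(spec.min_intergenic,
                  int(round(rng.normal(spec.intergenic_mean, spec.intergenic_sd))))
        chunks.append(_random_bases(rng, gap, spec.gc))
        pos += gap
        length = max(spec.min_gene_length,
                     int(round(rng.normal(spec.gene_length_mean, spec.gene_length_sd))))
        length -= length % 3
        coding = _random_cds(rng, length, spec.gc, spec.cds_alphabet)
        strand = "-" if rng.random_sample() < spec.minus_fraction else "+"
        genomic = coding if strand == "+" else revcomp(coding)
        chunks.append(genomic)
        features.append(CdsRecord(f"SYN_{i + 1:04d}", pos + 1, pos + length,
                                  strand, coding))
        pos += length
    gap = max(spec.min_intergenic,
              int(round(rng.normal(spec.intergenic_mean, spec.intergenic_sd))))
    chunks.append(_random_bases(rng, gap, spec.gc))
    genome = AnnotatedGenome("synthetic_1", "".join(chunks), spec.circular, features)
    return genome, PlantedLedger()


# ---------------------------------------------------------------------------
# planting STOP-capable protospacers


def _write_segment(genome: AnnotatedGenome, rec: CdsRecord, r0: int, r1: int,
                   segment: str) -> AnnotatedGenome:
    """Replace coding positions [r0, r1) of a CDS, returning a new genome."""
    coding = rec.coding_sequence[:r0] + segment + rec.coding_sequence[r1:]
    s0 = rec.start - 1
    if rec.strand == "+":
        g0, g1 = s0 + r0, s0 + r1
        piece = segment
    else:
        e0 = rec.end
        g0, g1 = e0 - r1, e0 - r0
        piece = revcomp(segment)
    seq = genome.sequence[:g0] + piece + genome.sequence[g1:]
    feats = [CdsRecord(f.id, f.start, f.end, f.strand,
                       coding if f.id == rec.id else f.coding_sequence, f.pseudo_flag)
             for f in genome.features]
    return AnnotatedGenome(genome.id, seq, genome.circular, feats)


def _fix_frame_stops(segment: str, r0: int, protected: set[int]) -> str | None:
    """Remove in-frame stops by editing unprotected bases (coding coords r0+i)."""
    seg = list(segment)
    for k in range(0, len(seg) - 2, 3):
        codon = "".join(seg[k:k + 3])
        if codon in STOP_CODONS:
            fixed = False
            for j in range(3):
                if r0 + k + j not in protected:
                    seg[k + j] = "C" if j else "G"  # no stop starts with G / has C
                    fixed = True
                    break
            if not fixed:
                return None
            if "".join(seg[k:k + 3]) in STOP_CODONS:
                return None
    return "".join(seg)


def plant_stop_protospacer(
    genome: AnnotatedGenome,
    cds_id: str,
    orientation: Literal["sense", "antisense"],
    window_offset: int,
    seed: int,
    *,
    pam_seq: str = "AGG",
    pam_pattern: str | None = None,
    window: EditingWindow = EditingWindow(),
    first_fraction: float = 0.75,
    allow_beyond: bool = False,
    spacer_length: int = 20,
    filler: str | None = None,
) -> tuple[AnnotatedGenome, PlantedProtospacer]:
    """Rewrite part of a CDS so a known STOP-capable protospacer exists there.

    Sense plants put a single window cytosine (a CAA codon, editable to TAA)
    at ``window_offset``; antisense plants put a coding-strand TGG codon whose
    protospacer-strand CCA image yields cytosines at ``window_offset`` and
    ``window_offset + 1`` (three stop-producing edit subsets). The ledger
    entry records the exact expected hit; placement is rejection-sampled until
    direct re-inspection of the rewritten genome validates every property.
    """
    rng = np.random.RandomState(seed)
    if pam_pattern is None:
        pam_pattern = pam_seq  # the literal PAM is its own (exact) pattern
    rec = next((f for f in genome.features if f.id == cds_id), None)
    if rec is None:
        raise KeyError(f"no CDS {cds_id!r}")
    if orientation == "sense":
        if not (window.from_pos <= window_offset <= window.to_pos):
            raise ValueError("window_offset outside the editing window")
    else:
        if not (window.from_pos <= window_offset
                and window_offset + 1 <= window.to_pos):
            raise ValueError("antisense plant needs window_offset and its "
                             "successor inside the editing window")
    L, k = spacer_length, len(pam_seq)
    cds_len = len(rec.coding_sequence)
    limit = cds_len if allow_beyond else int(first_fraction * cds_len)
    if allow_beyond:
        lo_codon = int(first_fraction * cds_len) // 3 + 2
    else:
        lo_codon = 1

    candidates = list(range(lo_codon, max(lo_codon + 1, (limit - 1) // 3)))
    rng.shuffle(candidates)
    last_error = "no candidate codon positions"
    for codon_idx in candidates[:RETRY_BUDGET]:
        cp = codon_idx * 3  # coding position of the stop-source codon start
        if orientation == "sense":
            a = cp - (L + window_offset)  # protospacer start, coding coords
            region = (a, a + L + k)
            stop_subsets = ((window_offset,),)
            c_offsets = (window_offset,)
        else:
            a = cp + 3 + window_offset
            region = (a - k, a + L)
            stop_subsets = ((window_offset,), (window_offset + 1,),
                            (window_offset, window_offset + 1))
            c_offsets = (window_offset, window_offset + 1)
        r0 = (region[0] // 3) * 3
        r1 = -(-region[1] // 3) * 3
        if r0 < 3 or r1 > cds_len - 3:
            continue
        fill = filler or ("GAA" if orientation == "sense" else "AAA")
        if len(fill) != 3 or fill in STOP_CODONS or "C" in fill:
            raise ValueError("filler must be a C-free non-stop codon")
        seg = list(fill * ((r1 - r0) // 3))
        protected: set[int] = set()

        def put(pos: int, text: str) -> None:
            for j, ch in enumerate(text):
                seg[pos - r0 + j] = ch
                protected.add(pos + j)

        if orientation == "sense":
            put(cp, "CAA")
            put(a + L, pam_seq)
            for o in window.offsets():  # keep the rest of the window C-free
                protected.add(a + L + o)
        else:
            put(cp, "TGG")
            put(a - k, revcomp(pam_seq))
            for o in window.offsets():
                protected.add(a - 1 - o)
        fixed = _fix_frame_stops("".join(seg), r0, protected)
        if fixed is None:
            last_error = "could not clear accidental in-frame stops"
            continue
        updated = _write_segment(genome, rec, r0, r1, fixed)
        entry = _verify_plant(updated, cds_id, orientation, a, L, k, pam_seq,
                              pam_pattern, window, c_offsets, stop_subsets, cp)
        if entry is None:
            last_error = "re-inspection of the rewritten genome failed"
            continue
        return updated, entry
    raise RuntimeError(f"could not plant protospacer in {cds_id}: {last_error}")


def _verify_plant(genome, cds_id, orientation, a, L, k, pam_seq, pam_pattern,
                  window, c_offsets, stop_subsets, cp):
    rec = next(f for f in genome.features if f.id == cds_id)
    coding = rec.coding_sequence
    # CDS integrity
    if (len(coding) % 3 or coding[:3] != "ATG" or coding[-3:] not in STOP_CODONS
            or any(coding[i:i + 3] in STOP_CODONS
                   for i in range(0, len(coding) - 3, 3))):
        return None
    n = len(genome)
    s0 = rec.start - 1
    # the protospacer spans coding positions [a, a+L) for either orientation;
    # orientation only decides which strand it is read from
    g_left = s0 + a if rec.strand == "+" else rec.end - (a + L)
    if orientation == "sense":
        proto_strand = rec.strand
    else:
        proto_strand = "-" if rec.strand == "+" else "+"
    # protospacer bases 5'->3' on its own strand
    seg = genome.fetch(g_left, g_left + L)
    proto = seg if proto_strand == "+" else revcomp(seg)
    if proto_strand == "+":
        pam = genome.fetch(g_left + L, g_left + L + k)
    else:
        pam = revcomp(genome.fetch((g_left - k) % n, (g_left - k) % n + k))
    if not iupac_matches(pam_pattern, pam) or pam != pam_seq:
        return None
    got_c = tuple(o for o in window.offsets() if proto[L + o] == "C")
    if got_c != tuple(sorted(c_offsets)):
        return None
    # direct substitution check for every expected subset
    wt = coding[cp:cp + 3]
    for subset in stop_subsets:
        mut = list(wt)
        for o in subset:
            cpos = (a + L + o) if orientation == "sense" else (a - 1 - o)
            if not cp <= cpos < cp + 3:
                return None
            mut[cpos - cp] = "T" if orientation == "sense" else "A"
        if "".join(mut) not in STOP_CODONS:
            return None
    frac = (cp + 1) / len(coding)
    hitlike = SimpleNamespace(window_c_offsets=got_c)
    return PlantedProtospacer(
        cds_id=cds_id, genome_start=g_left + 1, strand=proto_strand,
        orientation=orientation, protospacer_seq=proto, pam_seq=pam,
        window_c_offsets=got_c, stop_offsets=tuple(stop_subsets),
        expected_quality=classify_hit(hitlike, window), cds_fraction=frac,
    )


# ---------------------------------------------------------------------------
# planting off-target sites


def _intergenic_slots(genome: AnnotatedGenome, need: int, clearance: int,
                      avoid: Sequence[tuple[int, int]] = ()) -> list[int]:
    """Starts of intergenic windows of length ``need`` with CDS clearance.

    ``avoid`` lists extra 1-based inclusive intervals (e.g. previously planted
    sites) to keep clear of.
    """
    n = len(genome)
    covered = np.zeros(n, dtype=bool)
    for f in genome.features:
        s0, e0 = f.start - 1 - clearance, f.end + clearance
        covered[max(s0, 0):min(e0, n)] = True
    for a, b in avoid:
        s0, e0 = a - 1 - clearance, b + clearance
        covered[max(s0, 0):min(e0, n)] = True
    free = ~covered
    run = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if free[i] else 0
    return [i for i in range(n - need) if run[i] >= need]


def plant_offtarget_site(
    genome: AnnotatedGenome,
    spacer: str,
    n_mismatches: int,
    bulge_type: Literal["none", "DNA", "RNA"],
    bulge_size: int,
    seed: int,
    *,
    label: str = "planted",
    pam_seq: str = "AGG",
    pam_pattern: str = "NGG",
    clearance: int | None = None,
    avoid: Sequence[tuple[int, int]] = (),
    verify_limits: tuple[int, int, int] | None = None,
) -> tuple[AnnotatedGenome, PlantedOffTarget]:
    """Write a target at an intergenic locus with an exact mismatch/bulge profile.

    The profile is validated by running the off-target search over
    ``verify_limits`` (default: the planted mismatch count with 2-nt bulges of
    both kinds, i.e. the full search space the site will be tested under) and
    requiring the best alignment at the planted position to match exactly;
    placements where an alternative gapped alignment explains the site more
    cheaply are rejected and re-sampled (up to the retry budget).
    """
    if bulge_type == "none" and bulge_size != 0:
        raise ValueError("bulge_size must be 0 when bulge_type is none")
    if bulge_type != "none" and bulge_size < 1:
        raise ValueError("bulge_size must be >= 1 for a bulge")
    rng = np.random.RandomState(seed)
    L = len(spacer)
    target_len = L + (bulge_size if bulge_type == "DNA" else
                      -bulge_size if bulge_type == "RNA" else 0)
    need = target_len + len(pam_seq)
    slots = _intergenic_slots(genome, need, clearance if clearance is not None
                              else L, avoid)
    if not slots:
        raise RuntimeError("no intergenic slot large enough for the planted site")
    bases = "ACGT"
    for _ in range(RETRY_BUDGET):
        target = list(spacer)
        if bulge_type == "RNA":
            i = rng.randint(1, L - bulge_size)
            target = target[:i] + target[i + bulge_size:]
        elif bulge_type == "DNA":
            i = rng.randint(1, L)
            ins = [bases[j] for j in rng.randint(0, 4, size=bulge_size)]
            target = target[:i] + ins + target[i:]
        if bulge_type == "DNA":
            # inserted positions are wildcards in the search; mismatches there
            # would silently vanish from the profile
            concrete = [j for j in range(len(target)) if not i <= j < i + bulge_size]
        else:
            concrete = list(range(len(target)))
        mm_pos = rng.choice(concrete, size=n_mismatches, replace=False)
        for j in mm_pos:
            target[j] = bases[(bases.index(target[j]) + rng.randint(1, 4)) % 4]
        target_seq = "".join(target)
        pos0 = int(slots[rng.randint(0, len(slots))])
        strand = "+-"[rng.randint(0, 2)]
        if strand == "+":
            insert, g0 = target_seq + pam_seq, pos0
        else:
            insert, g0 = revcomp(target_seq + pam_seq), pos0
        trial = AnnotatedGenome(
            genome.id,
            genome.sequence[:g0] + insert + genome.sequence[g0 + len(insert):],
            genome.circular, list(genome.features),
        )
        if strand == "+":
            planted_pos1 = g0 + 1
        else:
            planted_pos1 = g0 + len(pam_seq) + 1
        vm, vd, vr = verify_limits or (
            n_mismatches,
            max(2, bulge_size if bulge_type == "DNA" else 0),
            max(2, bulge_size if bulge_type == "RNA" else 0),
        )
        query = OffTargetQuery(label, spacer, pam_pattern, vm, vd, vr)
        found = [s for s in search_offtargets(trial, query, mode="primary")
                 if s.genome_position == planted_pos1 and s.strand == strand]
        if (len(found) == 1 and found[0].mismatches == n_mismatches
                and found[0].bulge_type == bulge_type
                and found[0].bulge_size == bulge_size):
            entry = PlantedOffTarget(label, spacer, planted_pos1, strand,
                                     n_mismatches, bulge_type, bulge_size, pam_seq)
            return trial, entry
    raise RuntimeError("could not plant off-target site with the exact profile")


# ---------------------------------------------------------------------------
# variants


def generate_variants(
    genome: AnnotatedGenome,
    sites: Sequence[PlantedOffTarget],
    distances: Sequence[int] = (0, 25, 50, 51),
    n_background: int = 3,
    background_gap: int = 500,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[PlantedVariant]]:
    """SNPs at controlled distances from sites, plus distant background SNPs."""
    rng = np.random.RandomState(seed)
    n = len(genome)
    bases = "ACGT"
    variants: list[VariantRecord] = []
    ledger: list[PlantedVariant] = []
    site_spans = []
    for i, site in enumerate(sites):
        span = len(site.spacer) + (site.bulge_size if site.bulge_type == "DNA"
                                   else -site.bulge_size if site.bulge_type == "RNA"
                                   else 0)
        start, end = site.genome_position, site.genome_position + span - 1
        site_spans.append((start, end))
        for d in distances:
            pos = start if d == 0 else end + d
            if not (1 <= pos <= n):
                continue
            ref = genome.sequence[pos - 1]
            alt = bases[(bases.index(ref) + rng.randint(1, 4)) % 4] if ref != "N" else "A"
            variants.append(VariantRecord(genome.id, pos, ref, alt, f"planted_d{d}"))
            ledger.append(PlantedVariant(pos, ref, alt, site.query_label,
                                         site.genome_position, d))
    placed = 0
    for _ in range(RETRY_BUDGET * max(n_background, 1)):
        if placed >= n_background:
            break
        pos = int(rng.randint(1, n + 1))
        if all(abs(pos - s) > background_gap and abs(pos - e) > background_gap
               and not (s <= pos <= e) for s, e in site_spans):
            ref = genome.sequence[pos - 1]
            if ref == "N":
                continue
            alt = bases[(bases.index(ref) + rng.randint(1, 4)) % 4]
            variants.append(VariantRecord(genome.id, pos, ref, alt, "background"))
            ledger.append(PlantedVariant(pos, ref, alt, "", 0, -1))
            placed += 1
    variants.sort(key=lambda v: v.pos)
    ledger.sort(key=lambda v: v.pos)
    return variants, ledger


# ---------------------------------------------------------------------------
# writers


def write_genbank(genome: AnnotatedGenome, path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="synthetic annotated genome",
                       annotations={
                           "molecule_type": "DNA",
                           "topology": "circular" if genome.circular else "linear",
                           "date": "01-JAN-2000",
                       })
    for f in genome.features:
        feat = SeqFeature(
            FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1),
            type="CDS",
            qualifiers={"locus_tag": [f.id], "transl_table": ["11"]},
        )
        if f.pseudo_flag:
            feat.qualifiers["pseudo"] = [""]
        record.features.append(feat)
    from Bio import SeqIO

    SeqIO.write(record, path, "genbank")


def write_fasta_gff3(genome: AnnotatedGenome, fasta_path: str, gff3_path: str) -> None:
    with open(fasta_path, "w") as fh:
        topo = "circular" if genome.circular else "linear"
        fh.write(f">{genome.id} {topo} synthetic annotated genome\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            attrs = f"ID={f.id};locus_tag={f.id}"
            if f.pseudo_flag:
                attrs += ";pseudo=true"
            fh.write(f"{genome.id}\tbestop\tCDS\t{f.start}\t{f.end}\t.\t"
                     f"{f.strand}\t0\t{attrs}\n")


def write_vcf(variants: Sequence[VariantRecord], genome: AnnotatedGenome,
              path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={len(genome)}>\n")
        fh.write("##INFO=<ID=ANN,Number=1,Type=String,Description=\"Annotation\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.pos):
            info = f"ANN={v.annotation}" if v.annotation else "."
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
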
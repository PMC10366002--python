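"""Annotated-genome I/O, CDS extraction and codon-usage computation.

The genome container is deliberately small: a sequence, a circular flag and an
ordered list of CDS records. GenBank and FASTA+GFF3 are read through Biopython
and gffutils; everything downstream (PAM scans, off-target search) works on
this container only, so synthetic and real genomes are interchangeable.

Coordinates: ``CdsRecord.start``/``end`` are 1-based inclusive, matching
GenBank/GFF3. A record on a circular genome may wrap the origin, in which case
``start > end``. Internal helpers use 0-based half-open offsets.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from ._seq import revcomp, validate_dna, STOP_CODONS

__all__ = [
    "AnnotatedGenome",
    "CdsRecord",
    "CodonUsageTable",
    "read_genome",
    "extract_cds_records",
    "compute_codon_usage",
    "write_hits",
    "read_hits_json",
]

#: Standard bacterial/archaeal code (transl_table=11).
BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def codon_to_aa(codon: str) -> str:
    """One-letter amino acid under the bacterial code; '*' for stops."""
    return "*" if codon in STOP_CODONS else BACTERIAL_TABLE.forward_table[codon]


@dataclass
class CdsRecord:
    """One protein-coding feature.

    ``coding_sequence`` is read 5'->3' on the coding strand (i.e. it is the
    reverse complement of the genomic slice for minus-strand genes).
    ``pseudo_flag`` marks records excluded from design scans: annotated
    pseudogenes, compound (join) locations and CDSs whose length is not a
    multiple of three.
    """

    id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start means the CDS wraps the origin
    strand: str  # '+' or '-'
    coding_sequence: str
    pseudo_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return len(self.coding_sequence)


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    circular: bool = False
    features: list[CdsRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        self.sequence = validate_dna(self.sequence, what="genome sequence")
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature identifiers must be unique")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start0: int, end0: int) -> str:
        """Slice [start0, end0) with origin wrap-around on circular genomes."""
        n = len(self.sequence)
        if 0 <= start0 <= end0 <= n:
            return self.sequence[start0:end0]
        if not self.circular:
            raise IndexError(f"[{start0}, {end0}) outside linear genome of length {n}")
        start0 %= n
        end0 = start0 + (end0 - start0) if end0 >= start0 else end0
        out = []
        length = end0 - start0
        if length < 0:
            raise IndexError("end before start")
        pos = start0
        while length > 0:
            take = min(length, n - pos)
            out.append(self.sequence[pos:pos + take])
            length -= take
            pos = (pos + take) % n
        return "".join(out)

    def cds_genomic_slice(self, rec: CdsRecord) -> str:
        """Forward-strand genomic bases of a record (wrap-aware)."""
        if rec.end >= rec.start:
            return self.fetch(rec.start - 1, rec.end)
        if not self.circular:
            raise ValueError(f"wrapping CDS {rec.id} on a linear genome")
        return self.fetch(rec.start - 1, rec.end + len(self.sequence))


def _feature_id(feature, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"CDS_{index:05d}"


def _from_seqrecord(record) -> AnnotatedGenome:
    circular = record.annotations.get("topology", "linear") == "circular"
    genome = AnnotatedGenome(id=record.id, sequence=str(record.seq), circular=circular)
    seen: set[str] = set()
    for i, feature in enumerate(f for f in record.features if f.type == "CDS"):
        fid = _feature_id(feature, i)
        while fid in seen:
            fid += "_dup"
        seen.add(fid)
        loc = feature.location
        compound = len(loc.parts) > 1
        start = int(loc.start) + 1
        end = int(loc.end)
        strand = "-" if loc.strand == -1 else "+"
        coding = str(feature.extract(record.seq))
        pseudo = (
            "pseudo" in feature.qualifiers
            or "pseudogene" in feature.qualifiers
            or compound
            or len(coding) % 3 != 0
        )
        genome.features.append(
            CdsRecord(fid, start, end, strand, coding.upper(), pseudo)
        )
    genome.features.sort(key=lambda r: (r.start, r.strand))
    return genome


def _from_fasta_gff3(fasta_path: str, gff3_path: str) -> AnnotatedGenome:
    import gffutils

    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    record = records[0]
    circular = "circular" in record.description.lower()
    genome = AnnotatedGenome(id=record.id, sequence=str(record.seq), circular=circular)

    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    for i, feat in enumerate(db.features_of_type("CDS", order_by="start")):
        if feat.seqid != record.id:
            raise ValueError(
                f"GFF3 seqid {feat.seqid!r} does not match FASTA id {record.id!r}"
            )
        fid = (
            feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or f"CDS_{i:05d}"
        )
        seg = genome.fetch(feat.start - 1, feat.end)
        coding = revcomp(seg) if feat.strand == "-" else seg
        pseudo = (
            feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
            or len(coding) % 3 != 0
        )
        genome.features.append(
            CdsRecord(fid, feat.start, feat.end, feat.strand or "+", coding.upper(), pseudo)
        )
    genome.features.sort(key=lambda r: (r.start, r.strand))
    return genome


def read_genome(path: str, format: str = "genbank", gff3: str | None = None) -> AnnotatedGenome:
    """Read an annotated genome from GenBank or FASTA+GFF3.

    Parameters
    ----------
    path
        GenBank flat file, or the FASTA file when ``format="fasta+gff3"``.
    format
        ``"genbank"`` or ``"fasta+gff3"``.
    gff3
        The GFF3 annotation path (required for ``fasta+gff3``).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "genbank":
        try:
            records = list(SeqIO.parse(path, "genbank"))
        except Exception as exc:  # Biopython raises assorted parse errors
            raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
        if len(records) != 1:
            raise ValueError(f"expected a single GenBank record, found {len(records)}")
        return _from_seqrecord(records[0])
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3= path")
        return _from_fasta_gff3(path, gff3)
    raise ValueError(f"unknown format {format!r}")


def extract_cds_records(genome: AnnotatedGenome) -> list[CdsRecord]:
    """Non-pseudo CDS records ordered by genomic start ('+' before '-' on ties)."""
    recs = [f for f in genome.features if not f.pseudo_flag]
    return sorted(recs, key=lambda r: (r.start, 0 if r.strand == "+" else 1))


class CodonUsageTable:
    """Codon counts, synonymous-family fractions and per-1000 frequencies.

    Mirrors the output of the EMBOSS CUSP tool: one row per codon with its
    amino acid, raw count, fraction within its synonymous family and
    occurrences per 1000 codons.
    """

    def __init__(self, counts: dict[str, int]):
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no codons to count")
        rows = []
        for codon in ALL_CODONS:
            count = counts.get(codon, 0)
            rows.append({"codon": codon, "aa": codon_to_aa(codon), "count": count})
        df = pd.DataFrame(rows)
        family_totals = df.groupby("aa")["count"].transform("sum")
        df["fraction"] = (df["count"] / family_totals).where(family_totals > 0, 0.0)
        df["per_thousand"] = df["count"] / total * 1000.0
        self.table = df.set_index("codon")
        self.total_codons = total

    def count(self, codon: str) -> int:
        return int(self.table.at[codon.upper(), "count"])

    def fraction(self, codon: str) -> float:
        return float(self.table.at[codon.upper(), "fraction"])

    def per_thousand(self, codon: str) -> float:
        return float(self.table.at[codon.upper(), "per_thousand"])

    def rank(self, codon: str) -> int:
        """1-based rank of a codon by genome-wide frequency (1 = most used)."""
        order = self.table["count"].rank(method="min", ascending=False)
        return int(order[codon.upper()])

    def to_tsv(self, path: str) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6f")


def compute_codon_usage(cds_records: Iterable[CdsRecord]) -> CodonUsageTable:
    """Tally codon usage across coding sequences (codons containing N skipped)."""
    counts: dict[str, int] = {}
    n_records = 0
    for rec in cds_records:
        if rec.pseudo_flag:
            raise ValueError(f"record {rec.id} is pseudo; codon usage is undefined")
        n_records += 1
        seq = rec.coding_sequence
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    if n_records == 0:
        raise ValueError("no CDS records given")
    return CodonUsageTable(counts)


# ---------------------------------------------------------------------------
# hit serialisation

HIT_COLUMNS = [
    "cds_id", "protospacer_seq", "pam_seq", "genome_start", "genome_end",
    "protospacer_strand", "orientation", "window_c_offsets", "n_stop_edits",
    "stop_codon_position", "cds_fraction", "quality",
]


def write_hits(hits: Sequence, path: str, format: str = "tsv") -> None:
    """Write protospacer hits as TSV, BED6 or lossless JSON.

    TSV columns are :data:`HIT_COLUMNS` (positions 1-based inclusive). BED6
    intervals are 0-based half-open over the protospacer, name = cds_id,
    score = number of stop edits. JSON round-trips through
    :func:`read_hits_json`.
    """
    if format == "tsv":
        rows = []
        for h in hits:
            rows.append({
                "cds_id": h.cds_id,
                "protospacer_seq": h.protospacer_seq,
                "pam_seq": h.pam_seq,
                "genome_start": h.genome_start,
                "genome_end": h.genome_end,
                "protospacer_strand": h.protospacer_strand,
                "orientation": h.orientation,
                "window_c_offsets": ",".join(str(o) for o in h.window_c_offsets),
                "n_stop_edits": len(h.stop_edits),
                "stop_codon_position": min(e.codon_index for e in h.stop_edits) * 3 + 1,
                "cds_fraction": f"{h.cds_fraction:.4f}",
                "quality": h.quality,
            })
        pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for h in hits:
                fh.write(
                    f"{h.genome_id}\t{h.genome_start - 1}\t{h.genome_end}\t"
                    f"{h.cds_id}\t{len(h.stop_edits)}\t{h.protospacer_strand}\n"
                )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([asdict(h) for h in hits], fh, indent=1)
    else:
        raise ValueError(f"unknown hit format {format!r}")


def read_hits_json(path: str) -> list:
    from .design import ProtospacerHit, StopEdit

    with open(path) as fh:
        raw = json.load(fh)
    hits = []
    for d in raw:
        d = dict(d)
        d["window_c_offsets"] = tuple(d["window_c_offsets"])
        d["stop_edits"] = tuple(
            StopEdit(**{**e, "edited_offsets": tuple(e["edited_offsets"])})
            for e in d["stop_edits"]
        )
        hits.append(ProtospacerHit(**d))
    return hits
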
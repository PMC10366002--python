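"""Protospacer scanning and STOP-codon knockout design for cytosine base editors.

A cytosine base editor (CBE) converts C->T on the protospacer strand within a
PAM-relative editing window (here -19..-16, counting the PAM-proximal
protospacer base as -1). A protospacer qualifies as a knockout guide when some
non-empty subset of its window cytosines, once deaminated, turns an in-frame
codon of an overlapping CDS into TAA, TAG or TGA:

* sense protospacers (same strand as the CDS) edit the coding strand directly,
  so CAA->TAA, CAG->TAG and CGA->TGA are the productive wild-type codons;
* antisense protospacers edit the template strand, which reads as G->A on the
  coding strand, so TGG (Trp) is the productive codon: its CCA image on the
  protospacer strand yields TTA, TCA or CTA, i.e. TAA, TGA or TAG in frame.

Genome-wide scans are numpy-vectorized; per-site stop-edit enumeration is
exhaustive over C subsets (the window holds at most a handful of cytosines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal

import numpy as np

from ._seq import (
    STOP_CODONS,
    encode,
    iupac_match_table,
    revcomp,
    validate_dna,
)
from .genome import AnnotatedGenome, CdsRecord, extract_cds_records

__all__ = [
    "PamSpec",
    "EditingWindow",
    "StopEdit",
    "PamSite",
    "ProtospacerHit",
    "scan_pam_sites",
    "stop_edits_for_protospacer",
    "design_knockouts",
    "classify_hit",
    "PAM_PRESETS",
]


@dataclass(frozen=True)
class PamSpec:
    """A PAM recognition pattern, e.g. NGG (SpCas9), NG (SpCas9-NG), NAA (iSpymac)."""

    name: str
    pattern: str
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("PAM pattern must be non-empty")
        iupac_match_table(self.pattern)  # validates characters
        if self.spacer_length <= 0:
            raise ValueError("spacer_length must be positive")


PAM_PRESETS = {
    "NGG": PamSpec("Target-AID", "NGG"),
    "NG": PamSpec("Target-AID-NG", "NG"),
    "NGN": PamSpec("Target-AID-NG(NGN)", "NGN"),
    "NAA": PamSpec("Cas9-iSpymac", "NAA"),
}


@dataclass(frozen=True)
class EditingWindow:
    """Inclusive PAM-relative window of deaminase activity (negative offsets)."""

    from_pos: int = -19
    to_pos: int = -16

    def __post_init__(self) -> None:
        if not (self.from_pos <= self.to_pos <= -1):
            raise ValueError("window must satisfy from_pos <= to_pos <= -1")

    def offsets(self) -> range:
        return range(self.from_pos, self.to_pos + 1)

    def validate_for(self, spacer_length: int) -> None:
        if self.from_pos < -spacer_length:
            raise ValueError(
                f"window start {self.from_pos} outside a {spacer_length} nt spacer"
            )


@dataclass(frozen=True)
class StopEdit:
    """One C->T edit subset that creates a premature stop codon."""

    edited_offsets: tuple[int, ...]  # PAM-relative window offsets, ascending
    codon_index: int                 # 0-based codon number on the coding sequence
    wt_codon: str
    mutant_codon: str
    stop_triplet: str

    def __post_init__(self) -> None:
        if self.mutant_codon != self.stop_triplet or self.stop_triplet not in STOP_CODONS:
            raise ValueError("mutant codon must be the stop triplet")
        if self.wt_codon in STOP_CODONS:
            raise ValueError("wild-type codon is already a stop")


@dataclass(frozen=True)
class PamSite:
    """A PAM occurrence with room for a full-length protospacer 5' of it.

    ``proto_start0`` is the 0-based forward-strand coordinate of the leftmost
    protospacer base; on the minus strand the protospacer reads 5'->3' from the
    rightmost base of that interval and the PAM sits immediately left of it.
    """

    strand: str
    proto_start0: int
    spacer_length: int
    pam_length: int

    def protospacer_seq(self, genome: AnnotatedGenome) -> str:
        seg = genome.fetch(self.proto_start0, self.proto_start0 + self.spacer_length)
        return seg if self.strand == "+" else revcomp(seg)

    def pam_seq(self, genome: AnnotatedGenome) -> str:
        n = len(genome)
        if self.strand == "+":
            a = self.proto_start0 + self.spacer_length
            return genome.fetch(a, a + self.pam_length)
        a = (self.proto_start0 - self.pam_length) % n
        return revcomp(genome.fetch(a, a + self.pam_length))

    def offset_to_fwd(self, offset: int, n: int) -> int:
        """Forward-strand coordinate of PAM-relative protospacer ``offset`` (< 0)."""
        i = self.spacer_length + offset  # index along the protospacer, 5'->3'
        if self.strand == "+":
            return (self.proto_start0 + i) % n
        return (self.proto_start0 + self.spacer_length - 1 - i) % n


@dataclass(frozen=True)
class ProtospacerHit:
    """A (protospacer site, CDS) pair with its stop-producing edit set."""

    genome_id: str
    cds_id: str
    protospacer_seq: str
    pam_seq: str
    genome_start: int            # 1-based inclusive, leftmost protospacer base
    genome_end: int              # 1-based inclusive
    protospacer_strand: str
    orientation: str             # 'sense' | 'antisense' relative to the CDS
    window_c_offsets: tuple[int, ...]
    stop_edits: tuple[StopEdit, ...]
    cds_fraction: float          # first base of earliest stop codon / CDS length
    quality: str = field(default="")

    def __post_init__(self) -> None:
        if not self.stop_edits:
            raise ValueError("a hit must carry at least one stop edit")
        if not (0.0 < self.cds_fraction <= 1.0):
            raise ValueError("cds_fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# PAM scanning


def _match_positions(codes_ext: np.ndarray, table: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Positions p in [lo, hi) where the pattern matches codes_ext[p : p+k]."""
    if hi <= lo:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(hi - lo, dtype=bool)
    for i in range(table.shape[0]):
        mask &= table[i][codes_ext[lo + i: hi + i]]
    return np.nonzero(mask)[0] + lo


def scan_pam_sites(genome: AnnotatedGenome, pam: PamSpec) -> list[PamSite]:
    """All PAM occurrences on both strands with a full protospacer available.

    Circular genomes are scanned across the origin (the protospacer and the
    PAM may both wrap). Sites are sorted by forward protospacer start, '+'
    strand first on ties.
    """
    n = len(genome)
    k = len(pam.pattern)
    L = pam.spacer_length
    table = iupac_match_table(pam.pattern)
    codes = encode(genome.sequence)
    rc_codes = encode(revcomp(genome.sequence))

    sites: list[PamSite] = []
    if genome.circular:
        pad = k - 1
        ext_f = np.concatenate([codes, codes[:pad]]) if pad else codes
        ext_r = np.concatenate([rc_codes, rc_codes[:pad]]) if pad else rc_codes
        lo, hi = 0, n
    else:
        ext_f, ext_r = codes, rc_codes
        lo, hi = L, n - k + 1
    if n < L + k and not genome.circular:
        return []
    for p in _match_positions(ext_f, table, lo, hi):
        sites.append(PamSite("+", int(p - L) % n if genome.circular else int(p - L), L, k))
    for p in _match_positions(ext_r, table, lo, hi):
        sites.append(PamSite("-", int(n - p) % n, L, k))
    sites.sort(key=lambda s: (s.proto_start0, 0 if s.strand == "+" else 1))
    return sites


# ---------------------------------------------------------------------------
# stop-edit enumeration


def _enumerate_edit_subsets(
    c_offsets: list[int],
    edit_map: dict[int, tuple[int, str]],
    coding_sequence: str,
    single_only: bool = False,
) -> list[StopEdit]:
    """All stop-producing C->T subsets.

    ``c_offsets`` are the window offsets carrying a protospacer-strand C;
    ``edit_map`` maps those offsets to (coding position, edited coding base) for
    the offsets that fall inside the CDS. Offsets outside the CDS may join a
    subset but can never produce a stop themselves.
    """
    edits: list[StopEdit] = []
    seq = coding_sequence
    max_size = 1 if single_only else len(c_offsets)
    for size in range(1, max_size + 1):
        for subset in combinations(sorted(c_offsets), size):
            in_cds = [edit_map[o] for o in subset if o in edit_map]
            codons = sorted({cp // 3 for cp, _ in in_cds})
            for ci in codons:
                wt = seq[3 * ci: 3 * ci + 3]
                if len(wt) < 3 or wt in STOP_CODONS:
                    continue
                mut = list(wt)
                for cp, base in in_cds:
                    if cp // 3 == ci:
                        mut[cp % 3] = base
                mutant = "".join(mut)
                if mutant in STOP_CODONS:
                    edits.append(StopEdit(tuple(subset), ci, wt, mutant, mutant))
    edits.sort(key=lambda e: (e.codon_index, len(e.edited_offsets), e.edited_offsets))
    return edits


def stop_edits_for_protospacer(
    protospacer_seq: str,
    orientation: Literal["sense", "antisense"],
    frame_offset: int,
    window: EditingWindow = EditingWindow(),
    single_only: bool = False,
) -> list[StopEdit]:
    """Enumerate stop-producing C->T subsets from the protospacer alone.

    ``frame_offset`` (0..2) is the codon phase of the 5'-most base of the
    protospacer's coding-strand projection (the protospacer itself for sense
    guides, its reverse complement for antisense guides). Only codons lying
    wholly within the protospacer span are considered; codon indices are
    numbered along that projection.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0..2, got {frame_offset}")
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be sense/antisense, got {orientation!r}")
    s = validate_dna(protospacer_seq, what="protospacer")
    L = len(s)
    window.validate_for(L)
    cs = s if orientation == "sense" else revcomp(s)
    edited_base = "T" if orientation == "sense" else "A"

    c_offsets = [o for o in window.offsets() if s[L + o] == "C"]
    edit_map: dict[int, tuple[int, str]] = {}
    for o in c_offsets:
        i = L + o
        j = i if orientation == "sense" else L - 1 - i
        edit_map[o] = (j + frame_offset, edited_base)
    # shift so coding positions are phased: position p has phase p % 3
    return _enumerate_edit_subsets(c_offsets, edit_map, "N" * frame_offset + cs,
                                   single_only=single_only)


def classify_hit(hit: ProtospacerHit, window: EditingWindow = EditingWindow()) -> str:
    """Quality label for a hit based on its window cytosine placement.

    ``clean``: a single window C at -18 or -19 (the positions the deaminase
    edits reliably); ``multi_C``: two or more window Cs (risk of unwanted
    co-edits and mixed colonies); ``window_edge``: a single C at -17 or -16
    (rarely edited successfully).
    """
    cs = hit.window_c_offsets
    if len(cs) >= 2:
        return "multi_C"
    if len(cs) == 1 and cs[0] in (-18, -19):
        return "clean"
    return "window_edge"


# ---------------------------------------------------------------------------
# genome-wide knockout design


class _CdsIndex:
    """Interval lookup over non-pseudo CDS records (wrap-aware)."""

    def __init__(self, genome: AnnotatedGenome):
        self.n = len(genome)
        recs = extract_cds_records(genome)
        entries = []
        for rec in recs:
            start0 = rec.start - 1
            end0 = start0 + len(rec.coding_sequence)  # may exceed n when wrapping
            entries.append((start0, end0, rec))
        entries.sort(key=lambda e: e[0])
        self.starts = np.array([e[0] for e in entries], dtype=np.int64)
        self.entries = entries
        self.max_len = max((e[1] - e[0] for e in entries), default=0)

    def covering(self, pos: int) -> list[tuple[int, int, CdsRecord]]:
        """CDS entries whose interval contains forward position ``pos``."""
        out = []
        for g in (pos, pos + self.n):
            hi = int(np.searchsorted(self.starts, g, side="right"))
            lo = int(np.searchsorted(self.starts, g - self.max_len, side="left"))
            for j in range(lo, hi):
                s0, e0, rec = self.entries[j]
                if s0 <= g < e0:
                    out.append((s0, e0, rec))
        return out


def _coding_position(g: int, s0: int, e0: int, strand: str, n: int) -> int:
    """0-based coding-strand position of forward coordinate g within [s0, e0)."""
    gu = g if s0 <= g < e0 else g + n
    return gu - s0 if strand == "+" else e0 - 1 - gu


def design_knockouts(
    genome: AnnotatedGenome,
    pam: PamSpec,
    window: EditingWindow = EditingWindow(),
    first_fraction: float = 0.75,
    *,
    anchor: Literal["stop", "protospacer"] = "stop",
    single_only: bool = False,
    sites: Iterable[PamSite] | None = None,
) -> list[ProtospacerHit]:
    """Find all (protospacer site, CDS) pairs that can acquire a premature stop.

    A pair is reported when at least one non-empty subset of the protospacer's
    window cytosines, edited C->T on the protospacer strand, creates a stop
    codon lying wholly within the CDS, and the position filter holds:
    with ``anchor="stop"`` the first base of the stop codon must fall within
    the first ``first_fraction`` of the CDS; with ``anchor="protospacer"`` the
    protospacer's 5'-most in-CDS coding position is used instead. With
    ``single_only=True`` only single-cytosine subsets qualify.
    """
    if not (0 < first_fraction <= 1):
        raise ValueError("first_fraction must be in (0, 1]")
    window.validate_for(pam.spacer_length)
    index = _CdsIndex(genome)
    if not index.entries:
        warnings.warn("genome has no non-pseudo CDS; no knockouts designed")
        return []
    if sites is None:
        sites = scan_pam_sites(genome, pam)
    n = len(genome)
    seq = genome.sequence
    hits: list[ProtospacerHit] = []

    for site in sites:
        # window offsets carrying C on the protospacer strand
        c_fwd: list[tuple[int, int]] = []  # (offset, forward position)
        for o in window.offsets():
            g = site.offset_to_fwd(o, n)
            base = seq[g]
            if (site.strand == "+" and base == "C") or (site.strand == "-" and base == "G"):
                c_fwd.append((o, g))
        if not c_fwd:
            continue
        window_c_offsets = tuple(o for o, _ in c_fwd)

        # candidate CDSs: those containing at least one window C
        cands: dict[str, tuple[int, int, CdsRecord]] = {}
        for _, g in c_fwd:
            for s0, e0, rec in index.covering(g):
                cands[rec.id] = (s0, e0, rec)

        for s0, e0, rec in cands.values():
            orientation = "sense" if site.strand == rec.strand else "antisense"
            edited_base = "T" if orientation == "sense" else "A"
            edit_map = {}
            for o, g in c_fwd:
                gu = g if s0 <= g < e0 else g + n
                if s0 <= gu < e0:
                    edit_map[o] = (
                        _coding_position(g, s0, e0, rec.strand, n), edited_base
                    )
            if not edit_map:
                continue
            edits = _enumerate_edit_subsets(
                [o for o, _ in c_fwd], edit_map, rec.coding_sequence,
                single_only=single_only,
            )
            if not edits:
                continue
            cds_len = len(rec.coding_sequence)
            limit = int(first_fraction * cds_len)
            if anchor == "stop":
                kept = [e for e in edits if e.codon_index * 3 + 1 <= limit]
            else:
                proto_cps = [cp for cp, _ in edit_map.values()]
                anchor_cp = min(proto_cps)
                kept = edits if anchor_cp + 1 <= limit else []
            if not kept:
                continue
            frac = (min(e.codon_index for e in kept) * 3 + 1) / cds_len
            proto_end0 = site.proto_start0 + site.spacer_length
            hit = ProtospacerHit(
                genome_id=genome.id,
                cds_id=rec.id,
                protospacer_seq=site.protospacer_seq(genome),
                pam_seq=site.pam_seq(genome),
                genome_start=site.proto_start0 + 1,
                genome_end=(proto_end0 - 1) % n + 1,
                protospacer_strand=site.strand,
                orientation=orientation,
                window_c_offsets=window_c_offsets,
                stop_edits=tuple(kept),
                cds_fraction=frac,
            )
            hits.append(
                ProtospacerHit(**{**hit.__dict__, "quality": classify_hit(hit, window)})
            )
    hits.sort(
        key=lambda h: (h.genome_start, 0 if h.protospacer_strand == "+" else 1, h.cds_id)
    )
    return hits
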
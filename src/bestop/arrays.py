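"""Multiplex sgRNA expression-cassette assembly and pre-tRNA screening.

Three cassette architectures are supported:

* ``msgRNA`` — one full transcriptional unit (promoter, spacer, scaffold,
  terminator) per guide;
* ``mCRISPR`` — a native-style CRISPR array (one promoter, direct repeats
  alternating with spacers, one terminator) plus a separate tracrRNA unit;
* ``mtRNA``  — a single transcriptional unit of sgRNA-tRNA fusions, relying on
  host tRNA maturation (RNase P / RNase Z cleavage) to release the guides.

The pre-tRNA screen applies sequence-level selection criteria: no poly-U run
in the 20-nt 3' trailer (a premature terminator), a weak A/U-rich stem-loop
near the CCA end of the mature tRNA (found by base-pair maximization, a
deliberate sequence-level stand-in for thermodynamic folding with a hook to
plug in an external folder), and a decoded codon in high usage so the host
tRNA pool is not unbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._seq import validate_dna
from .genome import CodonUsageTable

__all__ = [
    "PreTrnaCandidate",
    "StemCandidate",
    "TrnaReport",
    "ArrayPart",
    "ArrayConstruct",
    "default_parts",
    "load_parts_fasta",
    "evaluate_pre_trna",
    "rank_candidates",
    "build_array",
    "write_construct",
]

# ---------------------------------------------------------------------------
# pre-tRNA screening


@dataclass(frozen=True)
class PreTrnaCandidate:
    """A mature tRNA plus the first 20 nt of its genomic 3' trailer."""

    name: str
    mature_seq: str
    trailer_seq: str
    anticodon: str
    decoded_codon: str

    def __post_init__(self) -> None:
        for attr in ("mature_seq", "trailer_seq", "anticodon", "decoded_codon"):
            object.__setattr__(self, attr,
                               validate_dna(getattr(self, attr).replace("U", "T"),
                                            what=attr))
        if len(self.trailer_seq) != 20:
            raise ValueError("trailer must be the 20 nt 3' extension")


@dataclass(frozen=True)
class StemCandidate:
    position_from_cca: int   # nt from the CCA 3' end to the first stem base
    stem_length: int
    loop_length: int
    au_fraction: float       # A/U content of the stem bases


@dataclass
class TrnaReport:
    name: str
    has_polyU_trailer: bool
    has_cca_end: bool
    stem_candidates: list[StemCandidate]
    codon_usage_rank: int
    pass_flags: dict[str, bool]


def _pairs(a: str, b: str, wobble: bool = True) -> bool:
    if {a, b} in ({"A", "T"}, {"C", "G"}):
        return True
    return wobble and {a, b} == {"G", "T"}


def _hairpin_scan(seq: str, min_stem: int = 4, loop_range: tuple[int, int] = (3, 8),
                  wobble: bool = True) -> list[tuple[int, int, int]]:
    """Maximal perfect hairpins (start, stem_len, loop_len) by pair maximization."""
    found = []
    n = len(seq)
    for loop in range(loop_range[0], loop_range[1] + 1):
        for i in range(n):
            # grow the stem outwards around seq[i : i+loop]
            s = 0
            while (i - s - 1 >= 0 and i + loop + s < n
                   and _pairs(seq[i - s - 1], seq[i + loop + s], wobble)):
                s += 1
            if s >= min_stem:
                found.append((i - s, s, loop))
    # drop hairpins strictly contained in a longer one with the same loop centre
    maximal = []
    for h in found:
        start, s, loop = h
        contained = any(
            (o_start <= start and start + 2 * s + loop <= o_start + 2 * o_s + o_loop
             and (o_s, o_loop) != (s, loop) and o_s >= s)
            for o_start, o_s, o_loop in found if (o_start, o_s, o_loop) != h
        )
        if not contained:
            maximal.append(h)
    return sorted(set(maximal))


def evaluate_pre_trna(
    candidate: PreTrnaCandidate,
    usage: CodonUsageTable,
    *,
    polyu_run: int = 4,
    cca_window: tuple[int, int] = (10, 22),
    min_stem: int = 4,
    loop_range: tuple[int, int] = (3, 8),
    au_threshold: float = 0.75,
    max_rank: int = 32,
    fold_hook: Callable[[str], list[StemCandidate]] | None = None,
) -> TrnaReport:
    """Screen a pre-tRNA against the array-compatibility criteria.

    A candidate passes when its trailer has no run of ``polyu_run`` or more
    T/U (which would terminate transcription mid-array), it carries a weak
    (A/U-rich) stem-loop whose span overlaps the ``cca_window`` interval
    downstream of the mature CCA end, and its decoded codon ranks within the
    top ``max_rank`` codons of the genome's usage table. ``fold_hook``
    replaces the built-in hairpin scan with an external folding engine.
    """
    trailer = candidate.trailer_seq
    has_polyu = "T" * polyu_run in trailer
    has_cca = candidate.mature_seq.endswith("CCA")
    if not has_cca:
        warnings.warn(f"{candidate.name}: mature sequence lacks a CCA 3' end; "
                      "distance criteria skipped")

    region = candidate.mature_seq[-20:] + trailer
    cca_end = len(candidate.mature_seq[-20:])  # index of the first trailer base
    if fold_hook is not None:
        stems = fold_hook(region)
    else:
        stems = []
        for start, s, loop in _hairpin_scan(region, min_stem, loop_range):
            span_from = start - cca_end
            span_to = start + 2 * s + loop - 1 - cca_end
            if has_cca and not (span_from <= cca_window[1] and span_to >= cca_window[0]):
                continue
            stem_bases = region[start:start + s] + region[start + s + loop:
                                                          start + 2 * s + loop]
            au = sum(b in "AT" for b in stem_bases) / len(stem_bases)
            stems.append(StemCandidate(span_from, s, loop, au))

    rank = usage.rank(candidate.decoded_codon)
    flags = {
        "no_polyU_trailer": not has_polyu,
        "weak_au_stem_near_cca": any(st.au_fraction >= au_threshold for st in stems),
        "codon_in_high_usage": rank <= max_rank,
    }
    return TrnaReport(candidate.name, has_polyu, has_cca, stems, rank, flags)


def rank_candidates(
    candidates: Sequence[PreTrnaCandidate],
    usage: CodonUsageTable,
    **kwargs,
) -> list[tuple[PreTrnaCandidate, TrnaReport]]:
    """Order candidates best-first: most criteria passed, then codon rank."""
    scored = []
    for cand in candidates:
        rep = evaluate_pre_trna(cand, usage, **kwargs)
        scored.append((cand, rep))
    scored.sort(key=lambda cr: (-sum(cr[1].pass_flags.values()),
                                cr[1].codon_usage_rank, cr[0].name))
    return scored


# ---------------------------------------------------------------------------
# cassette assembly


@dataclass(frozen=True)
class ArrayPart:
    name: str
    role: str       # promoter | spacer | scaffold | terminator | dr | trna | tracr
    sequence: str


@dataclass
class ArrayConstruct:
    strategy: str
    parts: list[ArrayPart]
    assembled_seq: str = field(init=False)

    def __post_init__(self) -> None:
        self.assembled_seq = "".join(p.sequence for p in self.parts)

    def __len__(self) -> int:
        return len(self.assembled_seq)


# Placeholder registry: roles and lengths are realistic, the exact promoter/
# terminator/tRNA sequences are construct-specific and editable by the user.
_SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)
_SP_DR = "GTTTTAGAGCTATGCTGTTTTGAATGGTCCCAAAAC"


def default_parts() -> dict[str, ArrayPart]:
    parts = [
        ArrayPart("promoter", "promoter",
                  "TTGACAATTAATCATCGGCTCGTATAATGTGTGGAATTGTGAGCGGATAACAATT"),
        ArrayPart("scaffold", "scaffold", _SGRNA_SCAFFOLD),
        ArrayPart("terminator", "terminator",
                  "AAAAAAGCCCGCTCATTAGGCGGGCTTTTTTTT"),
        ArrayPart("dr", "dr", _SP_DR),
        ArrayPart("tracr", "tracr",
                  "GGAACCATTCAAAACAGCATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTG"
                  "GCACCGAGTCGGTGCTTTTTTT"),
        ArrayPart("trna_thr", "trna",
                  "GGCGCCGTGGCTTAGCTGGTTAAAGCGCCTGTCTTGTAAACAGGAGATCGCGGGTTCGATTCCC"
                  "GTCGGCGCCACCA"),
        ArrayPart("trna_fmet", "trna",
                  "CGCGGGGTGGAGCAGCCTGGTAGCTCGTCGGGCTCATAACCCGAAGGTCGTCGGTTCAAATCCG"
                  "GCCCCCGCAACCA"),
    ]
    return {p.name: p for p in parts}


def load_parts_fasta(path: str) -> dict[str, ArrayPart]:
    """Read a parts registry from FASTA; the role is the second header token."""
    from Bio import SeqIO

    parts = {}
    for rec in SeqIO.parse(path, "fasta"):
        tokens = rec.description.split()
        role = tokens[1] if len(tokens) > 1 else "misc"
        parts[rec.id] = ArrayPart(rec.id, role, str(rec.seq).upper())
    return parts


def build_array(
    spacers: Sequence[str],
    strategy: str,
    parts: dict[str, ArrayPart] | None = None,
    seed: int = 0,
    *,
    trnas: Sequence[str] | None = None,
    terminal_trna: bool = False,
    mcrispr_mode: str = "legacy",
    restriction_site: str = "GGTCTC",
) -> ArrayConstruct:
    """Assemble a multiplex guide-expression cassette.

    ``msgRNA`` repeats (promoter, spacer, scaffold, terminator) per guide.
    ``mtRNA`` is promoter + sgRNA units joined by tRNAs (one per junction,
    optionally one terminal tRNA) + terminator. ``mCRISPR`` is promoter +
    (DR, 30-nt spacer)... + DR + terminator, followed by a separate tracrRNA
    unit; in ``legacy`` mode each 30-nt spacer is a 6-nt restriction site +
    4 seeded-random nt + the 20-nt spacer (the published design), in
    ``recommended`` mode the caller supplies 30-nt fully target-homologous
    spacers.
    """
    if not spacers:
        raise ValueError("at least one spacer required")
    spacers = [validate_dna(s, allow_n=False, what="spacer") for s in spacers]
    registry = dict(default_parts()) if parts is None else dict(parts)

    def part(name: str) -> ArrayPart:
        try:
            return registry[name]
        except KeyError:
            raise KeyError(f"part {name!r} missing from the registry") from None

    out: list[ArrayPart] = []
    if strategy == "msgRNA":
        for i, sp in enumerate(spacers, 1):
            out += [part("promoter"),
                    ArrayPart(f"spacer_{i}", "spacer", sp),
                    part("scaffold"), part("terminator")]
    elif strategy == "mtRNA":
        n_junctions = len(spacers) - 1 + (1 if terminal_trna else 0)
        if trnas is None:
            trnas = [p.name for p in registry.values() if p.role == "trna"]
        if len(trnas) < n_junctions:
            raise ValueError(
                f"mtRNA array needs {n_junctions} tRNA(s), got {len(trnas)}"
            )
        out.append(part("promoter"))
        for i, sp in enumerate(spacers):
            out += [ArrayPart(f"spacer_{i + 1}", "spacer", sp), part("scaffold")]
            if i < len(spacers) - 1 or terminal_trna:
                out.append(part(trnas[i]))
        out.append(part("terminator"))
    elif strategy == "mCRISPR":
        rng = np.random.RandomState(seed)
        out.append(part("promoter"))
        for i, sp in enumerate(spacers, 1):
            out.append(part("dr"))
            if mcrispr_mode == "legacy":
                if len(sp) != 20:
                    raise ValueError("legacy mCRISPR mode expects 20-nt spacers")
                pad = "".join("ACGT"[j] for j in rng.randint(0, 4, size=4))
                sp30 = restriction_site + pad + sp
            elif mcrispr_mode == "recommended":
                if len(sp) != 30:
                    raise ValueError(
                        "recommended mCRISPR mode expects 30-nt target-homologous spacers"
                    )
                sp30 = sp
            else:
                raise ValueError(f"unknown mcrispr_mode {mcrispr_mode!r}")
            out.append(ArrayPart(f"spacer30_{i}", "spacer", sp30))
        out += [part("dr"), part("terminator"),
                part("promoter"), part("tracr"), part("terminator")]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ArrayConstruct(strategy, out)


def write_construct(construct: ArrayConstruct, path: str, format: str = "genbank") -> None:
    """Write an assembled cassette as an annotated GenBank record or FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(construct.assembled_seq), id="array",
                       description=f"{construct.strategy} cassette",
                       annotations={"molecule_type": "DNA"})
    pos = 0
    for p in construct.parts:
        record.features.append(SeqFeature(
            FeatureLocation(pos, pos + len(p.sequence)), type="misc_feature",
            qualifiers={"label": [p.name], "note": [p.role]},
        ))
        pos += len(p.sequence)
    from Bio import SeqIO

    SeqIO.write(record, path, "genbank" if format == "genbank" else "fasta")
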
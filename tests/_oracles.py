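"""Independent brute-force oracles used to validate the vectorized scanners.

Everything here is deliberately naive: character-by-character matching,
explicit enumeration of edit subsets and gap placements, and whole-genome
string substitution followed by re-extraction of every CDS. None of it shares
code paths with the package's scanners beyond trivial helpers.
"""

from __future__ import annotations

from itertools import combinations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def char_match(pattern: str, text: str) -> bool:
    return len(pattern) == len(text) and all(
        t != "N" and t in IUPAC[p] for p, t in zip(pattern, text)
    )


def _strand_string(genome, strand: str, pad: int) -> str:
    seq = genome.sequence if strand == "+" else rc(genome.sequence)
    return seq + seq[:pad] if genome.circular else seq


def brute_pam_sites(genome, pattern: str, spacer_len: int = 20):
    """Set of (fwd 0-based protospacer start, strand) by naive matching."""
    n = len(genome.sequence)
    k = len(pattern)
    out = set()
    for strand in "+-":
        s = _strand_string(genome, strand, k - 1)
        lo = 0 if genome.circular else spacer_len
        hi = n if genome.circular else n - k + 1
        for p in range(lo, hi):
            if char_match(pattern, s[p:p + k]):
                if strand == "+":
                    out.add(((p - spacer_len) % n, "+"))
                else:
                    out.add(((n - p) % n, "-"))
    return out


def _extract_coding(seq: str, rec, n: int) -> str:
    s0 = rec.start - 1
    e0 = s0 + len(rec.coding_sequence)
    if e0 <= n:
        raw = seq[s0:e0]
    else:
        raw = seq[s0:] + seq[:e0 - n]
    return raw if rec.strand == "+" else rc(raw)


def brute_design(genome, pam_pattern: str, spacer_len: int = 20,
                 window=(-19, -16), first_fraction: float = 0.75,
                 single_only: bool = False):
    """Set of (1-based protospacer start, strand, cds_id) by direct substitution.

    For every PAM occurrence on either strand, every non-empty subset of
    window cytosines is applied to a copy of the genome; every CDS overlapping
    an edited base is re-extracted and scanned codon-by-codon for a stop that
    was not there before and starts within the first fraction of the CDS.
    """
    n = len(genome.sequence)
    k = len(pam_pattern)
    recs = [f for f in genome.features if not f.pseudo_flag]
    out = set()
    for strand in "+-":
        s = _strand_string(genome, strand, spacer_len + k)
        lo = 0 if genome.circular else spacer_len
        hi = n if genome.circular else n - k + 1
        for p in range(lo, hi):
            if not char_match(pam_pattern, s[p:p + k]):
                continue
            proto = s[p - spacer_len:p] if p >= spacer_len else \
                s[p - spacer_len + n:n] + s[:p] if genome.circular else None
            if proto is None or len(proto) < spacer_len:
                continue
            c_idx = [i for i in range(spacer_len + window[0], spacer_len + window[1] + 1)
                     if proto[i] == "C"]
            if not c_idx:
                continue
            max_size = 1 if single_only else len(c_idx)
            qualified = set()
            for size in range(1, max_size + 1):
                for subset in combinations(c_idx, size):
                    edited = list(genome.sequence)
                    touched = []
                    for i in subset:
                        sp = (p - spacer_len + i) % n  # strand coordinate
                        if strand == "+":
                            g = sp
                            edited[g] = "T"
                        else:
                            g = n - 1 - sp
                            edited[g] = "A"
                        touched.append(g)
                    eseq = "".join(edited)
                    for rec in recs:
                        s0 = rec.start - 1
                        e0 = s0 + len(rec.coding_sequence)
                        inside = any(s0 <= g < e0 or s0 <= g + n < e0
                                     for g in touched)
                        if not inside:
                            continue
                        wt = rec.coding_sequence
                        mut = _extract_coding(eseq, rec, n)
                        limit = int(first_fraction * len(wt))
                        for ci in range(len(wt) // 3):
                            wt_c = wt[3 * ci:3 * ci + 3]
                            mu_c = mut[3 * ci:3 * ci + 3]
                            if mu_c in STOPS and wt_c not in STOPS \
                                    and ci * 3 + 1 <= limit:
                                qualified.add(rec.id)
            for cds_id in qualified:
                if strand == "+":
                    start1 = (p - spacer_len) % n + 1
                else:
                    start1 = (n - p) % n + 1
                out.add((start1, strand, cds_id))
    return out


def brute_offtargets(genome, spacer: str, pam_pattern: str,
                     max_mm: int, max_dna: int, max_rna: int):
    """Best alignment per (1-based fwd position, strand) by explicit gap enumeration.

    Returns {(pos, strand): (mismatches, bulge_type, bulge_size)} keeping, per
    locus, the fewest mismatches, then the smallest bulge, then
    none < RNA < DNA.
    """
    n = len(genome.sequence)
    L = len(spacer)
    k = len(pam_pattern)
    rank = {"none": 0, "RNA": 1, "DNA": 2}
    configs = [("none", 0, 0)]
    for b in range(1, max_rna + 1):
        for i in range(1, L - b):
            configs.append(("RNA", b, i))
    for b in range(1, max_dna + 1):
        for i in range(1, L):
            configs.append(("DNA", b, i))
    best: dict = {}
    for strand in "+-":
        s = _strand_string(genome, strand, L + max_dna + k)
        hi = n if genome.circular else n + 1
        for btype, b, i in configs:
            tl = L + (b if btype == "DNA" else -b if btype == "RNA" else 0)
            stop = hi if genome.circular else n - tl - k + 1
            for p in range(max(stop, 0)):
                target = s[p:p + tl]
                if not char_match(pam_pattern, s[p + tl:p + tl + k]):
                    continue
                if btype == "RNA":
                    q = spacer[:i] + spacer[i + b:]
                    t = target
                elif btype == "DNA":
                    q = spacer
                    t = target[:i] + target[i + b:]
                else:
                    q, t = spacer, target
                mm = sum(a != c or c == "N" for a, c in zip(q, t))
                if mm > max_mm:
                    continue
                if strand == "+":
                    pos = p % n + 1
                else:
                    pos = (n - p - tl) % n + 1
                key = (pos, strand)
                cand = (mm, b, rank[btype], btype)
                if key not in best or cand[:3] < best[key][:3]:
                    best[key] = cand
    return {key: (mm, btype, b) for key, (mm, b, _, btype) in best.items()}


def brute_rna_bulge_patterns(spacer: str, bulge: int):
    """Distinct patterns from deleting one interior run of ``bulge`` bases."""
    L = len(spacer)
    return {spacer[:i] + spacer[i + bulge:] for i in range(1, L - bulge)}


def smith_waterman_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Plain O(len(a)*len(b)) local-alignment DP, linear gap penalty."""
    rows, cols = len(a) + 1, len(b) + 1
    prev = [0.0] * cols
    best = 0.0
    for i in range(1, rows):
        cur = [0.0] * cols
        for j in range(1, cols):
            sub = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(0.0, sub, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best


def brute_codon_tally(cds_seqs):
    counts: dict[str, int] = {}
    for seq in cds_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            c = seq[i:i + 3]
            if "N" not in c:
                counts[c] = counts.get(c, 0) + 1
    return counts
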
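"""Reference-genome inputs for the full-scale acceptance checks.

The published *C. autoethanogenum* chromosome (GenBank CP012395.1, ~4.6 Mb)
is not redistributed with the package; place the GenBank flat file at
``data/reference/CP012395.1.gb`` (repo root) to run the full-genome checks.

The six protospacers targeted in the sequenced triple-mutant strain are
published inputs: the first three were used with the NGG editor, the last
three with the NG editor.
"""

from pathlib import Path

REFERENCE_PATH = Path(__file__).resolve().parent.parent / "data" / "reference" / "CP012395.1.gb"

# (label, spacer 5'->3', PAM pattern of the editor that used it)
CFS05_SPACERS = [
    ("CLAU532A", "CTCCAGTCAGGTGTTGTGCA", "NGG"),
    ("CLAU534A", "AGCCCAATGTCTAGCTGGGA", "NGG"),
    ("CLAU1794A", "AAACAAGCAATTGTTCCGTT", "NGG"),
    ("CLAU1794D", "AGACAAAAAGCTAAATTTGT", "NG"),
    ("CLAU1794F", "TCACAATGTTTAGCAGGTAT", "NG"),
    ("CLAU1794G", "GCCATACAGCTCCTGTTTTA", "NG"),
]


def load_reference_genome():
    from bestop.genome import read_genome

    if not REFERENCE_PATH.exists():
        raise FileNotFoundError(
            f"reference genome not available: place the CP012395.1 GenBank "
            f"flat file at {REFERENCE_PATH} to run the full-genome checks"
        )
    return read_genome(str(REFERENCE_PATH), "genbank")
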
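"""Sequence-level analysis of transcription-scaffold oligonucleotides.

An elongation-complex scaffold consists of a template DNA strand (t-strand),
a non-template strand (nt-strand) and a nascent RNA.  This module measures
three design features directly from the sequences: the RNA:t-strand hybrid
anchored at the RNA 3' end, the duplex/bubble segmentation of the two DNA
strands under a fixed antiparallel register (no indels — scaffold oligos are
designed register-aligned), and the upstream duplex length.

Pairing rules are strict Watson-Crick: A·T, G·C for DNA/DNA and A·U(T),
G·C for RNA/DNA; G·U wobble pairs are not counted.

The module ships the E. coli Mfd-EC scaffold oligos (64-nt strands with a
non-complementary bubble, a 20-mer RNA giving a nine-base-pair
post-translocated hybrid, and ~40 bp of upstream duplex) as constants for
worked examples and tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

__all__ = [
    "ScaffoldAnnotation",
    "Segment",
    "hybrid_length",
    "duplex_segmentation",
    "annotate_scaffold",
    "scaffold_report",
    "MFD_EC_SCAFFOLD",
    "AlphabetError",
]

DNA_ALPHABET = set("ACGT")
RNA_ALPHABET = set("ACGU")
_DNA_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
# DNA template base -> RNA base it pairs with
_DNA_TO_RNA_PARTNER = {"A": "U", "T": "A", "G": "C", "C": "G"}

# The Mfd-EC nucleic-acid scaffold (nt-strand/t-strand 5'->3', RNA 5'->3').
MFD_EC_SCAFFOLD = {
    "nt_strand": "CCCAACGGCACCGCTGCAAGGAATAGGATACTTGCGGGCTAGGCTCTTATGGCGGCGAATACCC",
    "t_strand": "GGGTATTCGCCGCGTACCTCTCCTAGCCCGCAAGTATCCTATTCCTTGCAGCGGTGCCGTTGGG",
    "rna": "GCAUUCAAAGCGGAGAGGUA",
}


class AlphabetError(ValueError):
    pass


def _check_alphabet(seq: str, alphabet: set[str], what: str) -> str:
    s = seq.upper()
    bad = set(s) - alphabet
    if not s:
        raise AlphabetError(f"empty {what} sequence")
    if bad:
        raise AlphabetError(f"{what} sequence contains invalid characters: {sorted(bad)}")
    return s


@dataclass
class Segment:
    kind: str  # "duplex" | "bubble"
    length: int
    start: int  # 1-based, top-strand coordinates
    end: int  # inclusive


@dataclass
class ScaffoldAnnotation:
    rna: str
    t_strand: str
    nt_strand: str
    hybrid_length: int
    hybrid_register: tuple[int, int]  # 1-based on the t-strand 5'->3' string
    segments: list[Segment]
    upstream_duplex_length: int
    overhangs: tuple[int, int] = (0, 0)  # unaligned top / bottom tail lengths
    hybrid_ties: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldAnnotation":
        d = json.loads(text)
        d["segments"] = [Segment(**s) for s in d["segments"]]
        d["hybrid_register"] = tuple(d["hybrid_register"])
        d["overhangs"] = tuple(d["overhangs"])
        d["hybrid_ties"] = [tuple(t) for t in d["hybrid_ties"]]
        return cls(**d)


def hybrid_length(rna: str, t_strand: str) -> tuple[int, tuple[int, int], list[tuple[int, int]]]:
    """Longest contiguous Watson-Crick run pairing the RNA 3' terminus
    against the t-strand (antiparallel), scanned over every t-strand offset.

    Returns (length, (start, end) register on the t-strand 5'->3' string,
    list of tying registers).  Length 0 means the RNA 3' base pairs nowhere.
    """
    rna = _check_alphabet(rna, RNA_ALPHABET, "RNA")
    t = _check_alphabet(t_strand, DNA_ALPHABET, "t-strand")
    best = 0
    best_reg = (0, 0)
    ties: list[tuple[int, int]] = []
    for j in range(len(t)):
        k = 0
        # RNA 3'->5' walks along the t-strand 5'->3'
        while k < len(rna) and j + k < len(t) and _DNA_TO_RNA_PARTNER[t[j + k]] == rna[len(rna) - 1 - k]:
            k += 1
        if k == 0:
            continue
        reg = (j + 1, j + k)
        if k > best:
            best, best_reg, ties = k, reg, []
        elif k == best:
            ties.append(reg)
    return best, best_reg, ties


def duplex_segmentation(
    top: str,
    bottom: str,
    min_duplex_run: int = 2,
    upstream: str = "left",
) -> tuple[list[Segment], int, tuple[int, int]]:
    """Segment two DNA strands into duplex/bubble runs at a fixed
    antiparallel register: top[i] pairs bottom[n−1−i] (0-based), no indels.

    Matching runs shorter than ``min_duplex_run`` inside a bubble are
    absorbed into the bubble (scaffold bubbles often contain isolated
    complementary positions by chance).  Unequal strand lengths leave a
    reported overhang on the longer strand's tail; the aligned region is the
    shorter length.  ``upstream`` names the top-strand side ("left"/"right")
    whose flanking duplex counts as the upstream duplex.
    """
    top = _check_alphabet(top, DNA_ALPHABET, "top-strand")
    bottom = _check_alphabet(bottom, DNA_ALPHABET, "bottom-strand")
    if upstream not in ("left", "right"):
        raise ValueError("upstream must be 'left' or 'right'")
    m = min(len(top), len(bottom))
    overhangs = (len(top) - m, len(bottom) - m)
    match = [
        _DNA_COMP[top[i]] == bottom[len(bottom) - 1 - i] for i in range(m)
    ]
    # absorb short match runs into surrounding mismatch context
    absorbed = list(match)
    i = 0
    while i < m:
        if absorbed[i]:
            j = i
            while j < m and absorbed[j]:
                j += 1
            run = j - i
            interior = i > 0 and j < m  # flanked by mismatches on both sides
            if run < min_duplex_run and interior:
                for k in range(i, j):
                    absorbed[k] = False
            i = j
        else:
            i += 1
    segments: list[Segment] = []
    i = 0
    while i < m:
        j = i
        while j < m and absorbed[j] == absorbed[i]:
            j += 1
        segments.append(
            Segment(
                kind="duplex" if absorbed[i] else "bubble",
                length=j - i,
                start=i + 1,
                end=j,
            )
        )
        i = j
    if upstream == "left":
        upstream_len = segments[0].length if segments and segments[0].kind == "duplex" else 0
    else:
        upstream_len = segments[-1].length if segments and segments[-1].kind == "duplex" else 0
    return segments, upstream_len, overhangs


def annotate_scaffold(
    rna: str,
    t_strand: str,
    nt_strand: str,
    min_duplex_run: int = 2,
    upstream: str = "left",
) -> ScaffoldAnnotation:
    """Full sequence-level annotation of one scaffold."""
    hlen, hreg, ties = hybrid_length(rna, t_strand)
    segments, upstream_len, overhangs = duplex_segmentation(
        nt_strand, t_strand, min_duplex_run=min_duplex_run, upstream=upstream
    )
    return ScaffoldAnnotation(
        rna=rna.upper(),
        t_strand=t_strand.upper(),
        nt_strand=nt_strand.upper(),
        hybrid_length=hlen,
        hybrid_register=hreg,
        segments=segments,
        upstream_duplex_length=upstream_len,
        overhangs=overhangs,
        hybrid_ties=ties,
    )


def scaffold_report(annotation: ScaffoldAnnotation) -> str:
    """Deterministic human-readable rendering, including a diagram line
    marking duplex (=), bubble (.) and the hybrid span (h) in top-strand
    coordinates."""
    ann = annotation
    n = len(ann.nt_strand)
    diagram = []
    for seg in ann.segments:
        diagram.append(("=" if seg.kind == "duplex" else ".") * seg.length)
    diagram = list("".join(diagram).ljust(min(n, len(ann.t_strand))))
    # map hybrid register (t-strand coords, 5'->3') into top-strand coords
    h_start, h_end = ann.hybrid_register
    if ann.hybrid_length > 0:
        Lb = len(ann.t_strand)
        for t_pos in range(h_start, h_end + 1):
            top_pos = Lb - t_pos  # 0-based top coordinate
            if 0 <= top_pos < len(diagram):
                diagram[top_pos] = "h"
    lines = [
        "scaffold annotation",
        f"  nt 5'-{ann.nt_strand}-3'",
        f"        {''.join(diagram)}",
        f"  t  3'-{ann.t_strand[::-1]}-5'",
        f"  rna 5'-{ann.rna}-3'",
        f"  hybrid: {ann.hybrid_length} bp at t-strand {h_start}-{h_end}"
        + (f" (ties: {ann.hybrid_ties})" if ann.hybrid_ties else ""),
        "  segments: "
        + ", ".join(f"{s.kind}({s.length}) @{s.start}-{s.end}" for s in ann.segments),
        f"  upstream duplex: {ann.upstream_duplex_length} bp",
    ]
    if any(ann.overhangs):
        lines.append(f"  overhangs (top, bottom): {ann.overhangs}")
    return "\n".join(lines)
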
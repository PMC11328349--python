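"""Small shared sequence utilities: IUPAC matching, encoding, FASTA/BED I/O.

A genome is represented as a plain ``dict`` of contig name -> uppercase
nucleotide string (A/C/G/T/N).  FASTA parsing goes through Biopython.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte codes used by the vectorised scanners
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
# N stays 255: never equal to any encoded base (N never matches a guide base)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, N/other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def validate_pattern(pattern: str) -> None:
    bad = set(pattern.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC symbol(s) {sorted(bad)!r} in pattern {pattern!r}")


def pattern_mask(encoded: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean mask over positions where ``pattern`` matches the encoded sequence.

    Genomic N matches only the pattern letter N (which accepts anything);
    it never satisfies a concrete IUPAC letter.
    """
    validate_pattern(pattern)
    pattern = pattern.upper()
    k = len(pattern)
    n = encoded.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for j, sym in enumerate(pattern):
        if sym == "N":
            continue
        col = encoded[j : j + n]
        allowed = np.zeros(256, dtype=bool)
        for base in IUPAC[sym]:
            allowed["ACGT".index(base)] = True
        mask &= allowed[col]
    return mask


def matches_pattern(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    for b, sym in zip(seq.upper(), pattern.upper()):
        if sym == "N":
            continue
        if b not in IUPAC[sym]:
            return False
    return True


def validate_genome(genome: dict[str, str]) -> dict[str, str]:
    """Uppercase and validate a contig dict (ACGTN only, non-empty)."""
    out: dict[str, str] = {}
    for name, seq in genome.items():
        if not seq:
            raise ValueError(f"contig {name!r} is empty")
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {name!r} contains non-ACGTN symbol(s) {sorted(bad)!r}")
        out[name] = seq
    return out


def read_fasta(path) -> dict[str, str]:
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return validate_genome(genome)


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Parse a BED3+ file (0-based half-open). Malformed lines raise with context."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r} (need >=3 columns)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r} ({exc})") from None
            if end < start:
                raise ValueError(f"malformed BED line {lineno}: end < start")
            intervals.append((fields[0], start, end))
    return intervals
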
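"""Candidate off-target enumeration and barcoded oligo panel construction.

For an in-vitro cleavage assay the candidate set is deliberately permissive:
every genomic window matching the guide with up to 8 mismatches and no bulge,
or up to 5 mismatches plus one DNA or RNA bulge of size 1 or 2, on either
strand, with no PAM restriction (the PAM is recorded verbatim; the assay
interrogates PAM tolerance empirically).

Conventions: a *DNA bulge* is extra genomic base(s) unpaired against the
guide; an *RNA bulge* is guide base(s) unpaired (a genomic deletion relative
to the guide).  Protospacer coordinates are 1..23 with base 1 PAM-proximal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_scan import PAM_LEN, PROTOSPACER_LEN
from .sequence import encode, revcomp, validate_genome


@dataclass(frozen=True)
class BulgeSpec:
    kind: str = "none"  # none | dna | rna
    size: int = 0
    position: int | None = None  # protospacer coordinate after which the bulge sits

    def __post_init__(self):
        if self.kind not in ("none", "dna", "rna"):
            raise ValueError(f"unknown bulge kind {self.kind!r}")
        if (self.kind == "none") != (self.size == 0):
            raise ValueError("bulge kind 'none' iff size 0")


NO_BULGE = BulgeSpec()


@dataclass
class CandidateOffTarget:
    site_id: str
    contig: str
    strand: str
    anchor: int  # strand-local window start: where guide base 1 pairs
    start: int  # 0-based leftmost forward-strand coordinate of the matched window
    window: str  # genomic window in guide (5'->3' strand) orientation
    pam: str  # adjacent 4-mer on the PAM side, verbatim (N-padded at contig edges)
    mismatch_positions: frozenset[int]
    bulge: BulgeSpec

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)

    def aligned_target(self) -> str:
        """Genomic bases paired to guide positions 1..23 ('-' at RNA-bulge gaps).

        DNA-bulge bases (extra genomic bases) are dropped; RNA-bulge guide
        positions show '-'.  The result always has length 23.
        """
        w, b = self.window, self.bulge
        if b.kind == "none":
            return w
        p = b.position
        if b.kind == "dna":
            return w[:p] + w[p + b.size :]
        return w[:p] + "-" * b.size + w[p:]


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _alignment_configs(bulge_sizes) -> list[BulgeSpec]:
    """All bulge configurations, in tie-break preference order.

    Preference: fewer bulge bases first, then (at equal mismatches, applied
    later) leftmost bulge position.
    """
    configs = [NO_BULGE]
    for size in sorted(bulge_sizes):
        for kind in ("dna", "rna"):
            # internal bulges only: both flanks of the duplex must be non-empty
            max_pos = PROTOSPACER_LEN - 1 if kind == "dna" else PROTOSPACER_LEN - size - 1
            for pos in range(1, max_pos + 1):
                configs.append(BulgeSpec(kind, size, pos))
    return configs


def _config_window_len(spec: BulgeSpec) -> int:
    if spec.kind == "dna":
        return PROTOSPACER_LEN + spec.size
    if spec.kind == "rna":
        return PROTOSPACER_LEN - spec.size
    return PROTOSPACER_LEN


def _config_mismatches(enc_strand: np.ndarray, enc_guide: np.ndarray, spec: BulgeSpec) -> np.ndarray:
    """Vectorised mismatch count of the guide under ``spec`` at every window start."""
    wlen = _config_window_len(spec)
    n = enc_strand.size - wlen + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    if spec.kind == "rna":
        p = spec.position
        for j in range(p):
            mm += enc_strand[j : j + n] != enc_guide[j]
        for j in range(p + spec.size, PROTOSPACER_LEN):
            g = j - spec.size
            mm += enc_strand[g : g + n] != enc_guide[j]
    else:
        shift_at = spec.position if spec.kind == "dna" else PROTOSPACER_LEN
        for j in range(PROTOSPACER_LEN):
            g = j if j < shift_at else j + spec.size
            mm += enc_strand[g : g + n] != enc_guide[j]
    return mm


def enumerate_candidates(
    protospacer: str,
    genome: dict[str, str],
    max_mm_nobulge: int = 8,
    max_mm_bulge: int = 5,
    bulge_sizes=(1, 2),
) -> list[CandidateOffTarget]:
    """Enumerate all candidate off-target windows for ``protospacer``.

    Each genomic window — keyed by contig, strand and the strand-local
    position where guide base 1 pairs, so overlapping bulged alignments of
    one duplex merge — is reported once with its preferred alignment: fewest
    bulge bases, then fewest mismatches, then leftmost bulge position.  The
    on-target site itself (0 mismatches) is included; no PAM filtering is
    applied.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
    genome = validate_genome(genome)
    enc_guide = encode(protospacer)
    configs = _alignment_configs(bulge_sizes)

    best: dict[tuple[str, str, int], tuple[tuple[int, int, int], BulgeSpec, int, int]] = {}
    for contig, seq in genome.items():
        length = len(seq)
        for strand in ("+", "-"):
            strand_seq = seq if strand == "+" else revcomp(seq)
            enc = encode(strand_seq)
            for spec in configs:
                limit = max_mm_nobulge if spec.kind == "none" else max_mm_bulge
                mm = _config_mismatches(enc, enc_guide, spec)
                wlen = _config_window_len(spec)
                for s in np.nonzero(mm <= limit)[0]:
                    s = int(s)
                    key = (contig, strand, s)
                    bulge_bases = spec.size
                    pref = (bulge_bases, int(mm[s]), spec.position or 0)
                    if key not in best or pref < best[key][0]:
                        best[key] = (pref, spec, int(mm[s]))

    candidates: list[CandidateOffTarget] = []
    used_ids: dict[str, int] = {}
    for (contig, strand, s), (_, spec, _count) in sorted(best.items()):
        seq = genome[contig]
        length = len(seq)
        strand_seq = seq if strand == "+" else revcomp(seq)
        wlen = _config_window_len(spec)
        fwd_start = s if strand == "+" else length - s - wlen
        window = strand_seq[s : s + wlen]
        pam = ("N" * PAM_LEN + strand_seq)[s : s + PAM_LEN]  # 4-mer 5' of the window
        pos1 = fwd_start + 1 if strand == "+" else fwd_start + wlen
        base_id = f"chr{contig}_{pos1}" + ("" if strand == "+" else "_rc")
        n_seen = used_ids.get(base_id, 0)
        used_ids[base_id] = n_seen + 1
        site_id = base_id if n_seen == 0 else f"{base_id}.{n_seen}"
        mismatches = _mismatch_positions(window, protospacer, spec)
        candidates.append(
            CandidateOffTarget(
                site_id, contig, strand, s, fwd_start, window, pam, frozenset(mismatches), spec
            )
        )
    return candidates


def _mismatch_positions(window: str, protospacer: str, spec: BulgeSpec) -> set[int]:
    aligned = CandidateOffTarget("", "", "+", 0, 0, window, "", frozenset(), spec).aligned_target()
    return {
        j + 1
        for j, (a, g) in enumerate(zip(aligned, protospacer))
        if a != "-" and a != g
    }


# ---------------------------------------------------------------------------
# oligo panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OligoRecord:
    site_id: str
    left_barcode: str
    right_barcode: str
    left_const: str
    right_const: str
    genomic_window: str
    full_sequence: str


def _barcode_pool(barcode_len: int) -> list[str]:
    """All barcodes of the given length with no homopolymer run >=3."""
    pool = []
    for kmer in itertools.product("ACGT", repeat=barcode_len):
        if any(kmer[i] == kmer[i + 1] == kmer[i + 2] for i in range(len(kmer) - 2)):
            continue
        pool.append("".join(kmer))
    return pool


def build_panel(
    candidates: list[CandidateOffTarget],
    genome: dict[str, str],
    barcode_len: int = 8,
    flank_len: int = 20,
    constants: tuple[str, str] = ("ACGCTAGCTAGGTCTC", "GAGACCAGCTTGGCAT"),
    seed: int = 0,
) -> list[OligoRecord]:
    """Build the barcoded synthetic-oligo panel for the candidate sites.

    Each candidate window plus ``flank_len`` of genomic context on each side
    (N-padded at contig ends and right-padded to a common length so
    ``full_sequence`` is constant-length across the panel) is framed by a
    unique barcode pair and constant regions.  Deterministic for a given seed.
    """
    pool = _barcode_pool(barcode_len)
    if len(pool) < 2 * len(candidates):
        need = barcode_len
        while len(_barcode_pool(need)) < 2 * len(candidates):
            need += 1
        raise ValueError(
            f"barcode space exhausted: {len(pool)} usable barcodes of length "
            f"{barcode_len} for {2 * len(candidates)} needed; use barcode_len>={need}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    shuffled = [pool[i] for i in order]

    windows = []
    for cand in candidates:
        seq = genome[cand.contig]
        wlen = len(cand.window)
        lo, hi = cand.start - flank_len, cand.start + wlen + flank_len
        padded = (
            "N" * max(0, -lo)
            + seq[max(0, lo) : min(len(seq), hi)]
            + "N" * max(0, hi - len(seq))
        )
        if cand.strand == "-":
            padded = revcomp(padded)
        windows.append(padded)
    width = max(len(w) for w in windows) if windows else 0

    records = []
    for i, (cand, win) in enumerate(zip(candidates, windows)):
        left_bc, right_bc = shuffled[2 * i], shuffled[2 * i + 1]
        win = win + "N" * (width - len(win))
        full = constants[0] + left_bc + win + right_bc + constants[1]
        records.append(
            OligoRecord(cand.site_id, left_bc, right_bc, constants[0], constants[1], win, full)
        )
    return records


# ---------------------------------------------------------------------------
# tabular / FASTA output
# ---------------------------------------------------------------------------

def candidates_table(candidates: list[CandidateOffTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [c.site_id for c in candidates],
            "contig": [c.contig for c in candidates],
            "start": [c.start for c in candidates],
            "strand": [c.strand for c in candidates],
            "pam": [c.pam for c in candidates],
            "site_sequence": [c.aligned_target() for c in candidates],
            "mismatch_count": [c.mismatch_count for c in candidates],
            "mismatch_positions": [
                ",".join(map(str, sorted(c.mismatch_positions))) for c in candidates
            ],
            "bulge_kind": [c.bulge.kind for c in candidates],
            "bulge_size": [c.bulge.size for c in candidates],
            "bulge_position": [c.bulge.position or 0 for c in candidates],
        }
    )


def barcode_map(records: list[OligoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "barcode_left": [r.left_barcode for r in records],
            "barcode_right": [r.right_barcode for r in records],
        }
    )


def write_panel_fasta(records: list[OligoRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.site_id}\n{r.full_sequence}\n")
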
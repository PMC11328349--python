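"""Genome-wide LbCas12a target-site discovery and crRNA classification.

LbCas12a recognises a 4-nt T-rich PAM (canonically TTTV) 5' of a 23-nt
protospacer.  This module scans both strands of a genome for PAM+protospacer
occurrences, counts design-time off-targets (sites with up to three mismatches
under the relaxed PAM set TTTN/NTTN/TTCA/TTCC), labels guides as *unique*
(exactly one perfect genomic match, zero off-targets) or *promiscuous* (more
than ten off-targets), clusters sites into fixed 1-kb bins and assembles
repeat-spacer crRNA expression cassettes.

Coordinates are 0-based half-open internally; ``locus_id`` and all reports use
1-based forward-strand coordinates (``chr<contig>_<pos1>`` names).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence import (
    encode,
    matches_pattern,
    pattern_mask,
    revcomp,
    validate_genome,
    validate_pattern,
)

PROTOSPACER_LEN = 23
PAM_LEN = 4
DEFAULT_PAM = "TTTV"
DEFAULT_OFFTARGET_PAMS = ("TTTN", "NTTN", "TTCA", "TTCC")
LBCAS12A_REPEAT = "TAATTTCTACTAAGTGTAGAT"
PROMISCUOUS_MIN_OFFTARGETS = 10  # strictly more than this many -> promiscuous


@dataclass(frozen=True)
class TargetSite:
    """One PAM + 23-nt protospacer occurrence on a genome strand.

    ``pam_pos`` is the 0-based leftmost *forward-strand* coordinate of the
    4-nt PAM; ``pos1`` the 1-based forward-strand coordinate of protospacer
    base 1 (the PAM-proximal base).  On the minus strand ``pam_seq`` and
    ``protospacer`` are given in the reading (5'->3') orientation of that
    strand.
    """

    contig: str
    strand: str
    pam_pos: int
    pam_seq: str
    protospacer: str

    @property
    def pos1(self) -> int:
        if self.strand == "+":
            return self.pam_pos + PAM_LEN + 1
        return self.pam_pos  # 0-based pam_pos-1, +1 for 1-based

    @property
    def locus_id(self) -> str:
        return f"chr{self.contig}_{self.pos1}"


@dataclass(frozen=True)
class GuideClassification:
    protospacer: str
    perfect_match_count: int
    offtarget_count: int

    @property
    def label(self) -> str:
        if self.perfect_match_count == 1 and self.offtarget_count == 0:
            return "unique"
        if self.offtarget_count > PROMISCUOUS_MIN_OFFTARGETS:
            return "promiscuous"
        return "neither"


@dataclass
class SiteBin:
    contig: str
    bin_index: int
    member_sites: list[TargetSite] = field(default_factory=list)
    gene_overlap: bool = False

    @property
    def start(self) -> int:
        """0-based half-open genomic interval covered by the bin."""
        return self.bin_index * 1000

    @property
    def end(self) -> int:
        return self.bin_index * 1000 + 1000


# ---------------------------------------------------------------------------
# target-site discovery
# ---------------------------------------------------------------------------

def find_target_sites(genome: dict[str, str], pam_class: str = DEFAULT_PAM) -> list[TargetSite]:
    """Enumerate PAM+23-nt protospacer sites on both strands.

    Sites whose protospacer would run off the contig are omitted.  Output is
    sorted by (contig, pam_pos, strand).
    """
    validate_pattern(pam_class)
    genome = validate_genome(genome)
    sites: list[TargetSite] = []
    for contig in genome:
        seq = genome[contig]
        length = len(seq)
        if length < PAM_LEN + PROTOSPACER_LEN:
            continue
        enc_fwd = encode(seq)
        rc = revcomp(seq)
        enc_rev = encode(rc)
        for strand, enc, src in (("+", enc_fwd, seq), ("-", enc_rev, rc)):
            mask = pattern_mask(enc, pam_class)
            # protospacer must fit: PAM start i needs i+4+23 <= length
            limit = length - PAM_LEN - PROTOSPACER_LEN + 1
            hits = np.nonzero(mask[:limit])[0] if limit > 0 else []
            for i in hits:
                i = int(i)
                pam_seq = src[i : i + PAM_LEN]
                proto = src[i + PAM_LEN : i + PAM_LEN + PROTOSPACER_LEN]
                pam_pos = i if strand == "+" else length - i - PAM_LEN
                sites.append(TargetSite(contig, strand, pam_pos, pam_seq, proto))
    sites.sort(key=lambda s: (s.contig, s.pam_pos, s.strand))
    return sites


def _mismatch_profile(enc_contig: np.ndarray, enc_query: np.ndarray) -> np.ndarray:
    """Mismatch count of the query at every start position (vectorised).

    Genomic N (encoded 255) never equals a query base, so it always counts
    as a mismatch.
    """
    k = enc_query.size
    n = enc_contig.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(k):
        mm += enc_contig[j : j + n] != enc_query[j]
    return mm


def _pam_hit_mask(seq: str, enc: np.ndarray, n_starts: int, patterns) -> np.ndarray:
    """True at protospacer start positions whose upstream 4-mer matches any pattern.

    Starts closer than 4 to the contig edge have no complete PAM and are False.
    """
    any_pam = np.zeros(max(n_starts, 0), dtype=bool)
    for pat in patterns:
        m = pattern_mask(enc, pat)  # mask over PAM start positions
        # protospacer start s has PAM at s-4
        usable = m[: n_starts - PAM_LEN] if n_starts > PAM_LEN else m[:0]
        any_pam[PAM_LEN : PAM_LEN + usable.size] |= usable
    return any_pam


def count_genome_matches(
    protospacer: str,
    genome: dict[str, str],
    max_mm: int = 3,
    offtarget_pams=DEFAULT_OFFTARGET_PAMS,
    on_target_pam: str = DEFAULT_PAM,
) -> GuideClassification:
    """Count perfect genomic matches and <=``max_mm``-mismatch off-target sites.

    Perfect matches require the on-target PAM class; off-target hits (1..max_mm
    mismatches, no indels) require the adjacent 4-mer to match any pattern in
    ``offtarget_pams``.  Hits are deduplicated by genomic site, so a site whose
    PAM satisfies several patterns counts once.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt, got {len(protospacer)}")
    if set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must contain only A/C/G/T (no N or ambiguity codes)")
    genome = validate_genome(genome)
    for pat in offtarget_pams:
        validate_pattern(pat)

    enc_query = encode(protospacer)
    perfect = 0
    offtargets = 0
    for contig, seq in genome.items():
        for strand_seq in (seq, revcomp(seq)):
            enc = encode(strand_seq)
            mm = _mismatch_profile(enc, enc_query)
            n = mm.size
            if n == 0:
                continue
            on_pam = _pam_hit_mask(strand_seq, enc, n, [on_target_pam])
            off_pam = _pam_hit_mask(strand_seq, enc, n, offtarget_pams)
            perfect += int(np.count_nonzero((mm == 0) & on_pam))
            offtargets += int(np.count_nonzero((mm >= 1) & (mm <= max_mm) & off_pam))
    return GuideClassification(protospacer, perfect, offtargets)


def classify_guides(
    sites: list[TargetSite],
    genome: dict[str, str],
    max_mm: int = 3,
    offtarget_pams=DEFAULT_OFFTARGET_PAMS,
    on_target_pam: str = DEFAULT_PAM,
) -> dict[str, GuideClassification]:
    """Classify each distinct protospacer among ``sites`` (cached by sequence)."""
    out: dict[str, GuideClassification] = {}
    for site in sites:
        if site.protospacer not in out and "N" not in site.protospacer:
            out[site.protospacer] = count_genome_matches(
                site.protospacer, genome, max_mm, offtarget_pams, on_target_pam
            )
    return out


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_and_select(
    sites: list[TargetSite],
    classifications: dict[str, GuideClassification],
    gene_intervals: list[tuple[str, int, int]] | None = None,
    min_sites: int = 5,
) -> list[SiteBin]:
    """Cluster sites into fixed 1-kb bins and keep candidate design bins.

    A bin is kept when it holds more than ``min_sites`` sites and contains at
    least one unique-labelled and one promiscuous-labelled guide.
    ``gene_overlap`` is true when the bin interval intersects any gene
    interval (half-open intersection).
    """
    gene_intervals = gene_intervals or []
    bins: dict[tuple[str, int], SiteBin] = {}
    for site in sites:
        idx = site.pos1 // 1000
        key = (site.contig, idx)
        bins.setdefault(key, SiteBin(site.contig, idx)).member_sites.append(site)

    selected: list[SiteBin] = []
    for b in bins.values():
        if len(b.member_sites) <= min_sites:
            continue
        labels = {
            classifications[s.protospacer].label
            for s in b.member_sites
            if s.protospacer in classifications
        }
        if "unique" not in labels or "promiscuous" not in labels:
            continue
        b.gene_overlap = any(
            contig == b.contig and start < b.end and b.start < end
            for contig, start, end in gene_intervals
        )
        selected.append(b)
    selected.sort(key=lambda b: (b.contig, b.bin_index))
    return selected


# ---------------------------------------------------------------------------
# cassette assembly
# ---------------------------------------------------------------------------

def build_crrna_cassette(
    protospacers: list[str],
    promoter: str,
    start: str = "GTCC",
    repeat: str = LBCAS12A_REPEAT,
    polyt_len: int = 9,
) -> str:
    """Assemble a crRNA expression cassette.

    Layout: promoter, transcription start, then alternating repeat/protospacer
    units closed by a final repeat, then a poly(T) terminator — with k
    protospacers there are k+1 repeats (k=1 gives the single-guide
    repeat/protospacer/repeat form).
    """
    if not protospacers:
        raise ValueError("at least one protospacer is required")
    for p in protospacers:
        if len(p) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer {p!r} is not {PROTOSPACER_LEN} nt")
    parts = [promoter, start]
    for p in protospacers:
        parts.append(repeat)
        parts.append(p)
    parts.append(repeat)
    parts.append("T" * polyt_len)
    return "".join(parts)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in sites],
            "contig": [s.contig for s in sites],
            "position": [s.pos1 for s in sites],
            "strand": [s.strand for s in sites],
            "pam": [s.pam_seq for s in sites],
            "protospacer": [s.protospacer for s in sites],
        }
    )


def classification_table(classifications: dict[str, GuideClassification]) -> pd.DataFrame:
    rows = [
        (c.protospacer, c.perfect_match_count, c.offtarget_count, c.label)
        for c in classifications.values()
    ]
    return pd.DataFrame(
        rows, columns=["protospacer", "perfect_match_count", "offtarget_count", "label"]
    )


def bins_table(bins: list[SiteBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [b.contig for b in bins],
            "bin_index": [b.bin_index for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "n_sites": [len(b.member_sites) for b in bins],
            "gene_overlap": [b.gene_overlap for b in bins],
        }
    )


def _pam_matches(pam: str, pattern: str) -> bool:
    return matches_pattern(pam, pattern)
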
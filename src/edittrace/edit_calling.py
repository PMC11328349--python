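"""Amplicon read assignment, allele extraction and edit calling.

Reads from multiplexed amplicon sequencing are assigned to loci by exact
locus-specific k-mer pairs, globally aligned to their reference amplicon with
an affine-gap aligner, and reduced to an *allele signature*: the set of
variant operations (deletions, insertions, substitutions) overlapping the
23-nt protospacer-bound window.  Hybrid reads produced by template switching
between near-identical paralogs are removed by exact window-sequence
comparison against the other assayed loci.  Alleles are then called with
generation-specific support thresholds: strictly >10% of reads in T0;
>=5 reads and >=5% of reads in T1.

Signatures use a compact grammar relative to the window start, e.g.
``D5:7`` (deletion at window offset 5, length 7), ``I3:AT`` (insertion),
``S10:G`` (substitution); the reference allele is ``ref``.  Indels are
left-normalized so allele identity is stable across plants and generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .sequence import revcomp

DEFAULT_DELETION_BINS = ((1, 5), (6, 10), (11, 15), (16, 20))  # then >20
MIN_ALIGN_IDENTITY = 0.60


@dataclass
class EditCallConfig:
    t0_min_fraction: float = 0.10  # exclusive
    t1_min_reads: int = 5  # inclusive
    t1_min_fraction: float = 0.05  # inclusive

    def __post_init__(self):
        if not 0 < self.t0_min_fraction < 1 or not 0 < self.t1_min_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if self.t1_min_reads < 1:
            raise ValueError("t1_min_reads must be >= 1")


@dataclass
class LocusAssay:
    locus_id: str
    reference_amplicon: str
    window_start: int  # 0-based offset of the 23-nt protospacer-bound window
    left_kmer: str
    right_kmer: str
    # SNP positions (amplicon offset) whose base resolves near-identical loci:
    # list of (offset, {base: true locus_id})
    discriminating_snps: list = field(default_factory=list)
    merged_with: str | None = None
    window_len: int = 23

    def __post_init__(self):
        self.reference_amplicon = self.reference_amplicon.upper()
        if self.left_kmer not in self.reference_amplicon:
            raise ValueError(f"{self.locus_id}: left kmer absent from reference amplicon")
        if self.right_kmer not in self.reference_amplicon:
            raise ValueError(f"{self.locus_id}: right kmer absent from reference amplicon")
        if not 0 <= self.window_start <= len(self.reference_amplicon) - self.window_len:
            raise ValueError(f"{self.locus_id}: window outside amplicon")

    @property
    def window_end(self) -> int:
        return self.window_start + self.window_len

    @property
    def window_seq(self) -> str:
        return self.reference_amplicon[self.window_start : self.window_end]


def validate_assays(assays: list[LocusAssay]) -> dict[str, LocusAssay]:
    """Index assays by locus, rejecting duplicate k-mers across loci."""
    seen: dict[str, str] = {}
    for a in assays:
        for kmer in (a.left_kmer, a.right_kmer):
            if kmer in seen and seen[kmer] != a.locus_id:
                raise ValueError(
                    f"kmer {kmer!r} shared by loci {seen[kmer]} and {a.locus_id}"
                )
            seen[kmer] = a.locus_id
    return {a.locus_id: a for a in assays}


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------
# An op is ("D", start, length) | ("I", pos, seq) | ("S", pos, base),
# coordinates relative to the assay window start (may be negative for ops
# that begin upstream but overlap the window).

def signature_to_str(signature: tuple) -> str:
    if not signature:
        return "ref"
    parts = []
    for op in signature:
        kind, pos, arg = op
        parts.append(f"{kind}{pos}:{arg}")
    return ";".join(parts)


def parse_signature(text: str) -> tuple:
    if text in ("ref", "", None):
        return ()
    ops = []
    for part in text.split(";"):
        kind = part[0]
        pos_s, arg = part[1:].split(":", 1)
        ops.append((kind, int(pos_s), int(arg) if kind == "D" else arg))
    return tuple(ops)


def classify_edit(signature: tuple, bins=DEFAULT_DELETION_BINS) -> tuple[str, int, str]:
    """Classify a non-empty signature: (edit_class, deletion_len, deletion_bin).

    Single-kind signatures take that kind; mixtures are ``complex``.
    Deletion length (total deleted bases) is binned into 1-5, 6-10, 11-15,
    16-20 and >20 nt by default.
    """
    if not signature:
        raise ValueError("reference alleles are never classified")
    kinds = {op[0] for op in signature}
    if len(kinds) > 1:
        edit_class = "complex"
    else:
        edit_class = {"D": "deletion", "I": "insertion", "S": "substitution"}[kinds.pop()]
    del_len = sum(op[2] for op in signature if op[0] == "D")
    del_bin = ""
    if del_len:
        for lo, hi in bins:
            if lo <= del_len <= hi:
                del_bin = f"{lo}-{hi}"
                break
        else:
            del_bin = f">{bins[-1][1]}"
    return edit_class, del_len, del_bin


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    seq: str  # oriented (forward with respect to the reference amplicon)
    ok: bool  # False when alignment identity fell below the floor
    identity: float
    ops: tuple  # all ops, absolute amplicon coordinates
    signature: tuple  # window-overlapping ops, window-relative coordinates
    window_seq: str  # read bases aligned to the window columns
    blocks: tuple  # matched (tstart, tend, qstart) blocks, for base lookup

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to a reference position, or None if deleted."""
        for ts, te, qs in self.blocks:
            if ts <= ref_pos < te:
                return self.seq[qs + (ref_pos - ts)]
        return None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _left_normalize_deletion(ref: str, start: int, length: int) -> int:
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_normalize_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def extract_allele(read: str, assay: LocusAssay, aligner: Align.PairwiseAligner | None = None) -> AlignedRead:
    """Globally align an (oriented) read to its reference amplicon.

    Variant operations are left-normalized; those overlapping the 23-nt
    window become the read's allele signature.  Reads below 60% alignment
    identity are flagged unalignable (``ok=False``).
    """
    ref = assay.reference_amplicon
    if read == ref:  # exact reference: nothing to align
        return AlignedRead(read, True, 1.0, (), (), assay.window_seq, ((0, len(ref), 0),))
    aligner = aligner or _make_aligner()
    aln = aligner.align(ref, read)[0]
    tblocks, qblocks = aln.aligned
    blocks = tuple((int(ts), int(te), int(qs)) for (ts, te), (qs, _qe) in zip(tblocks, qblocks))

    matches = 0
    columns = 0
    raw_ops: list[tuple] = []
    prev_te = 0
    prev_qe = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        dt, dq = ts - prev_te, qs - prev_qe
        if dt > 0:
            raw_ops.append(("D", prev_te, dt))
            columns += dt
        if dq > 0:
            raw_ops.append(("I", ts, read[prev_qe:qs]))
            columns += dq
        for t, q in zip(range(ts, te), range(qs, qe)):
            columns += 1
            if ref[t] == read[q]:
                matches += 1
            else:
                raw_ops.append(("S", t, read[q]))
        prev_te, prev_qe = te, qe
    dt, dq = len(ref) - prev_te, len(read) - prev_qe
    if dt > 0:
        raw_ops.append(("D", prev_te, dt))
        columns += dt
    if dq > 0:
        raw_ops.append(("I", len(ref), read[prev_qe:]))
        columns += dq

    identity = matches / columns if columns else 0.0
    if identity < MIN_ALIGN_IDENTITY:
        return AlignedRead(read, False, identity, (), (), "", blocks)

    ops: list[tuple] = []
    for op in raw_ops:
        if op[0] == "D":
            start = _left_normalize_deletion(ref, op[1], op[2])
            ops.append(("D", start, op[2]))
        elif op[0] == "I":
            pos, seq = _left_normalize_insertion(ref, op[1], op[2])
            ops.append(("I", pos, seq))
        else:
            ops.append(op)
    ops.sort(key=lambda o: (o[1], o[0]))

    ws, we = assay.window_start, assay.window_end
    signature = []
    for op in ops:
        kind, pos, arg = op
        if kind == "D":
            if pos < we and pos + arg > ws:
                signature.append(("D", pos - ws, arg))
        elif kind == "I":
            if ws <= pos <= we:
                signature.append(("I", pos - ws, arg))
        else:
            if ws <= pos < we:
                signature.append(("S", pos - ws, arg))

    window_parts: list[str] = []
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        lo, hi = max(ts, ws), min(te, we)
        if lo < hi:
            window_parts.append(read[qs + (lo - ts) : qs + (hi - ts)])
    # insertions strictly inside the window contribute their read bases
    prev_te = 0
    prev_qe = 0
    inner: list[tuple[int, str]] = []
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if qs > prev_qe and ws < ts < we and prev_te == ts:
            inner.append((ts, read[prev_qe:qs]))
        prev_te, prev_qe = te, qe
    window_seq = _window_with_insertions(window_parts, inner, blocks, ws)
    return AlignedRead(read, True, identity, tuple(ops), tuple(signature), window_seq, blocks)


def _window_with_insertions(parts, inner, blocks, ws):
    # parts are already ordered by reference position; splice insertions in
    if not inner:
        return "".join(parts)
    out = ""
    consumed = 0
    inner = sorted(inner)
    joined = "".join(parts)
    # map each insertion's reference position to an offset in the joined string
    offsets = []
    for pos, seq in inner:
        covered = 0
        for ts, te, _qs in blocks:
            lo, hi = max(ts, ws), min(te, pos)
            if lo < hi:
                covered += hi - lo
        offsets.append((covered, seq))
    for off, seq in sorted(offsets, reverse=True):
        joined = joined[:off] + seq + joined[off:]
    return joined


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

def assign_reads(reads, assays: list[LocusAssay]):
    """Assign reads to loci by exact k-mer pair matching.

    A read belongs to locus L iff it contains both of L's k-mers, checked on
    the read as given and its reverse complement (the returned sequence is
    orientation-normalized to the reference strand).  Reads matching the
    k-mer pairs of two or more loci, or none, go to the unassigned pool with
    a reason.  ``reads`` is an iterable of (read_id, sequence).
    """
    by_locus = validate_assays(assays)
    assigned: dict[str, list[tuple[str, str]]] = {lid: [] for lid in by_locus}
    unassigned: list[tuple[str, str]] = []
    cache: dict[str, tuple[str | None, str | None]] = {}

    def classify(seq: str) -> tuple[str | None, str | None]:
        """-> (locus or None, reason or None); seq oriented as given."""
        hits = [a.locus_id for a in assays if a.left_kmer in seq and a.right_kmer in seq]
        if len(hits) == 1:
            return hits[0], None
        if len(hits) > 1:
            return None, "ambiguous"
        return None, "no_kmer_match"

    for read_id, seq in reads:
        res = cache.get(seq)
        if res is None:
            locus, reason = classify(seq)
            oriented = seq
            if locus is None and reason == "no_kmer_match":
                rc = revcomp(seq)
                locus, reason = classify(rc)
                if locus is not None or reason == "ambiguous":
                    oriented = rc
            res = (locus, reason if locus is None else None, oriented)
            cache[seq] = res
        locus, reason, oriented = res
        if locus is not None:
            assigned[locus].append((read_id, oriented))
        else:
            unassigned.append((read_id, reason))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# template-switch filtering and SNP-twin splitting
# ---------------------------------------------------------------------------

def filter_template_switches(
    locus_reads: dict[str, list], assays: list[LocusAssay]
):
    """Remove hybrid reads whose window exactly matches another locus' reference.

    A read assigned to locus A whose aligned window sequence equals the
    reference window of a different assayed locus B (and differs from A's own
    reference window) is a template-switch artifact.  ``locus_reads`` maps
    locus -> list of AlignedRead or (read_id, AlignedRead).  Returns
    (kept, removed) with removed entries (read_id, read, donor, matched).
    """
    by_locus = validate_assays(assays)
    window_owner = {a.window_seq: a.locus_id for a in assays}
    kept: dict[str, list] = {}
    removed: list[tuple] = []
    for locus_id, reads in locus_reads.items():
        own_window = by_locus[locus_id].window_seq
        kept[locus_id] = []
        for item in reads:
            read_id, read = item if isinstance(item, tuple) else (None, item)
            other = window_owner.get(read.window_seq)
            if other is not None and other != locus_id and read.window_seq != own_window:
                removed.append((read_id, read, locus_id, other))
            else:
                kept[locus_id].append(item)
    return kept, removed


def split_snp_twins(reads: list[AlignedRead], assay: LocusAssay):
    """Partition reads of a merged assay by the discriminating SNP base.

    Reads carrying a deletion across the SNP are undecidable and go to the
    ``ambiguous`` pool attached to the merged locus.  Without a declared SNP
    the input passes through under the assay's own locus.
    """
    if not assay.discriminating_snps:
        return {assay.locus_id: reads}, []
    offset, base_to_locus = assay.discriminating_snps[0]
    out: dict[str, list[AlignedRead]] = {lid: [] for lid in base_to_locus.values()}
    ambiguous: list[AlignedRead] = []
    for read in reads:
        base = read.base_at(offset)
        if base is None or base not in base_to_locus:
            ambiguous.append(read)
        else:
            out[base_to_locus[base]].append(read)
    return out, ambiguous


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------

@dataclass
class AlleleCall:
    locus_id: str
    signature: tuple
    read_count: int
    read_fraction: float
    edited: bool  # signature non-empty (overlaps the window by construction)
    called: bool  # passes the generation-specific support thresholds
    edit_class: str  # deletion | insertion | substitution | complex | reference
    deletion_len: int
    deletion_bin: str

    @property
    def signature_str(self) -> str:
        return signature_to_str(self.signature)


def call_alleles(
    reads: list[AlignedRead],
    locus_id: str,
    generation: str,
    config: EditCallConfig | None = None,
) -> list[AlleleCall]:
    """Group reads by signature and call edited alleles.

    T0: an edited allele is called iff its read fraction strictly exceeds
    ``t0_min_fraction``.  T1: iff it has at least ``t1_min_reads`` reads AND
    at least ``t1_min_fraction`` of the locus reads.  The reference allele is
    always reported (uncalled-as-edit, fraction possibly 0).  Returns [] for
    a zero-read locus: no data, distinct from unedited.
    """
    if generation not in ("T0", "T1"):
        raise ValueError(f"generation must be T0 or T1, got {generation!r}")
    config = config or EditCallConfig()
    usable = [r for r in reads if r.ok]
    total = len(usable)
    if total == 0:
        return []
    groups: dict[tuple, int] = {}
    for read in usable:
        groups[read.signature] = groups.get(read.signature, 0) + 1
    groups.setdefault((), 0)

    calls = []
    for signature, count in sorted(groups.items(), key=lambda kv: (-kv[1], kv[0])):
        fraction = count / total
        edited = bool(signature)
        if not edited:
            edit_class, del_len, del_bin = "reference", 0, ""
            called = False
        else:
            edit_class, del_len, del_bin = classify_edit(signature)
            if generation == "T0":
                called = fraction > config.t0_min_fraction
            else:
                called = count >= config.t1_min_reads and fraction >= config.t1_min_fraction
        calls.append(
            AlleleCall(locus_id, signature, count, fraction, edited, called, edit_class, del_len, del_bin)
        )
    return calls


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------

class AmpliconCaller:
    """Per-cohort driver that caches alignments across plants.

    Identical read sequences recur heavily within a locus (error-free copies
    of the same allele), so alignments are memoized by (locus, sequence).
    """

    def __init__(self, assays: list[LocusAssay], config: EditCallConfig | None = None):
        self.assays = list(assays)
        self.by_locus = validate_assays(self.assays)
        self.config = config or EditCallConfig()
        self.aligner = _make_aligner()
        self._cache: dict[tuple[str, str], AlignedRead] = {}
        self.n_unalignable = 0

    def align(self, locus_id: str, seq: str) -> AlignedRead:
        key = (locus_id, seq)
        hit = self._cache.get(key)
        if hit is None:
            hit = extract_allele(seq, self.by_locus[locus_id], self.aligner)
            self._cache[key] = hit
        return hit

    def call_plant(self, reads, generation: str):
        """Process one plant's reads end to end.

        -> (calls per locus, removed template-switch reads as
        (read_id, read, donor, matched), unassigned reads).  Loci with zero
        assigned reads are absent from the calls dict (no-data).
        """
        assigned, unassigned = assign_reads(reads, self.assays)
        aligned = {
            lid: [(rid, self.align(lid, seq)) for rid, seq in rs]
            for lid, rs in assigned.items()
            if rs
        }
        kept, removed = filter_template_switches(aligned, self.assays)
        calls: dict[str, list[AlleleCall]] = {}
        for lid, pairs in kept.items():
            rs = [read for _rid, read in pairs]
            assay = self.by_locus[lid]
            split, ambiguous = split_snp_twins(rs, assay)
            for true_lid, sub in split.items():
                self.n_unalignable += sum(1 for r in sub if not r.ok)
                out = call_alleles(sub, true_lid, generation, self.config)
                if out:
                    calls[true_lid] = out
            if ambiguous and assay.merged_with:
                out = call_alleles(ambiguous, assay.merged_with, generation, self.config)
                if out:
                    calls.setdefault(assay.merged_with, []).extend(out)
        return calls, removed, unassigned


def calls_table(per_plant_calls: dict[str, dict[str, list[AlleleCall]]]) -> pd.DataFrame:
    """Flatten {plant_id: {locus_id: [AlleleCall]}} into the output table."""
    rows = []
    for plant_id, by_locus in per_plant_calls.items():
        for locus_id, calls in by_locus.items():
            for c in calls:
                rows.append(
                    (
                        plant_id,
                        locus_id,
                        c.signature_str,
                        c.read_count,
                        c.read_fraction,
                        c.edited,
                        c.called,
                        c.edit_class,
                        c.deletion_bin,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plant_id",
            "locus_id",
            "signature",
            "read_count",
            "read_fraction",
            "edited",
            "called",
            "edit_class",
            "deletion_bin",
        ],
    )
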
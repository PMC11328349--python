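"""Synthetic study generator: genome, plants, amplicon reads, cleavage counts.

The generator emulates the statistical structure the analysis pipeline
assumes, with full ground truth for every stage:

* a paralog-rich genome carrying one on-target site per guide plus engineered
  off-target sites with controlled mismatch/bulge patterns and PAMs;
* per-plant chimeric editing: each edit event arises at a developmental stage
  that fixes both its presence in the sampled T0 leaf and its germline
  transmission (early events transmit at the Mendelian 75%; late germline
  sectors reach only a minority of progeny; late sampled-leaf events are
  never transmitted);
* amplicon reads with uniform substitution sequencing errors and
  template-switch artifacts that swap the protospacer window between
  paralogs;
* in-vitro cleavage count tables whose site activities follow the in-planta
  position-dependent mismatch penalties, over an elbow-shaped background.

Everything is deterministic given ``SimConfig.seed``; every emitted read and
event is traceable to a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edit_calling import LocusAssay
from .genome_scan import PAM_LEN, PROTOSPACER_LEN
from .panel_design import NO_BULGE, BulgeSpec

_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _mutate(base: str, rot: int) -> str:
    for _ in range(rot % 4):
        base = _ROTATE[base]
    return base


@dataclass(frozen=True)
class OfftargetSpec:
    """An engineered off-target: which protospacer positions differ, and how."""

    mismatch_positions: tuple[int, ...]
    rot: int = 1  # base-rotation index; distinguishes paralogs sharing positions
    bulge: BulgeSpec = NO_BULGE
    pam: str = "TTTA"


def default_offtarget_specs(n: int = 19) -> list[OfftargetSpec]:
    """A promiscuous-guide panel: 3 PAM-distal (bases 21-23) sites editing at
    on-target rates plus seed-region sites with strongly reduced activity.

    All windows differ pairwise by >=3 nt so the paralogs remain
    distinguishable in amplicon assays.
    """
    specs = [OfftargetSpec((21, 22, 23), rot) for rot in (1, 2, 3)]
    seed_sets = [
        (1, 2, 3), (4, 5, 6), (7, 8, 9), (10, 11, 12), (13, 14, 15), (16, 17, 18),
        (3, 11, 19), (5, 13, 20), (1, 8, 15), (2, 10, 18), (4, 12, 20), (6, 9, 17),
        (7, 14, 19), (5, 16, 19), (2, 12, 17), (6, 10, 20),
    ]
    specs += [OfftargetSpec(positions, 1) for positions in seed_sets]
    if n > len(specs):
        raise ValueError(f"at most {len(specs)} default off-target specs available")
    return specs[:n]


@dataclass
class EditingModel:
    """Per-site editing probability: p_on x per-mismatch position penalties."""

    p_on: float = 0.5  # probability an allele copy is edited during the T0 life cycle
    penalty_distal: float = 1.0  # positions 21-23: no cost
    penalty_19_20: float = 0.1
    penalty_seed: float = 0.01  # positions 1-18
    bulge_factor: float = 0.01


def editing_probability(
    mismatch_positions, bulge: BulgeSpec = NO_BULGE, params: EditingModel | None = None
) -> float:
    params = params or EditingModel()
    p = params.p_on
    for pos in mismatch_positions:
        if not 1 <= pos <= PROTOSPACER_LEN:
            raise ValueError(f"mismatch position {pos} outside 1..{PROTOSPACER_LEN}")
        if pos >= 21:
            p *= params.penalty_distal
        elif pos >= 19:
            p *= params.penalty_19_20
        else:
            p *= params.penalty_seed
    if bulge.kind != "none":
        p *= params.bulge_factor
    return p


@dataclass
class ChimerismModel:
    """Developmental-stage mixture for edit events.

    Stage fractions are set so that ~80% of T0-observed edits are inherited
    and ~half of all T1-observed alleles are absent from the T0 leaf sample,
    the regime a constitutively expressed nuclease produces.
    """

    frac_early: float = 0.4  # in sampled leaf AND germline (transmission 0.75)
    frac_late_sampled: float = 0.1  # in sampled leaf, not germline
    frac_late_sector: float = 0.5  # germline sector only, minority transmission
    early_transmission: float = 0.75
    late_sector_transmission: tuple[float, float] = (0.05, 0.3)
    late_sampled_leaf_fraction: tuple[float, float] = (0.15, 0.5)
    early_leaf_fraction: float = 0.5  # heterozygous in the sampled leaf


@dataclass
class NoteseqModel:
    on_target_reads_10: int = 2000  # accepted-read scale, 10:1 RNP:DNA condition
    on_target_reads_1: int = 1200
    noise_mean: float = 1.0  # per-replicate background reads at inactive sites
    cut_sd: float = 3.0  # spread of observed cut offsets around the expected cut
    replicates: int = 3


@dataclass
class SimConfig:
    seed: int
    genome_len: int = 60_000
    guides: dict = field(
        default_factory=lambda: {
            "Promiscuous": default_offtarget_specs(19),
            "Unique": [],
        }
    )
    n_plants: dict = field(
        default_factory=lambda: {"Control": 36, "Unique": 59, "Promiscuous": 60}
    )
    n_progeny_range: tuple[int, int] = (9, 12)  # null segregants sampled per family
    read_depth: int = 50
    amplicon_flank: int = 45
    kmer_len: int = 12
    seq_error_rate: float = 2e-4  # per base, post-trimming consensus scale
    template_switch_rate: float = 0.02
    editing: EditingModel = field(default_factory=EditingModel)
    chimerism: ChimerismModel = field(default_factory=ChimerismModel)
    noteseq: NoteseqModel = field(default_factory=NoteseqModel)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory: no implicit randomness")
        for rate in (self.seq_error_rate, self.template_switch_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class PlantedSite:
    locus_id: str
    guide_name: str
    role: str  # on | off
    contig: str
    strand: str
    start: int  # 0-based leftmost coordinate of the site window
    window: str
    pam: str
    mismatch_positions: tuple[int, ...]
    bulge: BulgeSpec
    editing_p: float


@dataclass
class EditEvent:
    event_id: int
    plant_id: str
    locus_id: str
    allele_copy: int  # 0 or 1
    signature: tuple
    stage: str  # early | late_sampled | late_sector
    germline: bool
    transmission: float  # probability a progeny carries the allele
    leaf_fraction: float  # allele fraction in the sampled T0 leaf (0 if absent)


@dataclass
class GroundTruth:
    guides: dict  # guide name -> 23-nt protospacer
    sites: list  # PlantedSite
    events: list = field(default_factory=list)  # EditEvent
    progeny_carriers: dict = field(default_factory=dict)  # plant_id -> [(locus, sig, frac)]
    read_truth: pd.DataFrame | None = None

    def sites_of(self, guide_name: str) -> list:
        return [s for s in self.sites if s.guide_name == guide_name]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(config: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Random background genome with the guides' target-site families planted.

    Each guide gets one on-target site (TTTA PAM) plus one paralogous site
    per off-target spec, built by mutating a copy of the on-target window at
    the stated protospacer positions (and inserting/deleting bases for bulge
    specs).  All sites sit on the forward strand at evenly spaced positions.
    Deterministic per seed; identical configs give identical genomes.
    """
    rng = np.random.default_rng([config.seed, 1])
    bases = np.array(list("ACGT"))
    background = "".join(rng.choice(bases, size=config.genome_len))

    guides: dict[str, str] = {}
    planted: list[PlantedSite] = []
    blocks: list[tuple[int, str]] = []  # (position, PAM+window)
    n_sites = sum(1 + len(specs) for specs in config.guides.values())
    spacing = config.genome_len // (n_sites + 1)
    min_span = 2 * (config.amplicon_flank + PAM_LEN + PROTOSPACER_LEN + 4)
    if spacing < min_span:
        raise ValueError(
            f"genome_len {config.genome_len} too short for {n_sites} sites "
            f"with flank {config.amplicon_flank}"
        )

    slot = 0
    for guide_name, specs in config.guides.items():
        protospacer = "".join(rng.choice(bases, size=PROTOSPACER_LEN))
        guides[guide_name] = protospacer
        site_defs = [("on", OfftargetSpec((), 0))] + [("off", s) for s in specs]
        windows_seen: dict[str, str] = {}
        for role, spec in site_defs:
            window = _build_window(protospacer, spec)
            slot += 1
            pos = slot * spacing  # window start; PAM occupies pos-4..pos
            locus_id = f"chr1_{pos + 1}"
            if window in windows_seen:
                raise ValueError(
                    f"indistinguishable windows for {locus_id} and {windows_seen[window]}"
                )
            windows_seen[window] = locus_id
            p = editing_probability(spec.mismatch_positions, spec.bulge, config.editing)
            planted.append(
                PlantedSite(
                    locus_id, guide_name, role, "1", "+", pos, window,
                    spec.pam if role == "off" else "TTTA",
                    spec.mismatch_positions, spec.bulge, p,
                )
            )
            blocks.append((pos, (spec.pam if role == "off" else "TTTA") + window))

    genome_chars = list(background)
    for pos, block in blocks:
        genome_chars[pos - PAM_LEN : pos - PAM_LEN + len(block)] = list(block)
    genome = {"1": "".join(genome_chars)}
    # planted windows must survive verbatim (blocks never overlap by spacing)
    for site in planted:
        assert genome["1"][site.start : site.start + len(site.window)] == site.window
    return genome, GroundTruth(guides=guides, sites=planted)


def _build_window(protospacer: str, spec: OfftargetSpec) -> str:
    window = list(protospacer)
    for pos in spec.mismatch_positions:
        window[pos - 1] = _mutate(window[pos - 1], spec.rot)
    seq = "".join(window)
    b = spec.bulge
    if b.kind == "dna":  # extra genomic bases
        filler = "".join(_mutate(seq[b.position - 1], k + 1) for k in range(b.size))
        seq = seq[: b.position] + filler + seq[b.position :]
    elif b.kind == "rna":  # genomic deletion relative to the guide
        seq = seq[: b.position] + seq[b.position + b.size :]
    return seq


def make_assays(genome: dict[str, str], truth: GroundTruth, config: SimConfig) -> list[LocusAssay]:
    """One amplicon assay per planted site, k-mers taken from the flanks."""
    assays = []
    seq = genome["1"]
    flank, k = config.amplicon_flank, config.kmer_len
    for site in truth.sites:
        wlen = len(site.window)
        amp = seq[site.start - flank : site.start + wlen + flank]
        assays.append(
            LocusAssay(
                locus_id=site.locus_id,
                reference_amplicon=amp,
                window_start=flank,
                left_kmer=amp[:k],
                right_kmer=amp[-k:],
                window_len=wlen,
            )
        )
    return assays


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

_DELETION_LENGTHS = np.arange(1, 31)
_DELETION_WEIGHTS = np.concatenate(
    [np.full(5, 0.09), np.full(5, 0.05), np.full(5, 0.024), np.full(5, 0.016), np.full(10, 0.01)]
)
_DELETION_WEIGHTS = _DELETION_WEIGHTS / _DELETION_WEIGHTS.sum()


def _random_signature(rng: np.random.Generator, window: str) -> tuple:
    """A plausible Cas12a repair outcome overlapping the cut site (~base 18)."""
    kind = rng.choice(["D", "I", "S", "DI"], p=[0.85, 0.08, 0.04, 0.03])
    cut = min(18, len(window) - 2)
    if kind in ("D", "DI"):
        length = int(rng.choice(_DELETION_LENGTHS, p=_DELETION_WEIGHTS))
        start = cut - int(rng.integers(0, length + 1))
        ops = [("D", start, length)]
        if kind == "DI":
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            ops.append(("I", start, ins))
        return tuple(ops)
    if kind == "I":
        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 6))))
        return (("I", cut, ins),)
    pos = int(rng.integers(max(0, len(window) - 9), len(window)))
    return (("S", pos, _mutate(window[pos], int(rng.integers(1, 4)))),)


def simulate_population(truth: GroundTruth, config: SimConfig):
    """Draw T0 edit events and their transmission to null-segregant progeny.

    Control plants express no guide and receive no events.  Each T0
    plant x locus x allele-copy is edited with the site's probability; each
    event is assigned a developmental stage which fixes its leaf presence and
    germline transmission.  Per family, 9-12 null-segregant progeny are
    sampled; a progeny carries an event's allele with the event's
    transmission probability (homozygous carriers of germline events arise at
    the Mendelian 1/3 of carriers).

    Returns (samples table, truth updated in place).
    """
    rng = np.random.default_rng([config.seed, 2])
    ch = config.chimerism
    samples_rows = []
    event_id = 0
    for construct, n_plants in config.n_plants.items():
        sites = truth.sites_of(construct) if construct in truth.guides else []
        for i in range(n_plants):
            plant_id = f"{construct}_T0_{i:04d}"
            samples_rows.append((plant_id, "T0", construct, plant_id, True))
            plant_events: list[EditEvent] = []
            for site in sites:
                for copy in range(2):
                    if rng.random() >= site.editing_p:
                        continue
                    stage = rng.choice(
                        ["early", "late_sampled", "late_sector"],
                        p=[ch.frac_early, ch.frac_late_sampled, ch.frac_late_sector],
                    )
                    sig = _random_signature(rng, site.window)
                    if stage == "early":
                        transmission = ch.early_transmission
                        leaf = ch.early_leaf_fraction
                        germline = True
                    elif stage == "late_sampled":
                        transmission = 0.0
                        leaf = float(rng.uniform(*ch.late_sampled_leaf_fraction))
                        germline = False
                    else:
                        transmission = float(rng.uniform(*ch.late_sector_transmission))
                        leaf = 0.0
                        germline = True
                    ev = EditEvent(
                        event_id, plant_id, site.locus_id, copy, sig,
                        stage, germline, transmission, leaf,
                    )
                    event_id += 1
                    truth.events.append(ev)
                    plant_events.append(ev)
            n_progeny = int(rng.integers(config.n_progeny_range[0], config.n_progeny_range[1] + 1))
            for j in range(n_progeny):
                progeny_id = f"{plant_id}_T1_{j:02d}"
                samples_rows.append((progeny_id, "T1", construct, plant_id, False))
                carried = []
                for ev in plant_events:
                    if ev.transmission <= 0 or rng.random() >= ev.transmission:
                        continue
                    hom = ev.stage == "early" and rng.random() < 1 / 3
                    carried.append((ev.locus_id, ev.signature, 1.0 if hom else 0.5, ev.event_id))
                truth.progeny_carriers[progeny_id] = carried
    samples = pd.DataFrame(
        samples_rows,
        columns=["plant_id", "generation", "construct", "family_id", "transgene_present"],
    )
    return samples, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def apply_signature(assay: LocusAssay, signature: tuple) -> str:
    """Apply window-relative variant ops to the reference amplicon."""
    seq = assay.reference_amplicon
    ws = assay.window_start
    for op in sorted(signature, key=lambda o: -o[1]):  # right to left: stable coords
        kind, pos, arg = op
        p = ws + pos
        if kind == "D":
            seq = seq[:p] + seq[p + arg :]
        elif kind == "I":
            seq = seq[:p] + arg + seq[p:]
        else:
            base = arg if arg != seq[p] else _mutate(seq[p], 1)
            seq = seq[:p] + base + seq[p + 1 :]
    return seq


def _switch_read(assay: LocusAssay, target_window: str) -> str:
    """The chimeric molecule a template switch produces at this locus.

    The swapped segment comes from the other template's intact target
    region, so the product is the locus' reference amplicon carrying the
    paralog's window verbatim (any window-overlapping edit on the original
    template is lost in the chimera).
    """
    amp = assay.reference_amplicon
    return amp[: assay.window_start] + target_window + amp[assay.window_end :]


def simulate_reads(
    assays: list[LocusAssay],
    samples: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
):
    """Amplicon reads for every assayed plant x locus.

    Reads are drawn from the plant's allele mixture at the locus, hit by a
    template switch (window swapped with a random other planted locus) with
    probability ``template_switch_rate``, then by uniform per-base
    substitution errors.  Returns (reads table, read truth table); both are
    deterministic per seed.
    """
    rng = np.random.default_rng([config.seed, 3])
    by_locus = {a.locus_id: a for a in assays}
    windows = {a.locus_id: a.window_seq for a in assays}
    locus_ids = list(windows)

    events_by_plant: dict[str, list[EditEvent]] = {}
    for ev in truth.events:
        events_by_plant.setdefault(ev.plant_id, []).append(ev)

    read_rows: list[tuple[str, str, str]] = []
    truth_rows: list[tuple] = []
    n_read = 0
    for plant_id, generation in zip(samples["plant_id"], samples["generation"]):
        if generation == "T0":
            alleles_all = [
                (ev.locus_id, ev.signature, ev.leaf_fraction)
                for ev in events_by_plant.get(plant_id, [])
                if ev.leaf_fraction > 0
            ]
        else:
            alleles_all = [
                (locus, sig, frac)
                for locus, sig, frac, _ev in truth.progeny_carriers.get(plant_id, [])
            ]
        for locus_id in locus_ids:
            assay = by_locus[locus_id]
            here = [(sig, frac) for locus, sig, frac in alleles_all if locus == locus_id]
            fracs = np.array([f for _s, f in here], dtype=float)
            ref_frac = max(0.0, 1.0 - fracs.sum())
            probs = np.append(fracs, ref_frac)
            probs = probs / probs.sum()
            counts = rng.multinomial(config.read_depth, probs)
            variants = [sig for sig, _f in here] + [()]
            for sig, n in zip(variants, counts):
                if n == 0:
                    continue
                base_seq = apply_signature(assay, sig) if sig else assay.reference_amplicon
                n_switch = rng.binomial(n, config.template_switch_rate)
                for k in range(n):
                    switched = k < n_switch
                    seq = base_seq
                    switch_target = ""
                    if switched:
                        switch_target = locus_ids[int(rng.integers(len(locus_ids) - 1))]
                        if switch_target == locus_id:
                            switch_target = locus_ids[-1]
                        seq = _switch_read(assay, windows[switch_target])
                    seq = _inject_errors(seq, config.seq_error_rate, rng)
                    read_id = f"r{n_read:08d}"
                    n_read += 1
                    read_rows.append((read_id, plant_id, seq))
                    truth_rows.append(
                        (read_id, plant_id, locus_id, _sig_key(sig), switched, switch_target)
                    )
    reads = pd.DataFrame(read_rows, columns=["read_id", "plant_id", "sequence"])
    read_truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "plant_id", "locus_id", "true_signature", "switched", "switch_target"],
    )
    truth.read_truth = read_truth
    return reads, read_truth


def _sig_key(signature: tuple) -> str:
    from .edit_calling import signature_to_str

    return signature_to_str(signature)


def canonical_signature(assay: LocusAssay, signature: tuple) -> str:
    """The signature string the pipeline reports for a planted allele.

    Planted ops and aligner output can differ in representation (e.g. a
    deletion in a repeat left-normalizes to a smaller start); aligning an
    error-free read of the allele yields the canonical form, so ground-truth
    events can be matched to pipeline calls exactly.
    """
    from .edit_calling import extract_allele, signature_to_str

    read = apply_signature(assay, signature)
    return signature_to_str(extract_allele(read, assay).signature)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        chars[pos] = _mutate(chars[pos], int(rng.integers(1, 4)))
    return "".join(chars)


def write_fastq(reads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for read_id, plant_id, seq in reads.itertuples(index=False):
            fh.write(f"@{read_id} plant={plant_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# in-vitro cleavage counts
# ---------------------------------------------------------------------------

def simulate_noteseq(truth: GroundTruth, config: SimConfig, guide_name: str = "Promiscuous"):
    """Cleaved-half observations for one guide's planted panel.

    Expected accepted counts scale with the site's editing probability
    relative to the on-target; inactive sites see only a small Poisson noise
    floor.  Cut offsets spread around the expected cut point, so a fraction
    of observations falls outside the acceptance window (as in real data).
    """
    rng = np.random.default_rng([config.seed, 4])
    ns = config.noteseq
    p_on = config.editing.p_on
    rows = []
    for site in truth.sites_of(guide_name):
        rel = site.editing_p / p_on if p_on > 0 else 0.0
        for condition, scale in (
            ("ratio_10_1", ns.on_target_reads_10),
            ("ratio_1_1", ns.on_target_reads_1),
        ):
            for rep in range(1, ns.replicates + 1):
                lam = scale * rel / ns.replicates
                n_reads = rng.poisson(lam) + rng.poisson(ns.noise_mean)
                if n_reads == 0:
                    continue
                offsets = np.rint(rng.normal(0.0, ns.cut_sd, size=n_reads)).astype(int)
                vals, counts = np.unique(offsets, return_counts=True)
                for off, cnt in zip(vals, counts):
                    rows.append((site.locus_id, condition, rep, int(off), int(cnt)))
    return pd.DataFrame(
        rows, columns=["site_id", "condition", "replicate", "cut_offset", "count"]
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimConfig
    genome: dict[str, str]
    truth: GroundTruth
    assays: list
    samples: pd.DataFrame
    reads: pd.DataFrame
    noteseq: pd.DataFrame
    guide_loci: pd.DataFrame


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generator: genome -> population -> reads -> cleavage counts."""
    genome, truth = make_genome(config)
    assays = make_assays(genome, truth, config)
    samples, truth = simulate_population(truth, config)
    reads, _ = simulate_reads(assays, samples, truth, config)
    noteseq_guide = next(iter(config.guides)) if config.guides else None
    noteseq = (
        simulate_noteseq(truth, config, noteseq_guide)
        if noteseq_guide
        else pd.DataFrame(columns=["site_id", "condition", "replicate", "cut_offset", "count"])
    )
    guide_loci = pd.DataFrame(
        [(s.guide_name, s.locus_id, s.role) for s in truth.sites],
        columns=["construct", "locus_id", "role"],
    )
    return SimulatedStudy(config, genome, truth, assays, samples, reads, noteseq, guide_loci)
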
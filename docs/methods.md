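# Methods

This note documents the models, conventions and numerical choices behind
edittrace, and what the synthetic-data generator does and does not emulate.

## Coordinates, sites and guide classification

Coordinates are 0-based half-open internally; locus identifiers and reports
use 1-based forward-strand coordinates (`chr<contig>_<pos>`, the position of
protospacer base 1, the PAM-proximal base). On the minus strand, PAM and
protospacer are reported in that strand's 5'→3' reading orientation.

The target-site scan matches a 4-symbol IUPAC PAM pattern (default TTTV) and
takes the 23 nt downstream; sites whose protospacer would run off the contig
are dropped. A genomic `N` matches no concrete base and no PAM letter except
`N` itself, so it always counts as a mismatch.

Guide classification counts perfect matches under the on-target PAM class and
off-target sites at 1–3 mismatches (no indels) under the relaxed PAM set
{TTTN, NTTN, TTCA, TTCC}. NTTN subsumes TTTN, so hits are deduplicated by
(contig, strand, position): each genomic site counts once no matter how many
patterns its PAM satisfies. Zero-mismatch hits under a relaxed PAM that fail
the on-target class are counted in neither bucket. Mismatch counting is an
exact vectorised scan (one shifted numpy comparison per protospacer
position). A seeded k-mer index was considered and rejected: no single exact
seed length is pigeonhole-complete for 3 mismatches in a 23-mer (mismatches
at positions 6/12/18 leave no intact 11-mer), whereas the vectorised scan is
exhaustive by construction and fast enough for genomes far beyond the test
sizes. The brute-force per-position oracle lives in the test suite and the
two are asserted identical on randomized genomes.

Bins are fixed 1-kb windows anchored at coordinate 0 (not sliding). A bin is
a design candidate when it holds more than `min_sites` (default 5) target
sites including at least one unique-labelled and one promiscuous-labelled
guide; the tool reports gene overlap but leaves the non-essential/duplicated
judgement to the user's gene list. Cassette assembly follows the
repeat–spacer architecture: promoter, GTCC transcription start, then k+1
direct repeats interleaving k protospacers, closed by a 9-nt poly(T).

## Candidate off-target enumeration

Candidates are all genomic windows matching the guide with ≤8 mismatches and
no bulge, or ≤5 mismatches with a single internal DNA bulge (extra genomic
bases) or RNA bulge (guide bases unpaired) of size 1 or 2 — the permissive
envelope an in-vitro cleavage panel interrogates. No PAM filter is applied at
enumeration; the adjacent 4-mer is recorded verbatim because the assay itself
measures PAM tolerance.

All alignments of one guide:target duplex share the genomic position paired
with guide base 1, so candidates are deduplicated by (contig, strand, that
anchor). This grouping is invariant under reverse-complementing the genome,
which a forward-strand leftmost-start key is not once window lengths differ
(21–25 nt). Within a group the preferred alignment has the fewest bulge
bases, then the fewest mismatches, then the leftmost bulge position. Bulges
are internal only — an end gap is not a bulge but a shorter match.

Panel oligos carry a unique barcode pair per site, drawn without replacement
from a seeded shuffle of all k-mers with no homopolymer run ≥3 (synthesis
practicality), around the genomic window with 20 nt of flank (truncated at
contig ends and N-padded to a constant oligo length).

## In-vitro cleavage scoring

Observations are (site, condition, replicate, cut offset) tuples; the offset
is measured from the expected cut point, a configurable protospacer
coordinate defaulting to after base 18 — the PAM-distal staggered cut typical
of Cas12a; only the acceptance window widths (6 nt PAM side, 8 nt protospacer
side) are fixed by the assay definition. Replicates are pooled before
thresholding, and the two RNP:DNA conditions (10:1, 1:1) share one
background, matching how a single background value per guide is used in
practice. Scores are per condition — site count over on-target count — and
never clamped; scores above 1 occur at sites cleaved more efficiently than
the on-target. "Above background" is strict (>), so a floor of 10 requires an
11th read.

Background is max(10 reads, plateau of the ranked count curve): counts are
sorted descending and the plateau is the mean of the first run of 25
consecutive sites whose per-step relative change is below 5%. The window and
tolerance are defaults with overrides — the underlying criterion ("where the
curve levels out") is visual in origin. With fewer sites than the window the
floor is used, with a warning.

## Edit calling

Reads are assigned to a locus by exact containment of both of its k-mers,
evaluated on the read and its reverse complement (output is
orientation-normalized); reads matching two loci or none are set aside with a
reason, never silently dropped. Alignment is global with affine gaps (match
+1, mismatch −1, gap of length L costs 4 + (L−1)); the gap penalties favour
one contiguous indel, the dominant Cas12a repair outcome. Reads under 60%
alignment identity are counted as unalignable and excluded. Indels are
left-normalized before any comparison, so an allele has one canonical
signature across reads, plants and generations; a deletion in a repeat
always reports its leftmost placement.

The allele signature is the subset of operations overlapping the 23-nt
window. Overlap for deletions is interval intersection (a deletion starting
upstream and ending inside counts); substitutions count when inside;
insertions count when their insertion point touches the window boundary or
interior. Edit classes are deletion / insertion / substitution when a single
kind is present and complex otherwise; deletion lengths are binned 1–5,
6–10, 11–15, 16–20, >20 nt (configurable edges — the bins are a reporting
convention, not a model).

Template-switch artifacts — PCR chimeras between near-identical paralogs that
masquerade as multi-substitution alleles — are removed when a read's aligned
window sequence exactly equals a *different* assayed locus' reference window.
Exactness keeps the filter conservative: a genuinely novel allele one
substitution away from another paralog's window is kept. Twin loci
distinguishable only by a SNP are split by the base observed at the declared
offset; reads whose deletion spans the SNP go to an ambiguous pool attached
to the merged locus, and twins with no discriminating SNP are reported as a
single merged locus.

Calling thresholds: T0 edited alleles need strictly >10% of the locus reads;
T1 alleles need ≥5 reads and ≥5% (both inclusive, read as a conjunction).
The reference allele is always reported with its fraction; a locus with zero
reads is no-data, distinct from unedited, and excluded from editing-rate
denominators. No minimum read count is applied in T0 beyond the fraction.

## Inheritance

Only transgene-free (null-segregant) progeny enter the analysis: without the
nuclease their edits are inherited, not de novo. Per family × locus × allele,
the carrier count over progeny-with-data is tested against the 75%
transmission expected for a heterozygous edit in a selfed parent: a 1-df
chi-squared goodness-of-fit without continuity correction, with the exact
two-sided binomial p reported alongside for transparency. The categorical
call uses the fixed operational cut — non-Mendelian when ≤20% of progeny
carry the allele — rather than re-deriving a per-family cut from alpha,
because family sizes here (9–12) make the fixed bin the stable choice; the
chi-squared p is reported, not used for binning. Homozygous-parent handling
is out of scope; an allele in all of ≥10 progeny is flagged. An allele
present in progeny but not the parent's leaf sample is "T1-only";
inherited + T1-only partition the progeny-observed alleles.

## The synthetic-study generator

The generator produces every input the pipeline consumes, with ground truth
attached to each site, event and read. All randomness flows from one seed;
identical configurations give byte-identical outputs.

**Genome.** A uniform-random background with one on-target site (TTTA PAM)
per guide and one engineered paralog per off-target spec, built by mutating a
copy of the on-target window at stated protospacer positions (optionally with
a bulge). The default 19-site panel pairs 3 PAM-distal sites (mismatches
confined to bases 21–23, which cost nothing in the editing model) with 16
seed-region sites; all windows differ pairwise by ≥3 nt so paralogs stay
distinguishable in amplicon assays.

**Editing model.** Per allele copy, editing occurs with probability
p_on × ∏ penalties: 1.0 per mismatch at positions 21–23, 0.1 at 19–20, 0.01
at 1–18, ×0.01 for a bulge. p_on = 0.5 per copy puts plant-level editing at
~75%, the scale observed for active guides in soybean T0 cohorts. The
position profile encodes the central empirical finding the pipeline is meant
to resolve: PAM-distal mismatches are tolerated, seed mismatches are not.

**Chimerism.** Each edit event draws a developmental stage: *early* (present
in the sampled unifoliate leaf at fraction 0.5 and germline, transmission
0.75), *late-sampled* (in the leaf at U(0.15, 0.5), never transmitted), or
*late germline sector* (absent from the leaf, transmitted to U(0.05, 0.3) of
progeny). Stage fractions default to 0.4/0.1/0.5, chosen so the emergent
cohort statistics sit where a constitutively expressed nuclease puts them:
~80% of T0-observed edits inherited, roughly half of progeny-observed alleles
absent at T0, and T1-only alleles carried by ~20% of progeny on average.
Carriers of germline events are homozygous with probability 1/3 (selfing);
allele copies segregate independently — linkage between two edits in one
parent is not modelled. The transgene segregates away silently: sampled
progeny are the 9–12 null segregants per family and carry no new edits.

**Reads.** Per plant × locus, a fixed depth (default 50) is drawn
multinomially from the allele mixture. Template switches (default rate 2%,
a placeholder for testing — the real frequency is platform-dependent and not
modelled mechanistically) replace the read with the locus' reference amplicon
carrying another paralog's window verbatim: the swapped segment derives from
the other template's intact target region, so any window-overlapping edit on
the source molecule is lost in the chimera. Substitution errors are uniform
at 2×10⁻⁴ per base, a post-trimming consensus scale appropriate for merged
amplicon data; raw-instrument error profiles, indel errors, quality scores
and PCR duplicates are deliberately not emulated. Passing closed-loop tests
therefore demonstrates correctness of the analysis logic under the stated
statistical structure, not robustness to platform-specific artifacts.

**Cleavage counts.** Panel sites receive Poisson counts proportional to their
editing probability relative to the on-target (scales 2000 and 1200 accepted
reads for the 10:1 and 1:1 conditions, three replicates), over a Poisson
noise floor of 1 read per replicate, with cut offsets N(0, 3) around the
expected cut so a realistic fraction falls outside the acceptance window.

## Problem sizes and determinism

The closed-loop validation runs 60 families × 10 progeny over a 20-locus
panel (~660 k reads) and a 700-plant T0 cohort for editing-rate recovery;
both finish in seconds because alignments are memoized per (locus, read
sequence) — error-free reads of one allele align once. Mendelian stage
recovery is evaluated per truth allele: against the pipeline's record where
one exists, and as zero observed carriers (non-Mendelian bin) where the
allele was never called in parent or progeny — the classifier's verdict for
an unobserved allele. The late-chimeric assertion is scoped to alleles with
true transmission ≤0.1, where the ≤20% cut is statistically separable from
Mendelian transmission at 10 progeny; between 0.1 and 0.3 the binomial
overlap makes misclassification expected, not erroneous. All tests and the
acceptance script fix their seeds; hypothesis property tests run
derandomized.

## Known limitations

- Zygosity, multi-generation (T2+) tracking and developmental timing of
  edits are out of scope.
- The template-switch filter requires exact window equality; chimeras that
  also carry a sequencing error in the window escape it (~0.5% at default
  error rates) and surface as rare complex alleles below calling thresholds.
- Guide classification treats the genome as haploid reference; structural
  variation between the reference and the transformed line is not modelled.
- The expected-cut reference point for cleavage offsets is a convention;
  analyses comparing cut-site precision across enzymes should set it
  explicitly.
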
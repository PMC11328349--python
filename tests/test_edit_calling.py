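"""Read assignment, allele extraction, artifact filtering and edit calling."""

import numpy as np
import pytest

from edittrace.edit_calling import (
    EditCallConfig,
    LocusAssay,
    assign_reads,
    call_alleles,
    classify_edit,
    extract_allele,
    filter_template_switches,
    parse_signature,
    signature_to_str,
    split_snp_twins,
    validate_assays,
)
from edittrace.sequence import revcomp
from edittrace.synthetic_data import apply_signature


def _assay(locus_id, seed, window=None, flank=40):
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), size=flank))
    window = window or "".join(rng.choice(list("ACGT"), size=23))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    amp = left + window + right
    return LocusAssay(locus_id, amp, flank, amp[:12], amp[-12:])


class TestAssignReads:
    def setup_method(self):
        self.assays = [_assay(f"L{i}", seed=i) for i in range(3)]

    def test_reference_read_self_assigns(self):
        ref = self.assays[0].reference_amplicon
        assigned, unassigned = assign_reads([("r1", ref)], self.assays)
        assert assigned["L0"] == [("r1", ref)]
        assert unassigned == []

    def test_left_kmer_only_unassigned(self):
        a = self.assays[0]
        read = a.left_kmer + "ACGT" * 10
        _assigned, unassigned = assign_reads([("r1", read)], self.assays)
        assert unassigned == [("r1", "no_kmer_match")]

    def test_reverse_complement_reads_oriented(self):
        ref = self.assays[1].reference_amplicon
        assigned, _ = assign_reads([("r1", revcomp(ref))], self.assays)
        assert assigned["L1"] == [("r1", ref)]

    def test_read_matching_two_loci_is_ambiguous(self):
        a, b = self.assays[0], self.assays[1]
        chimera = a.left_kmer + a.right_kmer + b.left_kmer + b.right_kmer
        _assigned, unassigned = assign_reads([("r1", chimera)], self.assays)
        assert unassigned == [("r1", "ambiguous")]

    def test_duplicate_kmer_is_configuration_error(self):
        clone = _assay("L9", seed=0)  # same sequence as L0 -> same kmers
        with pytest.raises(ValueError, match="shared by loci"):
            validate_assays([self.assays[0], clone])

    def test_simulated_reads_match_generating_labels(self, rng):
        reads, labels = [], []
        for i in range(1000):
            assay = self.assays[i % 3]
            sig = (("D", int(rng.integers(0, 10)), int(rng.integers(1, 8))),)
            seq = apply_signature(assay, sig) if i % 2 else assay.reference_amplicon
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"r{i}", seq))
            labels.append(assay.locus_id)
        assigned, unassigned = assign_reads(reads, self.assays)
        assert not unassigned
        got = {rid: lid for lid, rs in assigned.items() for rid, _ in rs}
        assert got == {f"r{i}": lab for i, lab in enumerate(labels)}


class TestExtractAllele:
    def test_deletion_inside_window(self, toy_assay):
        read = apply_signature(toy_assay, (("D", 5, 7),))
        aligned = extract_allele(read, toy_assay)
        assert aligned.signature == (("D", 5, 7),)

    def test_substitution_outside_window_is_reference(self, toy_assay):
        amp = toy_assay.reference_amplicon
        pos = toy_assay.window_start - 30
        base = "A" if amp[pos] != "A" else "C"
        read = amp[:pos] + base + amp[pos + 1 :]
        aligned = extract_allele(read, toy_assay)
        assert aligned.signature == ()
        assert aligned.ops != ()  # the variant exists, it just misses the window

    def test_deletion_straddling_window_start_counts(self, toy_assay):
        # starts 2 nt before the window, ends inside: overlap suffices
        read = apply_signature(toy_assay, (("D", -2, 6),))
        aligned = extract_allele(read, toy_assay)
        assert len(aligned.signature) == 1
        kind, start, length = aligned.signature[0]
        assert kind == "D" and length == 6
        # interval oracle: [start, start+len) must intersect [0, 23)
        assert start < 23 and start + length > 0

    def test_deletion_wholly_outside_window_ignored(self, toy_assay):
        read = apply_signature(toy_assay, (("D", -30, 5),))
        assert extract_allele(read, toy_assay).signature == ()

    def test_left_normalization_stable_alleles(self):
        # deletion inside a repeat: any placement must normalize identically
        window = "AAAAATTTTTCCCCCGGGGGACG"
        assay = _assay("L0", seed=42, window=window)
        ws = assay.window_start
        amp = assay.reference_amplicon
        # delete three of the five T's, expressed at two different offsets
        read1 = amp[: ws + 5] + amp[ws + 8 :]
        read2 = amp[: ws + 7] + amp[ws + 10 :]
        sig1 = extract_allele(read1, assay).signature
        sig2 = extract_allele(read2, assay).signature
        assert sig1 == sig2

    def test_unalignable_read_flagged(self, toy_assay):
        junk = "ACGT" * (len(toy_assay.reference_amplicon) // 4)
        aligned = extract_allele(junk, toy_assay)
        assert not aligned.ok

    def test_exact_reference_fast_path(self, toy_assay):
        aligned = extract_allele(toy_assay.reference_amplicon, toy_assay)
        assert aligned.ok and aligned.signature == ()
        assert aligned.window_seq == toy_assay.window_seq


class TestTemplateSwitchFilter:
    def setup_method(self):
        base = _assay("A", seed=1)
        window_b = "".join(np.random.default_rng(2).choice(list("ACGT"), size=23))
        self.a = base
        self.b = _assay("B", seed=3, window=window_b)
        self.assays = [self.a, self.b]

    def _chimera(self):
        amp = self.a.reference_amplicon
        ws, we = self.a.window_start, self.a.window_end
        return amp[:ws] + self.b.window_seq + amp[we:]

    def test_chimeric_read_removed(self):
        read = extract_allele(self._chimera(), self.a)
        kept, removed = filter_template_switches({"A": [read]}, self.assays)
        assert kept["A"] == []
        assert [(d, m) for _rid, _r, d, m in removed] == [("A", "B")]

    def test_novel_substitution_kept(self):
        amp = self.a.reference_amplicon
        p = self.a.window_start + 10
        base = "A" if amp[p] != "A" else "C"
        read = extract_allele(amp[:p] + base + amp[p + 1 :], self.a)
        kept, removed = filter_template_switches({"A": [read]}, self.assays)
        assert kept["A"] == [read] and removed == []

    def test_reference_reads_never_removed(self):
        read = extract_allele(self.a.reference_amplicon, self.a)
        kept, removed = filter_template_switches({"A": [read]}, self.assays)
        assert kept["A"] == [read] and removed == []


class TestSplitSnpTwins:
    def _twin_assay(self):
        assay = _assay("merged", seed=5)
        snp_offset = assay.window_start + 11
        ref_base = assay.reference_amplicon[snp_offset]
        alt = "A" if ref_base != "A" else "G"
        assay.discriminating_snps = [(snp_offset, {ref_base: "twin1", alt: "twin2"})]
        assay.merged_with = "merged"
        return assay, snp_offset, ref_base, alt

    def test_partition_by_snp_base(self):
        assay, off, ref_base, alt = self._twin_assay()
        amp = assay.reference_amplicon
        read_ref = extract_allele(amp, assay)
        read_alt = extract_allele(amp[:off] + alt + amp[off + 1 :], assay)
        split, ambiguous = split_snp_twins([read_ref, read_alt], assay)
        assert split["twin1"] == [read_ref]
        assert split["twin2"] == [read_alt]
        assert ambiguous == []

    def test_deletion_over_snp_is_ambiguous(self):
        assay, off, *_ = self._twin_assay()
        rel = off - assay.window_start
        read = extract_allele(apply_signature(assay, (("D", rel - 2, 5),)), assay)
        _split, ambiguous = split_snp_twins([read], assay)
        assert ambiguous == [read]

    def test_no_snp_passthrough(self, toy_assay):
        read = extract_allele(toy_assay.reference_amplicon, toy_assay)
        split, ambiguous = split_snp_twins([read], toy_assay)
        assert split == {toy_assay.locus_id: [read]} and ambiguous == []


class TestCallAlleles:
    def _reads(self, assay, groups):
        """groups: list of (signature, count) -> aligned reads."""
        reads = []
        for sig, count in groups:
            seq = apply_signature(assay, sig) if sig else assay.reference_amplicon
            reads += [extract_allele(seq, assay)] * count
        return reads

    def test_t1_read_floor(self, toy_assay):
        # 4 reads at 10% of 40: fraction passes, read floor fails
        reads = self._reads(toy_assay, [((("D", 5, 3),), 4), ((), 36)])
        calls = call_alleles(reads, "L", "T1")
        edited = [c for c in calls if c.edited]
        assert edited and not edited[0].called

    def test_t1_boundary_met(self, toy_assay):
        # 6 reads at exactly 5% of 120: both thresholds inclusive
        reads = self._reads(toy_assay, [((("D", 5, 3),), 6), ((), 114)])
        calls = call_alleles(reads, "L", "T1")
        assert next(c for c in calls if c.edited).called

    def test_t0_exactly_ten_percent_not_called(self, toy_assay):
        reads = self._reads(toy_assay, [((("D", 5, 3),), 4), ((), 36)])
        calls = call_alleles(reads, "L", "T0")
        assert not next(c for c in calls if c.edited).called

    def test_t0_above_ten_percent_called(self, toy_assay):
        reads = self._reads(toy_assay, [((("D", 5, 3),), 5), ((), 35)])
        calls = call_alleles(reads, "L", "T0")
        assert next(c for c in calls if c.edited).called

    def test_threshold_fidelity_on_mixture(self, toy_assay):
        # planted fractions 0.5 / 0.25 / 0.04 at 200 reads
        planted = [(("D", 5, 7),), (("D", 2, 12),), (("I", 9, "TT"),)]
        reads = self._reads(
            toy_assay, [(planted[0], 100), (planted[1], 50), (planted[2], 8), ((), 42)]
        )
        # keys as the aligner canonicalizes them (indels left-normalized)
        keys = [
            extract_allele(apply_signature(toy_assay, sig), toy_assay).signature
            for sig in planted
        ]
        calls = {c.signature: c for c in call_alleles(reads, "L", "T1")}
        assert calls[keys[0]].called
        assert calls[keys[1]].called
        assert not calls[keys[2]].called

    def test_fractions_sum_to_one(self, toy_assay):
        reads = self._reads(toy_assay, [((("D", 5, 7),), 7), ((("I", 9, "A"),), 2), ((), 11)])
        calls = call_alleles(reads, "L", "T1")
        assert sum(c.read_fraction for c in calls) == pytest.approx(1.0, abs=1e-9)

    def test_reference_always_reported(self, toy_assay):
        reads = self._reads(toy_assay, [((("D", 5, 7),), 10)])
        calls = call_alleles(reads, "L", "T0")
        ref = [c for c in calls if not c.edited]
        assert len(ref) == 1 and ref[0].read_fraction == 0.0

    def test_order_independence(self, toy_assay, rng):
        reads = self._reads(toy_assay, [((("D", 5, 7),), 9), ((), 11)])
        shuffled = list(reads)
        rng.shuffle(shuffled)
        c1 = [(c.signature, c.read_count, c.called) for c in call_alleles(reads, "L", "T1")]
        c2 = [(c.signature, c.read_count, c.called) for c in call_alleles(shuffled, "L", "T1")]
        assert c1 == c2

    def test_zero_reads_is_no_data(self, toy_assay):
        assert call_alleles([], "L", "T1") == []

    def test_bad_generation_rejected(self, toy_assay):
        with pytest.raises(ValueError, match="T0 or T1"):
            call_alleles([], "L", "T2")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EditCallConfig(t0_min_fraction=0.0)


class TestClassifyEdit:
    @pytest.mark.parametrize(
        "signature,expected_class,expected_bin",
        [
            ((("D", 5, 7),), "deletion", "6-10"),
            ((("D", 5, 3), ("I", 5, "AT")), "complex", "1-5"),
            ((("I", 9, "A"),), "insertion", ""),
            ((("S", 9, "T"),), "substitution", ""),
            ((("D", 0, 25),), "deletion", ">20"),
            ((("D", 0, 20),), "deletion", "16-20"),
        ],
    )
    def test_classes_and_bins(self, signature, expected_class, expected_bin):
        edit_class, _del_len, del_bin = classify_edit(signature)
        assert (edit_class, del_bin) == (expected_class, expected_bin)

    def test_empty_signature_error(self):
        with pytest.raises(ValueError, match="reference"):
            classify_edit(())

    def test_signature_grammar_round_trip(self):
        sig = (("D", 5, 7), ("I", 12, "AT"), ("S", 20, "G"))
        assert parse_signature(signature_to_str(sig)) == sig
        assert parse_signature("ref") == ()
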
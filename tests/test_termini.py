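import numpy as np
import pytest

from pprfoot.seqio import GeneFeature, RelativePosition, SequenceRecord
from pprfoot.simulate import make_crtpcr_clones, make_genome_with_site
from pprfoot.termini import (
    AmbiguousJunctionError,
    CloneRead,
    TerminusObservation,
    UnmappableCloneError,
    call_junction,
    footprint_sequence,
    tally_termini,
    termini_overlap,
)

from oracles import overlap_by_set_intersection


REF = SequenceRecord("ref", "nucleotide", "AAAACCCCGGGGUUUU")


class TestCallJunction:
    def test_spec_reference_example(self):
        # transcript is positions 5..12; read spans the ligation junction
        read = CloneRead("c1", "GGGGCCCC")
        assert call_junction(read, REF, min_anchor=4) == (12, 5)

    def test_spec_example_split_is_unique_by_enumeration(self):
        # oracle: try every split point by hand; only k=4 gives two flanks
        # of >=4 bases that each occur in the reference
        ref = REF.residues
        valid = []
        read = "GGGGCCCC"
        for k in range(1, len(read)):
            left, right = read[:k], read[k:]
            if len(left) >= 4 and len(right) >= 4 and left in ref and right in ref:
                valid.append(k)
        assert valid == [4]

    def test_contiguous_read_is_unmappable(self):
        read = CloneRead("c2", "CCCCGGGG")  # lies flat on the reference
        with pytest.raises(UnmappableCloneError, match="no junction"):
            call_junction(read, REF, min_anchor=4)

    def test_one_mismatch_in_anchor_unmappable_in_exact_mode(self):
        read = CloneRead("c3", "GGGACCCC")
        with pytest.raises((UnmappableCloneError, AmbiguousJunctionError)):
            call_junction(read, REF, min_anchor=4)

    def test_polya_tail_trimmed(self):
        ref = SequenceRecord(
            "r", "nucleotide", "GCAUCGGAUUACGGCUAGGCUAUCCGGAUCAGGCUUACG"
        )
        # transcript 5' at 3, 3' at 22, with 4 untemplated As at the 3' end
        read = CloneRead("c4", ref.residues[11:22] + "AAAA" + ref.residues[2:13])
        p3, p5 = call_junction(read, ref, min_anchor=8)
        assert (p3, p5) == (22, 3)

    def test_zero_noise_inversion_over_seeds(self):
        misses = 0
        for seed in range(20):
            genome, (ga, gb), truth = make_genome_with_site(
                "GAUCCGGAUCAGUCGAUCGAAG", 67, seed=seed,
                end3_offset=40, end5_offset=-50,
            )
            clones, region, ctruth = make_crtpcr_clones(
                genome, ga, gb,
                {40: 0.7, 38: 0.2, 35: 0.1}, {-50: 0.5, -48: 0.5},
                n_clones=14, noise=0.0, seed=seed,
            )
            for clone, row in zip(clones, ctruth.clones):
                if call_junction(clone, region) != (row[3], row[4]):
                    misses += 1
        assert misses == 0

    @staticmethod
    def _perfectly_explains(read, region, pair, min_anchor=12):
        """True when some split makes the read an exact junction read of
        the called molecule -- an information-theoretically unavoidable
        misattribution when substitution noise forges it."""
        seq, ref = read.sequence, region.residues
        p3, p5 = pair
        for k in range(min_anchor, len(seq) - min_anchor + 1):
            if p3 - k < 0 or p5 - 1 + (len(seq) - k) > len(ref):
                continue
            if seq[:k] == ref[p3 - k : p3] and seq[k:] == ref[p5 - 1 : p5 - 1 + len(seq) - k]:
                return True
        return False

    def test_noise_never_yields_silently_wrong_terminus(self):
        silent_wrong = 0
        unmappable = 0
        for seed in range(30):
            genome, (ga, gb), truth = make_genome_with_site(
                "GAUCCGGAUCAGUCGAUCGAAG", 67, seed=seed,
                end3_offset=40, end5_offset=-50,
            )
            clones, region, ctruth = make_crtpcr_clones(
                genome, ga, gb, {40: 1.0}, {-50: 1.0},
                n_clones=10, noise=0.01, seed=seed + 1000,
            )
            for clone, row in zip(clones, ctruth.clones):
                try:
                    got = call_junction(clone, region, min_anchor=12)
                except (UnmappableCloneError, AmbiguousJunctionError):
                    unmappable += 1
                    continue
                if got != (row[3], row[4]) and not self._perfectly_explains(clone, region, got):
                    silent_wrong += 1
        assert silent_wrong == 0


class TestTallyTermini:
    @staticmethod
    def _obs(kind, anchor, offsets):
        return [
            TerminusObservation(f"c{i}", kind, RelativePosition(anchor, o))
            for i, o in enumerate(offsets)
        ]

    def test_modal_ten_of_fourteen(self):
        obs = self._obs("3prime", "stop_codon", [40] * 10 + [38] * 2 + [35] * 2)
        tally = tally_termini(obs, "3prime")
        assert tally.modal_position == 40
        assert tally.modal_fraction == pytest.approx(10 / 14)
        assert tally.total == 14

    def test_single_observation(self):
        tally = tally_termini(self._obs("5prime", "start_codon", [-50]), "5prime")
        assert tally.modal_position == -50
        assert tally.modal_fraction == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no observations"):
            tally_termini([], "3prime")

    def test_mixed_kind_rejected(self):
        obs = self._obs("3prime", "stop_codon", [40]) + self._obs("5prime", "start_codon", [-50])
        with pytest.raises(ValueError, match="kinds"):
            tally_termini(obs, "3prime")

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        offsets = [o for o in rng.integers(1, 50, size=37).tolist()]
        tally = tally_termini(self._obs("3prime", "stop_codon", offsets), "3prime")
        assert sum(tally.fractions().values()) == pytest.approx(1.0)
        assert tally.total == 37


class TestTerminiOverlap:
    @pytest.mark.parametrize("o3,o5,L,expected", [
        (40, -50, 67, 23),
        (40, -50, 90, 0),
        (10, -10, 5, 5),
    ])
    def test_examples(self, o3, o5, L, expected):
        end3 = RelativePosition("stop_codon", o3)
        end5 = RelativePosition("start_codon", o5)
        length, window = termini_overlap(end3, end5, L)
        assert length == expected
        assert length == overlap_by_set_intersection(o3, o5, L)
        if expected:
            lo, hi = window
            assert hi - lo + 1 == expected

    def test_against_set_oracle_random_triples(self):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            L = int(rng.integers(1, 120))
            o3 = int(rng.integers(1, 150))
            o5 = -int(rng.integers(1, 150))
            length, _ = termini_overlap(
                RelativePosition("stop_codon", o3),
                RelativePosition("start_codon", o5),
                L,
            )
            assert length == overlap_by_set_intersection(o3, o5, L)

    def test_nonpositive_spacer_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            termini_overlap(
                RelativePosition("stop_codon", 1),
                RelativePosition("start_codon", -1),
                0,
            )

    def test_wrong_anchors_rejected(self):
        with pytest.raises(ValueError):
            termini_overlap(
                RelativePosition("start_codon", 4),
                RelativePosition("start_codon", -4),
                10,
            )


def _toy_locus(spacer: str, strand: str = "+"):
    # geneA 1..6, spacer, geneB at the end; minimal anchors for coordinates
    gene_a_seq = "ATGTAA"
    gene_b_seq = "ATGTGA"
    if strand == "+":
        genome = SequenceRecord("toy", "nucleotide", gene_a_seq + spacer + gene_b_seq)
        ga = GeneFeature("gA", 1, 6, "+")
        gb = GeneFeature("gB", 7 + len(spacer), 12 + len(spacer), "+")
    else:
        from pprfoot.seqio import reverse_complement

        fwd = gene_a_seq + spacer + gene_b_seq
        genome = SequenceRecord("toy", "nucleotide", reverse_complement(fwd))
        n = len(fwd)
        ga = GeneFeature("gA", n - 6 + 1, n, "-")
        gb = GeneFeature("gB", 1, 6, "-")
    return genome, ga, gb


class TestFootprintSequence:
    def test_manual_slice(self):
        spacer = "ACGTACGTAG"  # L = 10
        genome, ga, gb = _toy_locus(spacer)
        fp = footprint_sequence(
            genome, ga, gb,
            RelativePosition("stop_codon", 6),
            RelativePosition("start_codon", -7),
        )
        # overlap covers spacer positions 4..6 -> "TAC" -> RNA
        assert fp.residues == "UAC"

    def test_full_spacer_returned(self):
        spacer = "ACGTACGTAG"
        genome, ga, gb = _toy_locus(spacer)
        fp = footprint_sequence(
            genome, ga, gb,
            RelativePosition("stop_codon", 10),
            RelativePosition("start_codon", -10),
        )
        assert fp.residues == spacer.replace("T", "U")

    def test_minus_strand_reports_transcript_orientation(self):
        spacer = "ACGTACGTAG"
        genome_plus, ga_p, gb_p = _toy_locus(spacer, "+")
        genome_minus, ga_m, gb_m = _toy_locus(spacer, "-")
        end3 = RelativePosition("stop_codon", 6)
        end5 = RelativePosition("start_codon", -7)
        fp_plus = footprint_sequence(genome_plus, ga_p, gb_p, end3, end5)
        fp_minus = footprint_sequence(genome_minus, ga_m, gb_m, end3, end5)
        assert fp_minus.residues == fp_plus.residues

    def test_no_overlap_is_an_error(self):
        spacer = "ACGTACGTAG"
        genome, ga, gb = _toy_locus(spacer)
        with pytest.raises(ValueError, match="no footprint"):
            footprint_sequence(
                genome, ga, gb,
                RelativePosition("stop_codon", 2),
                RelativePosition("start_codon", -2),
            )
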
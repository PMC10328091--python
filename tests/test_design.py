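"""Editing-design layer: constructs, templates, validators, scanners."""

import re

import numpy as np
import pytest

from pamflow._seq import revcomp
from pamflow.design import (
    QuantInput,
    build_editing_template,
    build_interference_construct,
    build_synthetic_array,
    check_amplicons,
    derive_native_flanks,
    find_candidate_spacers,
    pfaffl_expression,
    predicted_amplicon_delta,
    scan_rm_sites,
    validate_design,
)
from pamflow.model import GenomeRecord

AW_REPEAT = "ATTTACATTCCAATATGGATCTACTCAAAT"


def random_genome(rng, n=5000, sid="g"):
    return GenomeRecord(id=sid, sequence="".join(rng.choice(np.array(list("ACGT")), size=n)))


class TestNativeFlanks:
    def test_printed_repeat(self):
        assert derive_native_flanks(AW_REPEAT) == ("CAAAT", "ATTTA")

    def test_degenerate_n(self):
        assert derive_native_flanks(AW_REPEAT, 0) == ("", "")

    def test_n_exceeding_repeat(self):
        with pytest.raises(ValueError):
            derive_native_flanks("ACGT", 5)


class TestInterferenceConstruct:
    def test_concatenation(self):
        assert build_interference_construct("ACGT", "CAAAT", "ATTTA") == "CAAATACGTATTTA"

    def test_pam_swap_changes_only_leading_bases(self):
        native = build_interference_construct("ACGT", "CAAAT", "ATTTA")
        pam = build_interference_construct("ACGT", "CCAAT", "ATTTA")
        assert native[5:] == pam[5:]
        assert native[:5] != pam[:5]

    def test_empty_protospacer(self):
        assert build_interference_construct("", "CAAAT", "ATTTA") == "CAAATATTTA"


SPACER36 = "ACGTTGCAGGCTAATCGTCAGGCATTGACTAATGCA"  # 36 nt, 50% GC


class TestFindCandidateSpacers:
    def test_planted_plus_strand_candidate(self):
        genome = GenomeRecord(id="g", sequence="T" * 20 + "CCA" + SPACER36 + "T" * 20)
        (cand,) = find_candidate_spacers(genome, (0, len(genome.sequence)), ["CCA"])
        assert cand.strand == "+"
        assert cand.sequence == SPACER36
        assert cand.pam == "CCA"
        assert (cand.start, cand.end) == (23, 59)

    def test_gc_filter_excludes_extreme(self):
        gc_rich = ("GGCC" * 9)
        genome = GenomeRecord(id="g", sequence="T" * 20 + "CCA" + gc_rich + "T" * 20)
        assert find_candidate_spacers(genome, (0, 79), ["CCA"]) == []

    def test_degenerate_pattern_vs_regex_oracle(self, rng):
        genome = random_genome(rng, 4000)
        found = find_candidate_spacers(genome, (0, 4000), ["CCN"], length=36)
        plus = [c for c in found if c.strand == "+"]
        oracle = []
        for m in re.finditer(r"(?=CC[ACGT])", genome.sequence):
            s = m.start() + 3
            spacer = genome.sequence[s:s + 36]
            if len(spacer) == 36:
                gc = (spacer.count("G") + spacer.count("C")) / 36
                if 0.40 <= gc <= 0.60:
                    oracle.append((s, spacer))
        assert [(c.start, c.sequence) for c in plus] == oracle

    def test_ccg_found_by_ccn_pattern(self):
        # mirrors the knock-in fallback: no CCA in the window, CCG present
        genome = GenomeRecord(id="g", sequence="T" * 20 + "CCG" + SPACER36 + "T" * 20)
        assert find_candidate_spacers(genome, (0, 79), ["CCA"]) == []
        (cand,) = find_candidate_spacers(genome, (0, 79), ["CCN"])
        assert cand.pam == "CCG"

    def test_minus_strand_coordinates(self):
        insert = revcomp("CCA" + SPACER36)
        genome = GenomeRecord(id="g", sequence="T" * 20 + insert + "T" * 20)
        (cand,) = find_candidate_spacers(genome, (0, len(genome.sequence)), ["CCA"])
        assert cand.strand == "-"
        assert cand.sequence == SPACER36
        assert genome.sequence[cand.start:cand.end] == revcomp(SPACER36)

    def test_revcomp_invariance(self, rng):
        genome = random_genome(rng, 3000)
        n = len(genome.sequence)
        fwd = find_candidate_spacers(genome, (0, n), ["CCA"])
        flipped = GenomeRecord(id="g", sequence=revcomp(genome.sequence))
        rev = find_candidate_spacers(flipped, (0, n), ["CCA"])
        key_fwd = sorted((c.sequence, c.gc) for c in fwd)
        key_rev = sorted((c.sequence, c.gc) for c in rev)
        assert key_fwd == key_rev


class TestSyntheticArray:
    def test_length_arithmetic(self):
        arr = build_synthetic_array("G" * 100, AW_REPEAT, SPACER36)
        assert len(arr) == 100 + 2 * 30 + 36

    def test_exactly_two_repeats(self):
        arr = build_synthetic_array("G" * 100, AW_REPEAT, SPACER36)
        assert arr.count(AW_REPEAT) == 2

    def test_empty_spacer_rejected(self):
        with pytest.raises(ValueError):
            build_synthetic_array("G" * 100, AW_REPEAT, "")

    def test_spacer_equal_to_repeat_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pamflow.design"):
            build_synthetic_array("G" * 100, AW_REPEAT, AW_REPEAT)
        assert "recombination" in caplog.text


class TestEditingTemplate:
    def test_deletion_arm_coordinates(self, rng):
        genome = random_genome(rng)
        design = build_editing_template(
            genome, deletion=(1000, 1300), lha_len=471, rha_len=491
        )
        assert design.lha == genome.sequence[529:1000]
        assert design.rha == genome.sequence[1300:1791]
        assert design.edited_locus == design.lha + design.rha
        assert design.edit_size == 300

    def test_insertion_lengthens_by_cargo(self, rng):
        genome = random_genome(rng)
        cargo = "".join(rng.choice(np.array(list("ACGT")), size=614))
        design = build_editing_template(
            genome, insertion=(2000, cargo), lha_len=500, rha_len=500
        )
        wt_window = genome.sequence[1500:2500]
        assert len(design.edited_locus) - len(wt_window) == 614

    def test_zero_length_deletion_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            build_editing_template(random_genome(rng), deletion=(100, 100),
                                   lha_len=50, rha_len=50)

    def test_arms_off_contig_rejected(self, rng):
        with pytest.raises(ValueError, match="run off"):
            build_editing_template(random_genome(rng), deletion=(100, 200),
                                   lha_len=500, rha_len=50)

    def test_reconstruction_invariant(self, rng):
        for _ in range(10):
            genome = random_genome(rng, 3000)
            s = int(rng.integers(500, 1500))
            e = s + int(rng.integers(1, 500))
            design = build_editing_template(genome, deletion=(s, e),
                                            lha_len=300, rha_len=300)
            window = genome.sequence[s - 300:e + 300]
            rebuilt = window[:300] + window[len(window) - 300:]
            assert design.edited_locus == rebuilt


class TestValidateDesign:
    @pytest.mark.parametrize("size,expect", [(300, True), (354, True),
                                             (561, True), (301, False)])
    def test_in_frame_mod3(self, rng, size, expect):
        genome = random_genome(rng)
        design = build_editing_template(genome, deletion=(1000, 1000 + size),
                                        lha_len=400, rha_len=400)
        flags = validate_design(design, genome, cds_intervals=[(500, 3000)])
        assert flags["in_frame"] is expect

    def test_in_frame_na_without_cds(self, rng):
        genome = random_genome(rng)
        design = build_editing_template(genome, deletion=(1000, 1300),
                                        lha_len=400, rha_len=400)
        assert validate_design(design, genome)["in_frame"] == "n/a"

    def test_deletion_of_spacer_destroys_target(self, rng):
        seq = "T" * 1000 + "CCA" + SPACER36 + "T" * 1000
        genome = GenomeRecord(id="g", sequence=seq)
        design = build_editing_template(genome, deletion=(1000, 1060),
                                        lha_len=400, rha_len=400)
        (cand,) = find_candidate_spacers(genome, (990, 1060), ["CCA"])
        design.spacer = cand
        flags = validate_design(design, genome)
        assert flags["target_destroyed"] is True

    def test_pam_only_removal_destroys_target(self):
        # knock-in in place of the PAM: protospacer remains, PAM replaced
        seq = "T" * 1000 + "CCA" + SPACER36 + "T" * 1000
        genome = GenomeRecord(id="g", sequence=seq)
        (cand,) = find_candidate_spacers(genome, (990, 1060), ["CCA"])
        design = build_editing_template(
            genome, replacement=((1000, 1003), "GGTACCGGTACC"),
            lha_len=400, rha_len=400,
        )
        design.spacer = cand
        flags = validate_design(design, genome)
        assert flags["target_destroyed"] is True
        # the protospacer itself is still present in the edited locus
        assert SPACER36 in design.edited_locus

    def test_intact_target_not_destroyed(self):
        # deletion downstream of the target: PAM+protospacer survive in the LHA
        seq = "T" * 1000 + "CCA" + SPACER36 + "T" * 1000
        genome = GenomeRecord(id="g", sequence=seq)
        (cand,) = find_candidate_spacers(genome, (990, 1060), ["CCA"])
        design = build_editing_template(genome, deletion=(1039, 1339),
                                        lha_len=400, rha_len=200)
        design.spacer = cand
        assert validate_design(design, genome)["target_destroyed"] is False


class TestAmplicons:
    @pytest.mark.parametrize("wt,edited,delta", [
        (2595, 2034, 561),    # pyrE deletion, C. autoethanogenum
        (6353, 3116, 3237),   # hsdR1 deletion
        (3154, 3768, 614),    # FAST knock-in
    ])
    def test_printed_amplicon_deltas(self, wt, edited, delta):
        assert predicted_amplicon_delta(wt, edited) == delta

    def test_consistency_flag(self, rng):
        genome = random_genome(rng)
        design = build_editing_template(genome, deletion=(1000, 1561),
                                        lha_len=400, rha_len=400)
        pred = check_amplicons(design, 2595, 2034)
        assert pred["consistent"] is True
        pred = check_amplicons(design, 2595, 2035)
        assert pred["consistent"] is False


class TestRmScan:
    def test_planted_exact_site(self):
        scan = scan_rm_sites("TAAGACGTATCC")
        assert scan.count == 1
        assert scan.positions == (0,) and scan.strands == ("+",)

    def test_three_planted_sites(self, rng):
        site = "TAAGACGTATCC"
        seq = ("T" * 50).join([site, site, site])
        scan = scan_rm_sites("A" * 20 + seq + "A" * 20)
        assert scan.count == 3

    def test_random_sequence_vs_regex_oracle(self, rng):
        seq = "".join(rng.choice(np.array(list("ACGT")), size=10000))
        scan = scan_rm_sites(seq)
        pat = r"(?=TAAG[ACGT]{5}TCC)"
        rc_pat = r"(?=GGA[ACGT]{5}CTTA)"
        expected = len(re.findall(pat, seq)) + len(re.findall(rc_pat, seq))
        assert scan.count == expected

    def test_strand_symmetry(self, rng):
        seq = "".join(rng.choice(np.array(list("ACGT")), size=5000))
        assert scan_rm_sites(seq).count == scan_rm_sites(revcomp(seq)).count

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_rm_sites("ACGT", motif="TAAGQTCC")


class TestPfaffl:
    @pytest.mark.parametrize("cpt,cpr,expect", [(20, 20, 1.0), (19, 20, 2.0),
                                                (20, 23, 8.0)])
    def test_closed_forms(self, cpt, cpr, expect):
        q = QuantInput(E_target=2.0, E_reference=2.0,
                       Cp_target=cpt, Cp_reference=cpr)
        assert pfaffl_expression(q) == pytest.approx(expect)

    def test_efficiency_bounds(self):
        with pytest.raises(ValueError, match="E_target"):
            QuantInput(E_target=1.0, E_reference=2.0, Cp_target=20, Cp_reference=20)
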
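"""Windowed spacer search, flank extraction and tabular import."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracle import brute_force_search, hit_tuples, naive_mismatches, random_fixture, rc
from pamflow._seq import revcomp
from pamflow.model import GenomeRecord, SearchParams
from pamflow.search import (
    count_mismatches,
    extract_flanks,
    import_tabular_hits,
    search_spacers,
)

SPACER30 = "ACGTTGCAGGCTAATCGTCAGGCATTGACT"  # 30 nt, 50% GC


def _mutate(seq, positions_1based):
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    chars = list(seq)
    for p in positions_1based:
        chars[p - 1] = flip[chars[p - 1]]
    return "".join(chars)


class TestCountMismatches:
    def test_identity(self):
        assert count_mismatches(SPACER30, SPACER30) == (0, [])

    def test_single_substitution_position(self):
        assert count_mismatches("ACGTACGT", "ACGAACGT") == (1, [4])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_mismatches("ACGT", "ACG")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_character_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGTN"))
        L = int(rng.integers(5, 40))
        a = "".join(rng.choice(bases, size=L))
        b = "".join(rng.choice(bases, size=L))
        count, positions = count_mismatches(a, b)
        assert positions == naive_mismatches(a, b)
        assert count == len(positions)

    def test_n_wildcard_policy(self):
        assert count_mismatches("ANGT", "ACGT", n_policy="wildcard") == (0, [])
        assert count_mismatches("ANGT", "ACGT", n_policy="mismatch") == (1, [2])


class TestSearchSpacers:
    def test_planted_identity_single_hit(self, params):
        subject = GenomeRecord(id="s", sequence="T" * 20 + SPACER30 + "T" * 20)
        (hit,) = search_spacers([("sp", SPACER30)], [subject], params)
        assert hit.strand == "+"
        assert hit.interval == (20, 50)
        assert hit.mismatch_count == 0

    def test_global_boundary_strict(self, params):
        # 6/30 = exactly 20% -> rejected; 5/30 -> kept
        six = _mutate(SPACER30, [8, 11, 15, 20, 25, 30])
        five = _mutate(SPACER30, [8, 11, 15, 20, 25])
        subj6 = GenomeRecord(id="a", sequence="T" * 15 + six + "T" * 15)
        subj5 = GenomeRecord(id="b", sequence="T" * 15 + five + "T" * 15)
        assert search_spacers([("sp", SPACER30)], [subj6], params) == []
        (hit,) = search_spacers([("sp", SPACER30)], [subj5], params)
        assert hit.mismatch_count == 5
        assert hit.mismatch_positions == [8, 11, 15, 20, 25]

    def test_seed_rule_overrides_global(self, params):
        # 2 mismatches at protospacer positions 2 and 5: passes 20%, fails seed
        planted = _mutate(SPACER30, [2, 5])
        subject = GenomeRecord(id="s", sequence="T" * 15 + planted + "T" * 15)
        assert search_spacers([("sp", SPACER30)], [subject], params) == []

    def test_one_seed_mismatch_allowed(self, params):
        planted = _mutate(SPACER30, [2])
        subject = GenomeRecord(id="s", sequence="T" * 15 + planted + "T" * 15)
        (hit,) = search_spacers([("sp", SPACER30)], [subject], params)
        assert hit.mismatch_positions == [2]

    def test_reverse_complement_plant(self, params):
        pam5 = "GGCCA"
        prefix, suffix = "T" * 12, "T" * 13
        subject_seq = prefix + revcomp(pam5 + SPACER30) + suffix
        assert len(subject_seq) == 60
        subject = GenomeRecord(id="s", sequence=subject_seq)
        (hit,) = search_spacers([("sp", SPACER30)], [subject], params)
        assert hit.strand == "-"
        assert hit.mismatch_count == 0
        # flank read in protospacer orientation = the 5 nt 5' of the plant
        assert hit.upstream_flank == pam5

    def test_short_spacer_rejected(self, params):
        with pytest.raises(ValueError, match="seed_length"):
            search_spacers([("sp", "ACGT")], [GenomeRecord(id="s", sequence="A" * 50)], params)

    def test_self_exclusion(self, params):
        subject = GenomeRecord(id="host", sequence="T" * 20 + SPACER30 + "T" * 20)
        hits = search_spacers(
            [("sp", SPACER30)], [subject], params,
            exclude={"host": [(10, 60)]},
        )
        assert hits == []


class TestExtractFlanks:
    def test_plus_strand_arithmetic(self):
        seq = "".join("ACGT"[i % 4] for i in range(60))
        subject = GenomeRecord(id="s", sequence=seq)
        up, down, trunc = extract_flanks(subject, (10, 40), "+", 5, 5)
        assert up == seq[5:10]
        assert down == seq[40:45]
        assert not trunc

    def test_minus_strand_is_revcomp_of_following(self):
        seq = "AAAAACCCCCGGGGGTTTTTACGTACGTAC"
        subject = GenomeRecord(id="s", sequence=seq)
        up, down, trunc = extract_flanks(subject, (5, 15), "-", 5, 5)
        assert up == revcomp(seq[15:20])
        assert down == revcomp(seq[0:5])
        assert not trunc

    def test_edge_truncation(self):
        subject = GenomeRecord(id="s", sequence="ACGTACGTACGT")
        up, down, trunc = extract_flanks(subject, (2, 8), "+", 5, 5)
        assert up == "AC" and trunc


class TestTabularImport:
    def _subject(self):
        return GenomeRecord(
            id="s1", title="phage fixture",
            sequence="T" * 10 + SPACER30 + "A" * 20,
        )

    def test_matches_internal_search(self, tmp_path, params):
        subject = self._subject()
        row = "sp1\ts1\t100.00\t30\t0\t0\t1\t30\t11\t40\t1e-12\t60.0\n"
        p = tmp_path / "hits.tsv"
        p.write_text(row)
        imported = import_tabular_hits(p, [("sp1", SPACER30)], [subject], params)
        internal = search_spacers([("sp1", SPACER30)], [subject], params)
        assert hit_tuples(imported) == hit_tuples(internal)

    def test_minus_strand_row(self, tmp_path, params):
        seq = "T" * 10 + revcomp(SPACER30) + "A" * 20
        subject = GenomeRecord(id="s1", sequence=seq)
        row = "sp1\ts1\t100.00\t30\t0\t0\t1\t30\t40\t11\t1e-12\t60.0\n"
        p = tmp_path / "hits.tsv"
        p.write_text(row)
        (hit,) = import_tabular_hits(p, [("sp1", SPACER30)], [subject], params)
        assert hit.strand == "-"
        assert hit.interval == (10, 40)
        assert hit.mismatch_count == 0

    def test_gapped_row_dropped_under_forbid(self, tmp_path, params):
        row = "sp1\ts1\t96.00\t31\t0\t1\t1\t30\t11\t41\t1e-9\t50.0\n"
        p = tmp_path / "hits.tsv"
        p.write_text(row)
        assert import_tabular_hits(p, [("sp1", SPACER30)], [self._subject()], params) == []

    def test_partial_query_rejected(self, tmp_path, params):
        row = "sp1\ts1\t100.00\t28\t0\t0\t3\t30\t13\t40\t1e-9\t50.0\n"
        p = tmp_path / "hits.tsv"
        p.write_text(row)
        assert import_tabular_hits(p, [("sp1", SPACER30)], [self._subject()], params) == []

    def test_unknown_subject_errors(self, tmp_path, params):
        p = tmp_path / "hits.tsv"
        p.write_text("sp1\tnope\t100.00\t30\t0\t0\t1\t30\t11\t40\t1e-9\t50.0\n")
        with pytest.raises(ValueError, match="nope"):
            import_tabular_hits(p, [("sp1", SPACER30)], [self._subject()], params)

    def test_malformed_row_names_line(self, tmp_path, params):
        p = tmp_path / "hits.tsv"
        p.write_text("only\tthree\tcols\n")
        with pytest.raises(ValueError, match=":1"):
            import_tabular_hits(p, [("sp1", SPACER30)], [self._subject()], params)


class TestProperties:
    def test_oracle_equivalence_small(self, params):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            items, subjects = random_fixture(rng, subject_len=800)
            got = hit_tuples(search_spacers(items, subjects, params))
            expected = brute_force_search(items, subjects, params)
            assert got == expected

    def test_strand_symmetry(self, params):
        rng = np.random.default_rng(7)
        items, subjects = random_fixture(rng, subject_len=1000)
        fwd = search_spacers(items, subjects, params)
        flipped = [
            GenomeRecord(id=s.id, title=s.title, sequence=rc(s.sequence))
            for s in subjects
        ]
        rev = search_spacers(items, flipped, params)
        L = {s.id: len(s.sequence) for s in subjects}

        def key(h, mirror):
            strand, (a, b) = h.strand, h.interval
            if mirror:
                strand = "-" if strand == "+" else "+"
                a, b = L[h.subject_id] - b, L[h.subject_id] - a
            return (h.spacer_id, h.subject_id, strand, a, b,
                    h.mismatch_count, tuple(h.mismatch_positions),
                    h.upstream_flank, h.downstream_flank)

        assert sorted(key(h, False) for h in fwd) == sorted(key(h, True) for h in rev)

    def test_monotonicity_of_filters(self):
        rng = np.random.default_rng(11)
        items, subjects = random_fixture(rng, subject_len=1000)
        loose = SearchParams(max_mismatch_fraction=0.30, max_seed_mismatches=2)
        tight = SearchParams(max_mismatch_fraction=0.15, max_seed_mismatches=0)
        big = {(h.spacer_id, h.subject_id, h.strand, h.interval)
               for h in search_spacers(items, subjects, loose)}
        small = {(h.spacer_id, h.subject_id, h.strand, h.interval)
                 for h in search_spacers(items, subjects, tight)}
        assert small <= big
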
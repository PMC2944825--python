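import numpy as np
import pytest

from conftest import make_profile, random_pattern, random_sequence
from oracles import brute_force_profile, brute_force_scan, pattern_expansion_count

from domainsnp import domain_scan as ds
from domainsnp.io_formats import AA_INDEX, ProteinRecord


class TestParsePattern:
    def test_full_grammar_example(self):
        p = ds.parse_pattern("[AC]-x-V-x(4)-{ED}.")
        kinds = [(e.kind, e.min_repeat, e.max_repeat) for e in p.elements]
        assert kinds == [
            ("any_of", 1, 1),
            ("wildcard", 1, 1),
            ("exact", 1, 1),
            ("wildcard", 4, 4),
            ("none_of", 1, 1),
        ]
        assert p.elements[0].residues == {"A", "C"}
        assert p.elements[4].residues == {"E", "D"}
        assert not p.n_anchor and not p.c_anchor

    def test_anchors_and_ranges(self):
        p = ds.parse_pattern("<M-x(2,3)-D")
        assert p.n_anchor and not p.c_anchor
        assert [(e.kind, e.min_repeat, e.max_repeat) for e in p.elements] == [
            ("exact", 1, 1),
            ("wildcard", 2, 3),
            ("exact", 1, 1),
        ]
        q = ds.parse_pattern("A-x>")
        assert q.c_anchor

    @pytest.mark.parametrize(
        "bad",
        ["[]-A", "[AC", "{ACDEFGHIKLMNPQRSTVWY}", "A-x(3,2)", "A-B-Z9", "x(0,0)",
         "A--B", "A-", ""],
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(ds.PatternSyntaxError):
            ds.parse_pattern(bad)

    def test_error_reports_column(self):
        with pytest.raises(ds.PatternSyntaxError, match="column 3"):
            ds.parse_pattern("A-9")

    def test_format_round_trip_random(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_pattern(rng)
            text = ds.format_pattern(p)
            q = ds.parse_pattern(text)
            assert q.elements == p.elements
            assert (q.n_anchor, q.c_anchor) == (p.n_anchor, p.c_anchor)


class TestScanPattern:
    def test_basic_match(self):
        p = ds.parse_pattern("[AC]-x-V-x(4)-{ED}")
        assert ds.scan_pattern(p, "CPVAAAAH") == [(1, 8)]

    def test_n_anchor_blocks_offset_match(self):
        p = ds.parse_pattern("<M-x(2)-D")
        assert ds.scan_pattern(p, "AMKAD") == []
        assert ds.scan_pattern(p, "MKAD") == [(1, 4)]

    def test_no_match(self):
        assert ds.scan_pattern(ds.parse_pattern("F"), "AAA") == []

    def test_overlapping_starts_reported(self):
        p = ds.parse_pattern("A-A")
        assert ds.scan_pattern(p, "AAAA") == [(1, 2), (2, 3), (3, 4)]

    def test_greedy_longest_per_start(self):
        p = ds.parse_pattern("A(1,3)-G")
        assert ds.scan_pattern(p, "AAAG") == [(1, 4), (2, 4), (3, 4)]

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(20)
        checked = 0
        for _ in range(400):
            p = random_pattern(rng)
            if pattern_expansion_count(p) > 10_000:
                continue
            seq = random_sequence(rng, 1, 20)
            assert ds.scan_pattern(p, seq) == brute_force_scan(p, seq)
            checked += 1
        assert checked >= 300


class TestProfileScore:
    def test_spec_examples(self):
        scores = np.full((2, 20), -2.0)
        scores[0, AA_INDEX["A"]] = 2
        scores[1, AA_INDEX["G"]] = 3
        pr = ds.ProfileDefinition("T", scores, -4.0, -1.0, 1.0)
        assert ds.profile_score(pr, "AG") == (5.0, (1, 2))
        assert ds.profile_score(pr, "AAG") == (5.0, (2, 3))
        single = np.full((1, 20), -1.0)
        single[0, AA_INDEX["M"]] = 1
        pr1 = ds.ProfileDefinition("T1", single, -2.0, -1.0, 0.5)
        assert ds.profile_score(pr1, "M") == (1.0, (1, 1))

    def test_negative_best_score_allowed(self):
        scores = np.full((1, 20), -3.0)
        pr = ds.ProfileDefinition("T", scores + 0.0, -4.0, -1.0, 1.0)
        best, span = ds.profile_score(pr, "AA")
        assert best == -3.0 and span == (1, 1)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(120):
            L = int(rng.integers(1, 6))
            n = int(rng.integers(1, 9))
            # quarter-integer scores keep float sums exact in binary
            scores = rng.integers(-12, 13, size=(L, 20)) / 4.0
            gap_open = -float(rng.integers(0, 13)) / 4.0
            gap_extend = gap_open / 2.0
            seq = random_sequence(rng, n, n)
            pr = ds.ProfileDefinition("R", scores, gap_open, gap_extend, 1.0)
            got = ds.profile_score(pr, seq)
            want = brute_force_profile(scores.tolist(), seq, gap_open, gap_extend)
            assert got[0] == want[0] and got[1] == want[1]

    def test_monotone_under_extension(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            L = int(rng.integers(1, 5))
            scores = rng.integers(-8, 9, size=(L, 20)) / 2.0
            pr = ds.ProfileDefinition("R", scores, -4.0, -2.0, 1.0)
            seq = random_sequence(rng, 1, 10)
            base, _ = ds.profile_score(pr, seq)
            ext, _ = ds.profile_score(pr, seq + random_sequence(rng, 1, 5))
            assert ext >= base


class TestScanProteome:
    def test_pattern_and_profile_hits(self, toy_universe):
        matches = ds.scan_proteome(toy_universe["domains"], toy_universe["proteome"])
        key = [(m.protein_id, m.domain_id, m.start, m.end, m.kind) for m in matches]
        assert key == [
            ("P1", "DPAT", 2, 5, "pattern"),
            ("P2", "DPRO", 3, 5, "profile"),
            ("P3", "DPRO", 1, 3, "profile"),
        ]
        assert matches[1].matching_score == 12.0

    def test_cutoff_inclusive(self):
        pr = make_profile("D", "AC", high=4.0, cutoff=8.0)
        matches = ds.scan_proteome([pr], [ProteinRecord("P1", "GACG")])
        assert len(matches) == 1 and matches[0].matching_score == 8.0

    def test_empty_domain_list(self, toy_universe):
        assert ds.scan_proteome([], toy_universe["proteome"]) == []

    def test_order_independent(self, toy_universe):
        a = ds.scan_proteome(toy_universe["domains"], toy_universe["proteome"])
        b = ds.scan_proteome(
            list(reversed(toy_universe["domains"])),
            list(reversed(toy_universe["proteome"])),
        )
        assert a == b


class TestDomainFileDialect:
    def test_round_trip(self, tmp_path, toy_universe):
        path = tmp_path / "domains.txt"
        ds.write_domains(toy_universe["domains"], path)
        back = ds.read_domains(path)
        assert len(back) == 2
        pat, pro = back
        assert pat.elements == toy_universe["pattern"].elements
        assert np.array_equal(pro.scores, toy_universe["profile"].scores)
        assert pro.gap_open == toy_universe["profile"].gap_open
        assert pro.cutoff == toy_universe["profile"].cutoff

    def test_matches_round_trip(self, tmp_path, toy_universe):
        matches = ds.scan_proteome(toy_universe["domains"], toy_universe["proteome"])
        path = tmp_path / "matches.tsv"
        ds.write_matches(matches, path)
        assert ds.read_matches(path) == matches
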
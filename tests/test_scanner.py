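import numpy as np
import pytest

from pacfinder import scanner
from pacfinder.io_formats import ProteinRecord

from _oracles import regex_scan


def rec(seq, rid="r"):
    return ProteinRecord(id=rid, sequence=seq)


def compliant_domain():
    """Minimal strict domain: every variable spacer at its lower bound."""
    return ("G" + "AAA" + "C" + "AA" + "C" + "A" * 10 + "C" + "A" * 20 + "C"
            + "A" * 8 + "C" + "A" * 25 + "C")


class TestScanStrict:
    def test_no_cys_no_match(self):
        assert scanner.scan_strict(rec("A" * 200)) == []

    def test_constructed_minimal_domain(self):
        ms = scanner.scan_strict(rec(compliant_domain()))
        assert len(ms) == 1
        m = ms[0]
        assert m.span == (0, 75)
        assert tuple(c - m.gly_pos for c in m.cys_pos) == (4, 7, 18, 39, 48, 74)
        assert m.spacer_lengths == (2, 10, 20, 8, 25)
        assert m.cys_in_span == 6 and m.violations == []

    def test_spacer_below_minimum_rejected(self):
        seq = ("G" + "AAA" + "C" + "AA" + "C" + "A" * 10 + "C" + "A" * 19 + "C"
               + "A" * 8 + "C" + "A" * 25 + "C")
        assert scanner.scan_strict(rec(seq)) == []

    def test_ps00925_prefix_instance(self):
        # an instance of the pollen Ole e 1 consensus extended with a
        # minimally compliant Cys-free tail
        seq = "EGAVYCDTCR" + "A" * 9 + "C" + "A" * 20 + "C" + "A" * 8 + "C" + "A" * 25 + "C"
        ms = scanner.scan_strict(rec(seq))
        assert len(ms) == 1
        assert ms[0].gly_pos == 1
        assert ms[0].cys_pos[0] == 5 and ms[0].cys_pos[1] == 8

    def test_stop_codon_is_a_wall(self):
        seq = compliant_domain().replace("A" * 25, "A" * 12 + "*" + "A" * 12, 1)
        assert scanner.scan_strict(rec(seq)) == []

    def test_x_never_matches_anchor_but_allowed_in_spacer(self):
        seq = compliant_domain()
        assert scanner.scan_strict(rec(seq.replace("G", "X", 1))) == []
        softened = seq[:2] + "X" + seq[3:]  # X inside the Gly-Cys1 spacer
        assert len(scanner.scan_strict(rec(softened))) == 1

    def test_matches_ordered_left_to_right(self):
        two = compliant_domain() + "AAA" + compliant_domain()
        ms = scanner.scan_strict(rec(two))
        assert [m.span[0] for m in ms] == sorted(m.span[0] for m in ms)
        assert len(ms) == 2

    def test_oracle_equivalence_random(self, random_protein):
        """Strict scanning equals the regex oracle on random sequences."""
        for _ in range(400):
            seq = random_protein(int(np.random.default_rng(None).integers(50, 300)), 0.06)
            mine = {m.span for m in scanner.scan_strict(rec(seq))}
            assert mine == regex_scan(seq, scanner.DEFAULT_RULE)

    def test_oracle_equivalence_planted(self, rng):
        """Equivalence also holds around planted, boundary-straddling
        domains under perturbed rules."""
        aa19 = np.array(list("ARNDQEGHILKMFPSTWYV"))
        for _ in range(10):
            rule = perturbed_rule(rng)
            for _ in range(40):
                seq = planted_sequence(rng, rule, aa19)
                mine = {m.span for m in scanner.scan_strict(rec(seq), rule)}
                assert mine == regex_scan(seq, rule)

    def test_monotonicity_of_gap_widening(self, rng):
        aa19 = np.array(list("ARNDQEGHILKMFPSTWYV"))
        base = scanner.DEFAULT_RULE
        wider = scanner.PacSpacingRule(gap_c2_c3=(8, 32), gap_c3_c4=(18, 52),
                                       gap_c4_c5=(6, 22), gap_c5_c6=(23, 62))
        narrower = scanner.PacSpacingRule(gap_c2_c3=(12, 28), gap_c3_c4=(22, 48),
                                          gap_c4_c5=(10, 18), gap_c5_c6=(27, 58))
        for _ in range(60):
            seq = planted_sequence(rng, base, aa19)
            got_base = {m.span for m in scanner.scan_strict(rec(seq), base)}
            got_wide = {m.span for m in scanner.scan_strict(rec(seq), wider)}
            got_narrow = {m.span for m in scanner.scan_strict(rec(seq), narrower)}
            assert got_base <= got_wide
            assert got_narrow <= got_base

    def test_span_lengths_within_min_max(self, rng):
        aa19 = np.array(list("ARNDQEGHILKMFPSTWYV"))
        lo, hi = scanner.min_max_span()
        for _ in range(80):
            seq = planted_sequence(rng, scanner.DEFAULT_RULE, aa19)
            for m in scanner.scan_strict(rec(seq)):
                assert lo <= m.span[1] - m.span[0] <= hi


def perturbed_rule(rng):
    def rng_pair(lo_lo, hi_hi):
        a, b = sorted(int(x) for x in rng.integers(lo_lo, hi_hi, 2))
        return (a, b)

    return scanner.PacSpacingRule(
        gap_c2_c3=rng_pair(5, 35), gap_c3_c4=rng_pair(12, 55),
        gap_c4_c5=rng_pair(4, 25), gap_c5_c6=rng_pair(18, 65))


def planted_sequence(rng, rule, aa19):
    """A quasi-domain whose gaps straddle the rule bounds, with light Cys
    contamination, between random flanks."""
    parts = ["".join(rng.choice(aa19, size=int(rng.integers(0, 25))))]
    parts.append("G")
    for lo, hi in rule.all_bounds():
        if lo == hi:
            g = lo if rng.random() < 0.7 else int(rng.integers(max(0, lo - 3), hi + 4))
        else:
            g = int(rng.integers(max(0, lo - 4), hi + 5))
        sp = rng.choice(aa19, size=g)
        mask = rng.random(g) < 0.01
        parts.append("".join(np.where(mask, "C", sp)))
        parts.append("C")
    parts.append("".join(rng.choice(aa19, size=int(rng.integers(0, 25)))))
    return "".join(parts)


class TestMinMaxSpan:
    def test_default_rule(self):
        assert scanner.min_max_span(scanner.DEFAULT_RULE) == (75, 172)

    def test_collapsed_ranges_degenerate(self):
        rule = scanner.PacSpacingRule(gap_c2_c3=(10, 10), gap_c3_c4=(20, 20),
                                      gap_c4_c5=(8, 8), gap_c5_c6=(25, 25))
        lo, hi = scanner.min_max_span(rule)
        assert lo == hi == 75

    def test_single_range_collapse_arithmetic(self):
        rule = scanner.PacSpacingRule(gap_c2_c3=(10, 10))
        assert scanner.min_max_span(rule) == (75, 152)

    def test_exhaustive_boundary_enumeration(self):
        """min/max equal the extremes over all corner spacings."""
        import itertools

        rule = scanner.DEFAULT_RULE
        base = 7 + rule.gap_gly_c1 + rule.gap_c1_c2
        spans = [base + sum(combo) for combo in
                 itertools.product(*[(lo, hi) for lo, hi in rule.ranged_gaps()])]
        assert (min(spans), max(spans)) == scanner.min_max_span(rule)


class TestScanRelaxed:
    def test_strict_subset_of_relaxed(self):
        r = rec(compliant_domain())
        strict = scanner.scan_strict(r)
        relaxed = scanner.scan_relaxed(r, tolerances=scanner.RelaxedTolerances(
            allow_missing_gly=True, max_extra_cys=2, allow_missing_cys=True, gap_slack=3))
        keys = {m.key() for m in relaxed}
        assert strict[0].key() in keys
        reproduced = next(m for m in relaxed if m.key() == strict[0].key())
        assert reproduced.violations == []

    def test_extra_cys_in_spacer_reported(self):
        seq = list(compliant_domain())
        # plant a surplus Cys 5 residues into the Cys5–Cys6 spacer
        seq[49 + 5] = "C"
        r = rec("".join(seq))
        assert scanner.scan_strict(r) == []
        ms = scanner.scan_relaxed(r, tolerances=scanner.RelaxedTolerances(max_extra_cys=1))
        full = [m for m in ms if "extra_cys_in_spacer" in m.violations and m.cys_in_span == 7]
        assert len(full) == 1
        assert full[0].span == (0, 75)

    def test_missing_gly_admitted(self):
        seq = "A" + compliant_domain()[1:]
        r = rec(seq)
        assert scanner.scan_strict(r) == []
        ms = scanner.scan_relaxed(r, tolerances=scanner.RelaxedTolerances(allow_missing_gly=True))
        assert len(ms) == 1
        m = ms[0]
        assert m.gly_pos is None
        assert m.violations == ["missing_gly"]
        assert m.span == (4, 75)  # Cys1..Cys6

    def test_missing_interior_cys_admitted(self):
        seq = list(compliant_domain())
        seq[18] = "S"  # remove Cys3
        r = rec("".join(seq))
        assert scanner.scan_strict(r) == []
        ms = scanner.scan_relaxed(r, tolerances=scanner.RelaxedTolerances(allow_missing_cys=True))
        assert any(m.violations == ["missing_cys"] and None in m.cys_pos for m in ms)

    def test_gap_slack_flags_out_of_bounds(self):
        seq = ("G" + "AAA" + "C" + "AA" + "C" + "A" * 9 + "C" + "A" * 20 + "C"
               + "A" * 8 + "C" + "A" * 25 + "C")
        r = rec(seq)
        assert scanner.scan_strict(r) == []
        ms = scanner.scan_relaxed(r, tolerances=scanner.RelaxedTolerances(gap_slack=1))
        assert len(ms) == 1
        assert ms[0].violations == ["gap_out_of_bounds:c2_c3"]

    def test_tolerance_limits_enforced(self):
        with pytest.raises(ValueError):
            scanner.RelaxedTolerances(max_extra_cys=4)
        with pytest.raises(ValueError):
            scanner.RelaxedTolerances(gap_slack=-1)

    def test_determinism(self, random_protein):
        r = rec(random_protein(300, 0.08))
        tol = scanner.RelaxedTolerances(allow_missing_gly=True, max_extra_cys=2,
                                        allow_missing_cys=True, gap_slack=4)
        first = scanner.scan_relaxed(r, tolerances=tol)
        second = scanner.scan_relaxed(r, tolerances=tol)
        assert [(m.key(), tuple(m.violations)) for m in first] == \
               [(m.key(), tuple(m.violations)) for m in second]
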
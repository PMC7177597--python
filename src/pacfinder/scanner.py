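"""Constrained motif scanner for the PAC domain cysteine scaffold.

A bona fide PAC domain is six Cys residues downstream of a Gly anchor with
a defined spacing: Gly (3) Cys1 (2) Cys2 (10,30) Cys3 (20,50) Cys4 (8,20)
Cys5 (25,60) Cys6, where the bracketed numbers count residues *between*
successive anchors. Strict mode enforces exactly that pattern with
Cys-free spacers; relaxed mode admits named deviations (missing Gly, extra
Cys inside spacers, one missing interior Cys, per-gap slack) and reports
them as violations, which is how 5-, 7- up to 9-Cys variants and the
Gly-less ancestral candidates are surfaced.

'*' (stop, from noisy transcriptome frames) is a hard wall: no match may
span it. 'X' never matches an anchor but is allowed inside spacers.
Positions are 0-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

log = logging.getLogger(__name__)

MAX_CHAINS_PER_ANCHOR = 64

#: gap k (0-based index) separates anchor k from anchor k+1 in the order
#: Gly, Cys1..Cys6
GAP_NAMES = ("gly_c1", "c1_c2", "c2_c3", "c3_c4", "c4_c5", "c5_c6")


@dataclass(frozen=True)
class PacSpacingRule:
    """Spacing bounds between the Gly anchor and the six Cys residues.

    Exact gaps are single integers, variable gaps (min, max) pairs; all
    values count residues strictly between the two anchors.
    """

    gap_gly_c1: int = 3
    gap_c1_c2: int = 2
    gap_c2_c3: tuple = (10, 30)
    gap_c3_c4: tuple = (20, 50)
    gap_c4_c5: tuple = (8, 20)
    gap_c5_c6: tuple = (25, 60)

    def __post_init__(self):
        if self.gap_gly_c1 < 0 or self.gap_c1_c2 < 0:
            raise ValueError("exact gaps must be >= 0")
        for name, (lo, hi) in zip(GAP_NAMES[2:], self.ranged_gaps()):
            if lo < 0 or lo > hi:
                raise ValueError(f"gap {name}: need 0 <= min <= max, got ({lo}, {hi})")

    def ranged_gaps(self) -> tuple:
        return (self.gap_c2_c3, self.gap_c3_c4, self.gap_c4_c5, self.gap_c5_c6)

    def all_bounds(self) -> list:
        """All six gaps as (lo, hi) pairs, exact gaps collapsed."""
        return [(self.gap_gly_c1, self.gap_gly_c1),
                (self.gap_c1_c2, self.gap_c1_c2),
                *self.ranged_gaps()]


DEFAULT_RULE = PacSpacingRule()


@dataclass
class PacMatch:
    """One scanner hit.

    ``cys_pos`` always has six slots; in relaxed mode a missing Cys is
    ``None`` at its ordinal. ``span`` is half-open and covers Gly..Cys6
    (or Cys1..last Cys when the Gly is absent).
    """

    record_id: str
    gly_pos: Optional[int]
    cys_pos: tuple
    spacer_lengths: tuple
    span: tuple
    cys_in_span: int
    mode: str = "strict"
    violations: list = field(default_factory=list)

    def key(self) -> tuple:
        return (self.gly_pos, self.cys_pos)


@dataclass(frozen=True)
class RelaxedTolerances:
    """Admitted deviations for relaxed scanning.

    ``max_extra_cys`` ≤ 3 surplus Cys inside spacers (7–9 Cys variants);
    ``allow_missing_cys`` admits one absent interior Cys (5-Cys variants);
    ``gap_slack`` widens every gap bound by ±s residues.
    """

    allow_missing_gly: bool = False
    max_extra_cys: int = 0
    allow_missing_cys: bool = False
    gap_slack: int = 0

    def __post_init__(self):
        if not 0 <= self.max_extra_cys <= 3:
            raise ValueError("max_extra_cys must be in 0..3")
        if self.gap_slack < 0:
            raise ValueError("gap_slack must be >= 0")


def min_max_span(rule: PacSpacingRule = DEFAULT_RULE) -> tuple:
    """Tightest and loosest span length (residues, Gly..Cys6 inclusive)."""
    base = 7 + rule.gap_gly_c1 + rule.gap_c1_c2
    lo = base + sum(l for l, _ in rule.ranged_gaps())
    hi = base + sum(h for _, h in rule.ranged_gaps())
    return lo, hi


def _wall_free(seq: str, start: int, end: int) -> bool:
    seg = seq[start:end]
    return "*" not in seg and "-" not in seg


def _clean_spacer(seq: str, start: int, end: int) -> bool:
    return "C" not in seq[start:end] and _wall_free(seq, start, end)


def scan_strict(record, rule: PacSpacingRule = DEFAULT_RULE) -> list[PacMatch]:
    """Find all strict PAC matches, left-to-right by Gly anchor.

    Equivalent to evaluating the oracle pattern G[^C*]{3}C[^C*]{2}
    C[^C*]{10,30}C[^C*]{20,50}C[^C*]{8,20}C[^C*]{25,60}C (default bounds)
    at every start position. With Cys-free spacers the chain after Cys2 is
    forced: the next Cys is the only candidate for each ordinal.
    """
    seq = record.sequence
    rid = record.id
    matches = []
    pos = seq.find("G")
    while pos != -1:
        m = _try_strict_anchor(rid, seq, pos, rule)
        if m is not None:
            matches.append(m)
        pos = seq.find("G", pos + 1)
    return matches


def _try_strict_anchor(rid: str, seq: str, gly: int,
                       rule: PacSpacingRule) -> Optional[PacMatch]:
    c1 = gly + rule.gap_gly_c1 + 1
    c2 = c1 + rule.gap_c1_c2 + 1
    if c2 >= len(seq) or seq[c1] != "C" or seq[c2] != "C":
        return None
    if not (_clean_spacer(seq, gly + 1, c1) and _clean_spacer(seq, c1 + 1, c2)):
        return None
    chain = [c1, c2]
    cur = c2
    for lo, hi in rule.ranged_gaps():
        # first Cys after cur is the only candidate; walls kill the chain
        p = seq.find("C", cur + 1, min(len(seq), cur + hi + 2))
        if p == -1 or not _wall_free(seq, cur + 1, p) or not lo <= p - cur - 1 <= hi:
            return None
        chain.append(p)
        cur = p
    cys_pos = tuple(chain)
    spacers = tuple(b - a - 1 for a, b in zip(cys_pos[:-1], cys_pos[1:]))
    return PacMatch(record_id=rid, gly_pos=gly, cys_pos=cys_pos,
                    spacer_lengths=spacers, span=(gly, cys_pos[-1] + 1),
                    cys_in_span=6, mode="strict", violations=[])


def scan_relaxed(record, rule: PacSpacingRule = DEFAULT_RULE,
                 tolerances: RelaxedTolerances = RelaxedTolerances()) -> list[PacMatch]:
    """Scan admitting the deviations listed in ``tolerances``.

    Strict matches are reproduced with empty violations. Each returned
    match lists the named deviations it needed: ``missing_gly``,
    ``extra_cys_in_spacer``, ``missing_cys``, ``gap_out_of_bounds:<gap>``.
    Depth-first enumeration is capped at 64 chains per anchor (logged).
    """
    seq = record.sequence
    rid = record.id
    tol = tolerances
    bounds = rule.all_bounds()
    s = tol.gap_slack
    offset = rule.gap_gly_c1 + 1

    matches: list[PacMatch] = []
    seen: set = set()
    for p, ch in enumerate(seq):
        if ch != "C":
            continue
        g = p - offset
        has_gly = g >= 0 and seq[g] == "G" and _wall_free(seq, g + 1, p)
        anchors = []
        if has_gly:
            n_extra = seq.count("C", g + 1, p)
            if n_extra <= tol.max_extra_cys:
                anchors.append((g, n_extra))
        if tol.allow_missing_gly and not has_gly:
            anchors.append((None, 0))
        for gly, extras0 in anchors:
            out: list[PacMatch] = []
            _extend(rid, seq, tol, bounds, gly, {1: p}, 2, extras0, None, [], out)
            if len(out) >= MAX_CHAINS_PER_ANCHOR:
                log.warning("relaxed enumeration truncated at anchor %s:%d", rid, p)
            for m in out:
                if m.key() not in seen:
                    seen.add(m.key())
                    matches.append(m)
    matches.sort(key=lambda m: (m.span[0],
                                tuple(-1 if c is None else c for c in m.cys_pos)))
    return matches


def _extend(rid, seq, tol, bounds, gly, assign, next_ord, extras,
            missing_ord, gap_viols, out) -> None:
    """DFS over Cys-ordinal assignments.

    ``assign`` maps ordinal (1..6) → sequence position; ``missing_ord`` is
    the single skipped ordinal, if any.
    """
    if len(out) >= MAX_CHAINS_PER_ANCHOR:
        return
    if next_ord == 7:
        out.append(_emit(rid, seq, gly, assign, extras, missing_ord, gap_viols))
        return
    prev_ord = max(assign)
    cur = assign[prev_ord]
    s = tol.gap_slack
    # gap bounds from prev_ord to next_ord; a skipped ordinal in between
    # merges the two flanking gaps plus one residue for the absent Cys
    if next_ord == prev_ord + 1:
        lo, hi = bounds[next_ord - 1]
        name = GAP_NAMES[next_ord - 1]
    else:
        (lo1, hi1), (lo2, hi2) = bounds[prev_ord], bounds[next_ord - 1]
        lo, hi = lo1 + lo2 + 1, hi1 + hi2 + 1
        name = GAP_NAMES[prev_ord] + "+" + GAP_NAMES[next_ord - 1]
    lo_s, hi_s = max(0, lo - s), hi + s
    n_extra = 0
    for p in range(cur + 1, min(len(seq), cur + hi_s + 2)):
        ch = seq[p]
        if ch in "*-":
            break
        if ch != "C":
            continue
        gap = p - cur - 1
        if gap > hi_s:
            break
        if gap < lo_s:
            n_extra += 1
            if extras + n_extra > tol.max_extra_cys:
                break
            continue
        if extras + n_extra <= tol.max_extra_cys:
            viols = list(gap_viols)
            if not lo <= gap <= hi:
                viols.append(f"gap_out_of_bounds:{name}")
            new_assign = dict(assign)
            new_assign[next_ord] = p
            _extend(rid, seq, tol, bounds, gly, new_assign, next_ord + 1,
                    extras + n_extra, missing_ord, viols, out)
        n_extra += 1  # treating this Cys as a spacer extra and moving on
        if extras + n_extra > tol.max_extra_cys:
            break
    if tol.allow_missing_cys and missing_ord is None and 2 <= next_ord <= 5:
        _extend(rid, seq, tol, bounds, gly, assign, next_ord + 1, extras,
                next_ord, gap_viols, out)


def _emit(rid, seq, gly, assign, extras, missing_ord, gap_viols) -> PacMatch:
    violations = []
    if gly is None:
        violations.append("missing_gly")
    if extras > 0:
        violations.append("extra_cys_in_spacer")
    if missing_ord is not None:
        violations.append("missing_cys")
    violations.extend(gap_viols)
    cys_pos = tuple(assign.get(k) for k in range(1, 7))
    chain = [p for p in cys_pos if p is not None]
    start = gly if gly is not None else chain[0]
    span = (start, chain[-1] + 1)
    mode = "relaxed"
    return PacMatch(record_id=rid, gly_pos=gly, cys_pos=cys_pos,
                    spacer_lengths=tuple(b - a - 1 for a, b in zip(chain[:-1], chain[1:])),
                    span=span, cys_in_span=seq.count("C", span[0], span[1]),
                    mode=mode, violations=sorted(set(violations)))
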
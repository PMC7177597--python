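"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: the scanner
oracle is a backtracking regular expression, the alignment oracle a plain
dict-free pure-Python Gotoh following the documented tie-break policy,
and the PROSITE oracle expands variable-length elements into fixed-length
regular expressions.
"""

from __future__ import annotations

import re


# ---------------------------------------------------------------------------
# scanner oracle


def strict_regex(rule) -> re.Pattern:
    pattern = ("G" + "[^C*]{%d}" % rule.gap_gly_c1 + "C"
               + "[^C*]{%d}" % rule.gap_c1_c2 + "C"
               + "".join("[^C*]{%d,%d}C" % (lo, hi) for lo, hi in rule.ranged_gaps()))
    return re.compile("(?=(%s))" % pattern)


def regex_scan(seq: str, rule) -> set:
    """All (start, end) spans the strict rule admits, via regex."""
    rx = strict_regex(rule)
    return {(m.start(), m.start() + len(m.group(1))) for m in rx.finditer(seq)}


# ---------------------------------------------------------------------------
# alignment oracle (pure-Python Gotoh, free end gaps)

NEG = float("-inf")


def blosum62_scores() -> dict:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    scores = {}
    for a in blosum.alphabet:
        for b in blosum.alphabet:
            scores[a, b] = 0.0 if (a in "X*" or b in "X*") else float(blosum[a, b])
    return scores


_SC = blosum62_scores()


def align_oracle(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5):
    """Global affine-gap alignment with free terminal gaps.

    Returns (score, identity_pct, similarity_pct, length, gaps). Ties are
    broken diagonal, then up (gap in b), then left (gap in a), with the
    final cell chosen as the first strict maximum scanning the last
    column top-down and then the last row left-to-right.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _SC.get((a[i - 1], b[j - 1]), 0.0)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend)

    best, best_cell = NEG, None
    for i in range(n + 1):
        for state, mat in ((0, M), (1, X), (2, Y)):
            if mat[i][m] > best:
                best, best_cell = mat[i][m], (i, m, state)
    for j in range(m + 1):
        for state, mat in ((0, M), (1, X), (2, Y)):
            if mat[n][j] > best:
                best, best_cell = mat[n][j], (n, j, state)

    i, j, state = best_cell
    cols = []
    cols.extend((a[k], "-") for k in range(len(a) - 1, i - 1, -1))
    cols.extend(("-", b[k]) for k in range(len(b) - 1, j - 1, -1))
    while i > 0 or j > 0:
        if state == 0:
            prev = _arg3(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif state == 1:
            # column 0 holds assigned free-leading-gap scores, not computed ones
            prev = _x_edge(i) if j == 0 else _arg3(
                M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend, Y[i - 1][j] - gap_open)
            cols.append((a[i - 1], "-"))
            i -= 1
        else:
            prev = _y_edge(j) if i == 0 else _arg3(
                M[i][j - 1] - gap_open, X[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            cols.append(("-", b[j - 1]))
            j -= 1
        state = prev
    cols.reverse()
    length = len(cols)
    ident = sim = gaps = 0
    for x, y in cols:
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y and x not in "X*":
            ident += 1
        if _SC.get((x, y), 0.0) > 0:
            sim += 1
    return best, 100.0 * ident / length, 100.0 * sim / length, length, gaps


def _arg3(m, x, y):
    if m >= x and m >= y:
        return 0
    if x >= y:
        return 1
    return 2


def _x_edge(i):
    return 0 if i == 1 else 1


def _y_edge(j):
    return 0 if j == 1 else 2


# ---------------------------------------------------------------------------
# PROSITE oracle


def prosite_oracle(seq: str, pattern: str) -> set:
    """All (start, end) matches by expanding the pattern into fixed-length
    regular expressions."""
    terms = []
    for token in pattern.strip().rstrip(".").split("-"):
        token = token.strip()
        m = re.fullmatch(r"x\((\d+)(?:,(\d+))?\)", token)
        if m:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            terms.append([("." * k) for k in range(lo, hi + 1)])
        elif token == "x":
            terms.append(["."])
        elif token.startswith("["):
            terms.append([token])
        else:
            terms.append([re.escape(token)])

    expansions = [""]
    for options in terms:
        expansions = [e + o for e in expansions for o in options]
    out = set()
    for exp in expansions:
        rx = re.compile("(?=(%s))" % exp)
        for m in rx.finditer(seq):
            out.add((m.start(), m.start() + len(m.group(1))))
    return out
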
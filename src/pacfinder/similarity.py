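"""Global-alignment percent identity/similarity, per-species dedup and
distance matrices.

The aligner is Needleman–Wunsch/Gotoh with affine gaps at the classic
needle defaults (BLOSUM62, gap open 10, extend 0.5, terminal gaps free):
a gap of length L costs 10 + 0.5·(L−1) anywhere except at the alignment
ends, where it is free. Identity is the fraction of identical standard-
residue columns over the alignment length; similarity the fraction of
columns with a positive substitution score. 'X' and '*' score 0 against
everything and are never counted as identities, which keeps
identity ≤ similarity on X-containing sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Union

import numpy as np
import pandas as pd

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_NEG = -1e30


def _build_matrix() -> dict:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    scores: dict = {}
    for a in blosum.alphabet:
        for b in blosum.alphabet:
            if a in "X*" or b in "X*":
                scores[a, b] = 0.0
            else:
                scores[a, b] = float(blosum[a, b])
    return scores


_SCORES = _build_matrix()


def substitution_score(a: str, b: str) -> float:
    return _SCORES.get((a, b), 0.0)


@dataclass
class AlignmentResult:
    """Percent identity/similarity of one global alignment."""

    identity_pct: float
    similarity_pct: float
    length: int
    gaps: int
    score: float
    aligned_a: str
    aligned_b: str


def global_align(a: str, b: str, gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND) -> AlignmentResult:
    """Align two amino-acid sequences globally (needle-equivalent).

    Traceback ties are broken deterministically: diagonal, then up (gap in
    ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    n, m = len(a), len(b)
    # state matrices: M aligned pair, X gap in b (consumes a), Y gap in a
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    # pointers: 0 from M, 1 from X, 2 from Y
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # leading terminal gap in b is free
    Y[0, 1:] = 0.0
    ptr_x[2:, 0] = 1
    ptr_y[0, 2:] = 2
    score_row = [_SCORES.get((ca, cb), 0.0) for ca in a for cb in b]  # flat lookup below
    for i in range(1, n + 1):
        ca = a[i - 1]
        base = (i - 1) * m
        for j in range(1, m + 1):
            s = score_row[base + j - 1]
            # M: align a[i-1] with b[j-1]
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cand))  # ties prefer M, then X, then Y
            M[i, j] = cand[k] + s
            ptr_m[i, j] = k
            # X: gap in b, consume a[i-1]
            cand = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                    Y[i - 1, j] - gap_open)
            k = int(np.argmax(cand))
            X[i, j] = cand[k]
            ptr_x[i, j] = k
            # Y: gap in a, consume b[j-1]
            cand = (M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                    Y[i, j - 1] - gap_extend)
            k = int(np.argmax(cand))
            Y[i, j] = cand[k]
            ptr_y[i, j] = k

    # free trailing gaps: best cell on the last row or column
    best = (_NEG, None)
    for i in range(n + 1):
        for state, mat in ((0, M), (1, X), (2, Y)):
            v = mat[i, m]
            if v > best[0]:
                best = (v, (i, m, state))
    for j in range(m + 1):
        for state, mat in ((0, M), (1, X), (2, Y)):
            v = mat[n, j]
            if v > best[0]:
                best = (v, (n, j, state))
    score, (bi, bj, state) = best

    core_a: list = []
    core_b: list = []
    i, j = bi, bj
    ptrs = (ptr_m, ptr_x, ptr_y)
    while i > 0 or j > 0:
        prev = int(ptrs[state][i, j])
        if state == 0:
            core_a.append(a[i - 1])
            core_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            core_a.append(a[i - 1])
            core_b.append("-")
            i -= 1
        else:
            core_a.append("-")
            core_b.append(b[j - 1])
            j -= 1
        state = prev
    # free trailing gap: at most one of the two tails is non-empty
    sa = "".join(reversed(core_a)) + a[bi:] + "-" * (m - bj)
    sb = "".join(reversed(core_b)) + "-" * (n - bi) + b[bj:]
    return _summarise(sa, sb, float(score))


def _summarise(sa: str, sb: str, score: float) -> AlignmentResult:
    length = len(sa)
    ident = sim = gaps = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y and x not in "X*":
            ident += 1
        if _SCORES.get((x, y), 0.0) > 0:
            sim += 1
    return AlignmentResult(identity_pct=100.0 * ident / length,
                           similarity_pct=100.0 * sim / length,
                           length=length, gaps=gaps, score=score,
                           aligned_a=sa, aligned_b=sb)


def identity(a: str, b: str) -> float:
    return global_align(a, b).identity_pct


# ---------------------------------------------------------------------------
# per-species dedup


def dedupe(records: Iterable, threshold: float = 85.0,
           species: Optional[Union[dict, Callable]] = None) -> tuple:
    """Collapse near-identical domains within each species.

    Single-linkage clusters at identity ≥ ``threshold`` (percent); the
    representative is the longest member (ties: lexicographically
    smallest id). Returns (representatives in input order, clusters).
    ``species`` maps record id → species label (dict or callable); by
    default all records are treated as one species.
    """
    records = list(records)
    if species is None:
        get_species = lambda r: "_all_"
    elif callable(species):
        get_species = lambda r: species(r.id)
    else:
        get_species = lambda r: species[r.id]

    parent = {r.id: r.id for r in records}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_species: dict = {}
    for r in records:
        by_species.setdefault(get_species(r), []).append(r)
    for group in by_species.values():
        for i, r1 in enumerate(group):
            for r2 in group[i + 1:]:
                if global_align(r1.sequence, r2.sequence).identity_pct >= threshold:
                    parent[find(r1.id)] = find(r2.id)

    clusters: dict = {}
    for r in records:
        clusters.setdefault(find(r.id), []).append(r)
    rep_ids = set()
    for members in clusters.values():
        rep = min(members, key=lambda r: (-len(r.sequence), r.id))
        rep_ids.add(rep.id)
    representatives = [r for r in records if r.id in rep_ids]
    return representatives, [sorted((m.id for m in v)) for v in clusters.values()]


# ---------------------------------------------------------------------------
# distance matrix


def distance_matrix(records: Iterable) -> pd.DataFrame:
    """Symmetric 100 − identity matrix (zero diagonal) for tree building."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("distance_matrix requires at least 2 records")
    ids = [r.id for r in records]
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - global_align(records[i].sequence, records[j].sequence).identity_pct
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_phylip(df: pd.DataFrame, path) -> None:
    """Write a distance matrix in relaxed PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(df)}\n")
        for name, row in df.iterrows():
            vals = " ".join(f"{v:.4f}" for v in row.values)
            fh.write(f"{name}  {vals}\n")


def pairwise_identity_table(records: Iterable) -> pd.DataFrame:
    """Long-format pairwise identity/similarity table (id_a, id_b, ...)."""
    records = list(records)
    rows = []
    for i, r1 in enumerate(records):
        for r2 in records[i + 1:]:
            res = global_align(r1.sequence, r2.sequence)
            rows.append((r1.id, r2.id, res.identity_pct, res.similarity_pct))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "identity", "similarity"])
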
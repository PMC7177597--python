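"""Per-column conservation profiles, consensus motifs and PROSITE-pattern
matching for aligned PAC domains, with optional mapping onto structural
accessibility.

Information content per column is log2(20) minus the Shannon entropy of
the gap-excluded residue frequencies, scaled by the non-gap fraction so
that gappy columns score low.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
MAX_IC = math.log2(20.0)


@dataclass
class AlignmentProfile:
    """Column-wise frequencies (20 residues + gap), information content
    in bits, and a plurality consensus ('x' below plurality 0.5)."""

    columns: np.ndarray  # (n_columns, 21)
    information_content: np.ndarray  # bits
    consensus: str

    def __len__(self) -> int:
        return len(self.consensus)


def _as_rows(alignment) -> list[str]:
    rows = []
    for row in alignment:
        seq = row.sequence if hasattr(row, "sequence") else str(row)
        rows.append(seq.upper())
    return rows


def build_profile(alignment: Iterable) -> AlignmentProfile:
    """Build a conservation profile from a multiple alignment.

    Rows may be plain strings or records with a ``sequence`` attribute;
    all rows must have equal length and there must be at least two.
    Residues outside the 20 standard letters are counted as gaps.
    """
    rows = _as_rows(alignment)
    if len(rows) < 2:
        raise ValueError("build_profile requires at least 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: all rows must have equal length")
    index = {c: i for i, c in enumerate(ALPHABET)}
    counts = np.zeros((width, 21))
    for row in rows:
        for col, c in enumerate(row):
            counts[col, index.get(c, 20)] += 1
    freqs = counts / len(rows)

    ic = np.zeros(width)
    consensus = []
    for col in range(width):
        res_counts = counts[col, :20]
        nongap = res_counts.sum()
        nongap_frac = nongap / len(rows)
        if nongap > 0:
            p = res_counts[res_counts > 0] / nongap
            entropy = -(p * np.log2(p)).sum()
            ic[col] = (MAX_IC - entropy) * nongap_frac
        if nongap > 0:
            top = int(res_counts.argmax())
            if res_counts[top] / nongap >= 0.5:
                consensus.append(AMINO_ACIDS[top])
            else:
                consensus.append("x")
        else:
            consensus.append("x")
    return AlignmentProfile(columns=freqs, information_content=ic,
                            consensus="".join(consensus))


def top_motif(profile: AlignmentProfile, width: int) -> tuple:
    """The window of ``width`` columns maximising mean information
    content; ties go to the leftmost window. Returns (start, mean_IC)."""
    n = len(profile)
    if width > n:
        raise ValueError(f"width {width} exceeds profile length {n}")
    ic = profile.information_content
    sums = np.convolve(ic, np.ones(width), mode="valid")
    start = int(sums.argmax())  # argmax returns the first maximum
    return start, float(sums[start] / width)


# ---------------------------------------------------------------------------
# PROSITE pattern subset

_ELEMENT = re.compile(
    r"(?P<set>\[[A-Z]+\])|(?P<res>[A-Z])|(?P<any>x(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?)")


def parse_prosite(pattern: str) -> list:
    """Parse a PROSITE pattern subset into (residue-set, min, max) terms.

    Supported syntax: residue, [SET], x, x(n), x(n,m), '-' separators and
    an optional trailing '.'. Malformed input raises ``ValueError`` naming
    the offending position.
    """
    pattern = pattern.strip().rstrip(".")
    elements = []
    pos = 0
    for i, token in enumerate(pattern.split("-")):
        token = token.strip()
        if not token:
            raise ValueError(f"prosite pattern: empty element at position {pos}")
        m = _ELEMENT.fullmatch(token)
        if m is None:
            raise ValueError(f"prosite pattern: cannot parse {token!r} at position {pos}")
        if m.group("set"):
            elements.append((frozenset(m.group("set")[1:-1]), 1, 1))
        elif m.group("res"):
            elements.append((frozenset(m.group("res")), 1, 1))
        else:
            n = int(m.group("n")) if m.group("n") else 1
            mm = int(m.group("m")) if m.group("m") else n
            if mm < n:
                raise ValueError(f"prosite pattern: bad repeat {token!r} at position {pos}")
            elements.append((None, n, mm))  # None = any residue
        pos += len(token) + 1
    return elements


def match_prosite(seq: str, pattern: str) -> list:
    """All (start, end) half-open locations of a PROSITE pattern.

    Overlapping matches are reported; a variable-length x(n,m) element can
    yield several ends for one start.
    """
    elements = parse_prosite(pattern)
    results = []

    def extend(pos: int, k: int, out: set) -> None:
        if k == len(elements):
            out.add(pos)
            return
        allowed, lo, hi = elements[k]
        for ln in range(lo, hi + 1):
            if pos + ln > len(seq):
                break
            if allowed is not None and any(c not in allowed for c in seq[pos:pos + ln]):
                break
            extend(pos + ln, k + 1, out)

    for start in range(len(seq) + 1):
        ends: set = set()
        extend(start, 0, ends)
        results.extend((start, e) for e in sorted(ends))
    return results


# ---------------------------------------------------------------------------
# structural context


def map_accessibility(profile: AlignmentProfile, representative: str,
                      rsa_track, ss_track, buried_rsa: float = 0.2,
                      conserved_ic: float = 2.0) -> pd.DataFrame:
    """Join the conservation profile with per-residue RSA and secondary
    structure of a designated representative row.

    ``representative`` is the aligned (gapped) sequence of the row whose
    structure is known; ``rsa_track`` and ``ss_track`` cover its ungapped
    residues. Buried is RSA < ``buried_rsa``. Columns conserved above
    ``conserved_ic`` bits are labelled "core" when buried and "candidate
    functional site" when exposed; representative-gap columns carry no
    structural data.
    """
    if len(representative) != len(profile):
        raise ValueError("representative length must equal profile width")
    ungapped = len(representative.replace(GAP, ""))
    rsa = list(rsa_track)
    ss = str(ss_track.ss) if hasattr(ss_track, "ss") else str(ss_track)
    if len(rsa) != ungapped or len(ss) != ungapped:
        raise ValueError(
            f"rsa/ss tracks (len {len(rsa)}/{len(ss)}) must match the "
            f"representative's {ungapped} residues")
    rows = []
    res_i = 0
    for col, c in enumerate(representative):
        ic = float(profile.information_content[col])
        if c == GAP:
            rows.append((col, profile.consensus[col], ic, None, "", ""))
            continue
        r = float(rsa[res_i])
        state = ss[res_i]
        res_i += 1
        if ic >= conserved_ic:
            label = "core" if r < buried_rsa else "candidate functional site"
        else:
            label = ""
        rows.append((col, profile.consensus[col], ic, r, state, label))
    return pd.DataFrame(rows, columns=["column", "consensus", "ic", "rsa", "ss", "label"])


def frequency_matrix(profile: AlignmentProfile) -> pd.DataFrame:
    """Logo-ready per-column residue frequency matrix (gap excluded,
    renormalised)."""
    res = profile.columns[:, :20]
    sums = res.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sums > 0, res / sums, 0.0)
    return pd.DataFrame(norm, columns=list(AMINO_ACIDS))
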
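"""Bona fide gates: signal peptide, secondary-structure admissibility, and
exclusion of foreign functional domains.

Each gate is pluggable: a precomputed prediction table (exported from an
external predictor) overrides the built-in heuristic, so the pipeline is
testable without the neural predictors used in large-scale mining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

log = logging.getLogger(__name__)

#: h-region residues for the built-in signal peptide heuristic
HYDROPHOBIC = set("AILFVMWC")
POSITIVE = set("KR")
NEGATIVE = set("DE")

PASS, FAIL, UNKNOWN = "pass", "fail", "unknown"


@dataclass
class SecondaryStructureTrack:
    """Per-residue secondary-structure states over {H, E, C}."""

    record_id: str
    ss: str

    def __post_init__(self):
        if set(self.ss) - set("HEC"):
            raise ValueError(f"track {self.record_id!r}: alphabet must be H/E/C")


@dataclass
class DomainHit:
    """A located external domain annotation (1-based inclusive coords)."""

    record_id: str
    accession: str
    start: int
    end: int
    evalue: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"hit {self.accession} on {self.record_id}: start > end")
        if self.evalue < 0:
            raise ValueError(f"hit {self.accession} on {self.record_id}: negative e-value")


def read_domain_hits(path) -> list[DomainHit]:
    """Read a TSV of external domain hits.

    Columns: protein_id, domain_accession, ali_start, ali_end, evalue.
    A header line is recognised by a non-numeric third column.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["protein_id", "domain_accession", "ali_start", "ali_end", "evalue"])
    if df.empty:
        return []
    try:
        int(df.iloc[0]["ali_start"])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return [DomainHit(record_id=r.protein_id, accession=r.domain_accession,
                      start=int(r.ali_start), end=int(r.ali_end), evalue=float(r.evalue))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# signal peptide gate


def signal_peptide_gate(record, table: Optional[dict] = None) -> str:
    """Classify the N-terminus as a secretion signal: pass/fail/unknown.

    If ``table`` (record_id → verdict) holds a precomputed external
    prediction it wins. Otherwise the built-in heuristic: within residues
    1–35, an 8-residue window with ≥6 hydrophobic residues (h-region)
    preceded by an n-region of non-negative net charge. Frame-translated
    fragments lacking an initial Met are ``unknown`` — their true
    N-terminus may simply be absent from the contig.
    """
    if table is not None and record.id in table:
        verdict = table[record.id]
        if verdict not in (PASS, FAIL, UNKNOWN):
            raise ValueError(f"invalid verdict {verdict!r} for {record.id}")
        return verdict
    seq = record.sequence
    if record.source == "translated_frame" and not seq.startswith("M"):
        return UNKNOWN
    return PASS if find_signal_peptide(seq) is not None else FAIL


def check_prediction_table(table: dict, records: Iterable) -> None:
    """Raise if a table row references an unknown record."""
    known = {r.id for r in records}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"prediction table references unknown records: {sorted(unknown)[:5]}")


def find_signal_peptide(seq: str) -> Optional[tuple]:
    """Locate a signal peptide as (0, cleavage_end), or None.

    Finds the first 8-residue window within the first 35 residues holding
    ≥6 hydrophobic residues and a preceding n-region of net charge ≥ 0,
    extends through the hydrophobic run, and places the cleavage site
    three residues (a short c-region) after it.
    """
    limit = min(35, len(seq))
    for i in range(0, limit - 7):
        window = seq[i:i + 8]
        if sum(c in HYDROPHOBIC for c in window) < 6:
            continue
        n_region = seq[:i]
        charge = sum(c in POSITIVE for c in n_region) - sum(c in NEGATIVE for c in n_region)
        if charge < 0:
            continue
        j = i + 8
        while j < len(seq) and seq[j] in HYDROPHOBIC:
            j += 1
        return (0, min(len(seq), j + 3))
    return None


# ---------------------------------------------------------------------------
# secondary structure gate


@dataclass(frozen=True)
class SsParams:
    """Quantification of the qualitative β-sheet requirement.

    A candidate span passes when it contains at least ``min_strands``
    E-runs of length ≥ ``min_strand_len`` and its helix fraction does not
    exceed ``max_helix_frac`` (the reference fold is a seven-stranded
    β-barrel; large α-helical candidates are decoys).
    """

    min_strand_len: int = 3
    min_strands: int = 3
    max_helix_frac: float = 0.5


def _strand_runs(ss: str, min_len: int) -> int:
    count = run = 0
    for c in ss:
        if c == "E":
            run += 1
        else:
            if run >= min_len:
                count += 1
            run = 0
    if run >= min_len:
        count += 1
    return count


def ss_admissible(match, ss_track: SecondaryStructureTrack,
                  params: SsParams = SsParams()) -> str:
    """β-sheet admissibility of a scanner match span: pass/fail."""
    start, end = match.span
    if len(ss_track.ss) < end:
        raise ValueError(
            f"track {ss_track.record_id!r} (len {len(ss_track.ss)}) does not cover span {match.span}")
    sub = ss_track.ss[start:end]
    strands = _strand_runs(sub, params.min_strand_len)
    helix_frac = sub.count("H") / len(sub)
    return PASS if strands >= params.min_strands and helix_frac <= params.max_helix_frac else FAIL


# Chou–Fasman-style per-residue propensities (helix, strand, turn/coil);
# the turn scale doubles as the coil propensity.
PROPENSITIES = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.16, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}
_UNKNOWN_PROPENSITY = (0.0, 0.0, 0.01)  # X, '*', gaps → coil

SMOOTH_WINDOW = 5


def predict_ss_fallback(record) -> SecondaryStructureTrack:
    """Propensity-smoothing secondary-structure prediction (H/E/C).

    Averages per-residue helix/strand/coil propensities over a centred
    window of 5 and assigns the argmax (ties resolved H > E > C by the
    fixed state order). Deterministic; a coarse stand-in for sequence-only
    workflows, not a neural predictor.
    """
    import numpy as np

    seq = record.sequence
    props = np.array([PROPENSITIES.get(c, _UNKNOWN_PROPENSITY) for c in seq])
    half = SMOOTH_WINDOW // 2
    n = len(seq)
    smoothed = np.empty_like(props)
    cums = np.vstack([np.zeros(3), np.cumsum(props, axis=0)])
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed[i] = (cums[hi] - cums[lo]) / (hi - lo)
    states = np.array(list("HEC"))
    return SecondaryStructureTrack(record_id=record.id,
                                   ss="".join(states[np.argmax(smoothed, axis=1)]))


# ---------------------------------------------------------------------------
# foreign functional domain gate

#: pollen Ole e 1 / PAC accessions are expected on true PDPs
DEFAULT_ALLOW_LIST = frozenset({"PF01190", "PS00925"})


def foreign_domain_gate(record, hits: Iterable[DomainHit],
                        allow_list: frozenset = DEFAULT_ALLOW_LIST,
                        evalue_max: float = 1e-5) -> str:
    """Fail when a confident non-allow-listed functional domain is present.

    Hits such as aldehyde dehydrogenase (PF00171) or JmjC/JmjN (PF02373/5)
    indicate an intracellular protein and disqualify the candidate.
    """
    for hit in hits:
        if hit.record_id != record.id:
            continue
        if hit.evalue <= evalue_max and hit.accession not in allow_list:
            return FAIL
    return PASS
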
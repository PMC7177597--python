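"""Associated-domain detection and Type 1–4 architecture classification.

PAC domains occur alone (Type 1), at the N-terminus with downstream
domains such as a Pro-rich region or the Trp-X8-Trp "W-W" domain
(Type 2), at the C-terminus downstream of His-rich / Pro-rich / AGP-like
regions (Type 3), or centrally, flanked by two extensin domains (Type 4).
The detectors quantify motif definitions that are qualitative in the
field's usage (extensin = clustered Ser-(Pro)≥2; AGP-like = Ala/Pro-type
dipeptide repeats); their thresholds are centralised in
:class:`DetectorParams`.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

log = logging.getLogger(__name__)

KINDS = ("extensin", "pro_rich", "his_rich", "agp_like", "ww", "signal_peptide", "pac")


@dataclass
class DomainAnnotation:
    """A located associated domain; ``score`` is kind-specific
    (motif count for extensin, residue count for His stretches,
    composition fraction for Pro-rich/AGP-like)."""

    kind: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.kind}: start must be < end")


@dataclass(frozen=True)
class DetectorParams:
    """Thresholds for the associated-domain detectors."""

    extensin_merge_distance: int = 30
    extensin_min_motifs: int = 3
    his_min_count: int = 4
    his_window: int = 6
    pro_window: int = 20
    pro_min_frac: float = 0.3
    agp_window: int = 20
    agp_min_coverage: float = 0.3
    agp_dipeptides: tuple = ("AP", "PA", "SP", "TP", "VP")


DEFAULT_DETECTOR_PARAMS = DetectorParams()


def detect_ww(seq: str, search_from: int = 0) -> list[DomainAnnotation]:
    """Find the W-X8-W domain anchor at/after ``search_from``.

    The annotation runs from the motif start to the sequence end (the
    domain is C-terminal); when candidate anchors overlap, the first wins,
    so at most one annotation is returned.
    """
    m = re.search(r"W.{8}W", seq[search_from:], flags=re.DOTALL)
    if m is None:
        return []
    start = search_from + m.start()
    return [DomainAnnotation(kind="ww", start=start, end=len(seq), score=1.0)]


def detect_extensin(seq: str, params: DetectorParams = DEFAULT_DETECTOR_PARAMS) -> list[DomainAnnotation]:
    """Find extensin regions: clusters of Ser-(Pro)≥2 motifs.

    Motif instances within ``extensin_merge_distance`` residues of each
    other are merged; a merged region qualifies with at least
    ``extensin_min_motifs`` instances. Score = instance count.
    """
    instances = [(m.start(), m.end()) for m in re.finditer(r"SPP+", seq)]
    out = []
    for group in _merge_within(instances, params.extensin_merge_distance):
        if len(group) >= params.extensin_min_motifs:
            out.append(DomainAnnotation(kind="extensin", start=group[0][0],
                                        end=group[-1][1], score=len(group)))
    return out


def _merge_within(intervals: list, distance: int) -> list:
    groups: list[list] = []
    for iv in intervals:
        if groups and iv[0] - groups[-1][-1][1] <= distance:
            groups[-1].append(iv)
        else:
            groups.append([iv])
    return groups


def detect_his_rich(seq: str, params: DetectorParams = DEFAULT_DETECTOR_PARAMS) -> list[DomainAnnotation]:
    """Find His stretches: ≥4 His inside any 6-residue window, merged and
    trimmed to the first/last His. Score = His count in the region."""
    w, k = params.his_window, params.his_min_count
    qualifying = []
    for i in range(max(0, len(seq) - w + 1)):
        if seq[i:i + w].count("H") >= k:
            qualifying.append((i, i + w))
    if not qualifying and len(seq) < w and seq.count("H") >= k:
        qualifying.append((0, len(seq)))
    out = []
    for group in _merge_within(qualifying, 0):
        start, end = group[0][0], group[-1][1]
        sub = seq[start:end]
        first, last = sub.find("H"), sub.rfind("H")
        out.append(DomainAnnotation(kind="his_rich", start=start + first,
                                    end=start + last + 1,
                                    score=sub.count("H")))
    return out


def _windowed_regions(n: int, window: int, qualifies) -> list:
    """Merge overlapping qualifying fixed-size windows into regions."""
    regions = []
    for i in range(max(0, n - window + 1)):
        if qualifies(i):
            if regions and i <= regions[-1][1] - 1:
                regions[-1][1] = i + window
            else:
                regions.append([i, i + window])
    return regions


def detect_pro_rich(seq: str, params: DetectorParams = DEFAULT_DETECTOR_PARAMS) -> list[DomainAnnotation]:
    """Find Pro/Hyp-rich regions: 20-residue windows with Pro fraction
    ≥ 0.3, overlapping windows merged. Score = Pro fraction of the merged
    region."""
    w = params.pro_window
    thr = params.pro_min_frac

    def ok(i):
        return seq[i:i + w].count("P") / w >= thr

    out = []
    for start, end in _windowed_regions(len(seq), w, ok):
        sub = seq[start:end]
        out.append(DomainAnnotation(kind="pro_rich", start=start, end=end,
                                    score=sub.count("P") / len(sub)))
    return out


def detect_agp_like(seq: str, params: DetectorParams = DEFAULT_DETECTOR_PARAMS) -> list[DomainAnnotation]:
    """Find AGP-like regions: 20-residue windows where {AP, PA, SP, TP,
    VP} dipeptides cover ≥ 30% of positions. Score = dipeptide coverage of
    the merged region."""
    w = params.agp_window
    dips = set(params.agp_dipeptides)

    def coverage(sub: str) -> float:
        covered = [False] * len(sub)
        for i in range(len(sub) - 1):
            if sub[i:i + 2] in dips:
                covered[i] = covered[i + 1] = True
        return sum(covered) / len(sub)

    out = []
    for start, end in _windowed_regions(len(seq), w,
                                        lambda i: coverage(seq[i:i + w]) >= params.agp_min_coverage):
        out.append(DomainAnnotation(kind="agp_like", start=start, end=end,
                                    score=coverage(seq[start:end])))
    return out


def annotate(seq: str, pac_end: Optional[int] = None, signal_end: int = 0,
             params: DetectorParams = DEFAULT_DETECTOR_PARAMS) -> list[DomainAnnotation]:
    """Run all detectors on one sequence.

    ``pac_end`` sets where the W-W search starts (the domain follows the
    PAC in Type 2 architectures). Annotations overlapping the signal
    peptide are trimmed to start at ``signal_end``; the signal peptide
    itself is reported as its own annotation when present.
    """
    anns: list[DomainAnnotation] = []
    if signal_end > 0:
        anns.append(DomainAnnotation(kind="signal_peptide", start=0, end=signal_end, score=1.0))
    found = (detect_extensin(seq, params) + detect_pro_rich(seq, params)
             + detect_his_rich(seq, params) + detect_agp_like(seq, params)
             + detect_ww(seq, search_from=pac_end if pac_end is not None else 0))
    for a in found:
        if a.end <= signal_end:
            continue
        a.start = max(a.start, signal_end)
        anns.append(a)
    anns.sort(key=lambda a: (a.start, a.end, a.kind))
    return anns


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassifyParams:
    """Positional thresholds for type assignment.

    The PAC counts as terminal when the opposite flank of the mature
    protein is at most max(``terminal_margin``, ``terminal_frac`` × mature
    length), and as covering the whole protein at ``whole_min_cover``.
    """

    terminal_margin: int = 30
    terminal_frac: float = 0.10
    whole_min_cover: float = 0.80
    conserved_min_identity: float = 60.0


DEFAULT_CLASSIFY_PARAMS = ClassifyParams()

UPSTREAM_TYPE3_KINDS = {"his_rich", "pro_rich", "agp_like"}


@dataclass
class PdpClassification:
    """Type 1–4 call with the PAC positional category and subtype flags
    (``conserved_1prime`` for highly conserved Type 1 sequences,
    ``ww_2prime`` for Type 2 with a C-terminal W-W domain)."""

    record_id: str
    type: str  # "1".."4" or "unclassified"
    pac_position: Optional[str]  # whole / n_terminal / c_terminal / central
    flags: set = field(default_factory=set)
    notes: list = field(default_factory=list)


def classify(record, pac_matches: Iterable, annotations: Iterable[DomainAnnotation],
             params: ClassifyParams = DEFAULT_CLASSIFY_PARAMS,
             clade_c_refs: Optional[list] = None) -> PdpClassification:
    """Assign the domain-architecture type of one protein.

    ``pac_matches`` are the strict scanner matches; with several
    non-overlapping matches the most N-terminal one is classified and the
    multiplicity logged. ``clade_c_refs`` (sequences of the highly
    conserved Type 1 clade) enables the 1' flag.
    """
    seq = record.sequence
    matches = sorted((m for m in pac_matches if m.mode == "strict"),
                     key=lambda m: m.span[0])
    if not matches:
        return PdpClassification(record_id=record.id, type="unclassified",
                                 pac_position=None, notes=["no_strict_pac_match"])
    notes = []
    if len(matches) > 1:
        log.info("record %s: %d PAC matches; classifying the N-terminal-most",
                 record.id, len(matches))
        notes.append("multi_pac")
    pac = matches[0]
    pac_start, pac_end = pac.span

    anns = sorted(annotations, key=lambda a: a.start)
    sp = next((a for a in anns if a.kind == "signal_peptide"), None)
    mature_start = sp.end if sp else 0
    mature_len = len(seq) - mature_start
    others = [a for a in anns if a.kind not in ("signal_peptide", "pac")]
    # merged detector windows can bleed a few residues into the PAC span,
    # so flanking annotations are assigned by their midpoint
    upstream = [a for a in others if (a.start + a.end) / 2 <= pac_start]
    downstream = [a for a in others if (a.start + a.end) / 2 >= pac_end]

    up_len = max(0, pac_start - mature_start)
    down_len = len(seq) - pac_end
    margin = max(params.terminal_margin, params.terminal_frac * mature_len)
    cover = (pac_end - pac_start) / mature_len if mature_len else 0.0

    n_terminal = up_len <= margin and not upstream
    c_terminal = down_len <= margin and not downstream
    ext_up = any(a.kind == "extensin" for a in upstream)
    ext_down = any(a.kind == "extensin" for a in downstream)

    flags: set = set()
    if ext_up and ext_down:
        return PdpClassification(record_id=record.id, type="4",
                                 pac_position="central", flags=flags, notes=notes)
    if cover >= params.whole_min_cover and not others:
        if clade_c_refs:
            pac_seq = seq[pac_start:pac_end]
            if _max_identity(pac_seq, clade_c_refs) >= params.conserved_min_identity:
                flags.add("conserved_1prime")
        return PdpClassification(record_id=record.id, type="1",
                                 pac_position="whole", flags=flags, notes=notes)
    if n_terminal and (downstream or down_len > params.terminal_margin):
        if any(a.kind == "ww" for a in downstream):
            flags.add("ww_2prime")
        return PdpClassification(record_id=record.id, type="2",
                                 pac_position="n_terminal", flags=flags, notes=notes)
    if c_terminal and any(a.kind in UPSTREAM_TYPE3_KINDS for a in upstream):
        return PdpClassification(record_id=record.id, type="3",
                                 pac_position="c_terminal", flags=flags, notes=notes)
    position = ("n_terminal" if n_terminal else
                "c_terminal" if c_terminal else "central")
    return PdpClassification(record_id=record.id, type="unclassified",
                             pac_position=position, flags=flags, notes=notes)


def _max_identity(pac_seq: str, refs: list) -> float:
    from .similarity import global_align

    best = 0.0
    for ref in refs:
        ref_seq = ref.sequence if hasattr(ref, "sequence") else ref
        best = max(best, global_align(pac_seq, ref_seq).identity_pct)
    return best
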
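"""End-to-end convenience wrapper: scan → gates → annotate → classify.

This is the desk-scale equivalent of the mining pipeline: strict scan for
the Cys scaffold, the three bona fide gates (signal peptide, secondary
structure, foreign domains), associated-domain annotation, and Type 1–4
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import architecture, filters, scanner


@dataclass
class PipelineResult:
    record_id: str
    matches: list
    gate_verdicts: dict = field(default_factory=dict)
    bona_fide: bool = False
    annotations: list = field(default_factory=list)
    classification: Optional[architecture.PdpClassification] = None


def run_record(record, rule: scanner.PacSpacingRule = scanner.DEFAULT_RULE,
               hits: Iterable = (), ss_track=None,
               signal_table: Optional[dict] = None,
               ss_params: filters.SsParams = filters.SsParams(),
               detector_params: architecture.DetectorParams = architecture.DEFAULT_DETECTOR_PARAMS,
               classify_params: architecture.ClassifyParams = architecture.DEFAULT_CLASSIFY_PARAMS,
               clade_c_refs: Optional[list] = None) -> PipelineResult:
    """Run the full candidate pipeline on one protein record.

    A record is bona fide when a strict PAC match exists, its span passes
    the secondary-structure gate (``ss_track`` defaults to the built-in
    fallback predictor), the foreign-domain gate passes, and the signal
    peptide gate does not fail (``unknown`` — e.g. incomplete
    frame-translated fragments — does not exclude, but is recorded).
    """
    result = PipelineResult(record_id=record.id,
                            matches=scanner.scan_strict(record, rule))
    verdicts = result.gate_verdicts
    verdicts["signal_peptide"] = filters.signal_peptide_gate(record, signal_table)
    verdicts["foreign_domain"] = filters.foreign_domain_gate(record, hits)
    if result.matches:
        track = ss_track or filters.predict_ss_fallback(record)
        verdicts["secondary_structure"] = filters.ss_admissible(
            result.matches[0], track, ss_params)
    else:
        verdicts["secondary_structure"] = filters.UNKNOWN
    result.bona_fide = (bool(result.matches)
                        and verdicts["signal_peptide"] != filters.FAIL
                        and verdicts["secondary_structure"] == filters.PASS
                        and verdicts["foreign_domain"] == filters.PASS)
    if result.matches:
        sp_span = filters.find_signal_peptide(record.sequence)
        result.annotations = architecture.annotate(
            record.sequence, pac_end=result.matches[0].span[1],
            signal_end=sp_span[1] if sp_span else 0, params=detector_params)
        result.classification = architecture.classify(
            record, result.matches, result.annotations,
            params=classify_params, clade_c_refs=clade_c_refs)
    return result
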
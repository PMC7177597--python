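"""Readers/writers for the standard formats the pipeline touches.

Internal convention: protein positions are 0-based half-open everywhere in
this package; genomic coordinates (GFF3) stay 1-based inclusive at the
boundary, as do user-facing reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_FRAMES = (1, 2, 3, -1, -2, -3)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


@dataclass
class ProteinRecord:
    """One amino-acid sequence with provenance.

    ``source`` is ``"protein"`` for native protein entries and
    ``"translated_frame"`` for peptides obtained by translating a
    nucleotide contig; in the latter case ``frame`` records the reading
    frame (1..3 forward, -1..-3 on the reverse complement).
    """

    id: str
    sequence: str
    description: str = ""
    source: str = "protein"
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.source == "translated_frame":
            if self.frame not in VALID_FRAMES:
                raise ValueError(
                    f"record {self.id!r}: translated_frame requires frame in {VALID_FRAMES}"
                )
        elif self.frame is not None:
            raise ValueError(f"record {self.id!r}: frame only allowed for translated_frame")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene structure in 1-based inclusive genomic coordinates.

    ``exons`` and ``cds_segments`` are ordered 5'→3' in transcription
    order (descending genomic start on the '-' strand).
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list = field(default_factory=list)
    cds_segments: list = field(default_factory=list)
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        for name, segs in (("exons", self.exons), ("cds_segments", self.cds_segments)):
            for s, e in segs:
                if s > e:
                    raise ValueError(f"gene {self.gene_id!r}: {name} segment {s}>{e}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def genomic_start(self) -> int:
        return min(s for s, _ in self.exons or self.cds_segments)

    @property
    def genomic_end(self) -> int:
        return max(e for _, e in self.exons or self.cds_segments)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into ProteinRecords.

    Sequences are uppercased and '*' is retained. Duplicate ids raise
    ``ValueError``; an empty file returns an empty list with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    if not records:
        log.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def _translate_cds(nt: str) -> str:
    """Codon-table-1 translation; stop → '*', any codon containing N → 'X'.

    The trailing partial codon, if any, is dropped.
    """
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i:i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STANDARD_TABLE.stop_codons:
            out.append("*")
        else:
            out.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(out)


def translate_frames(nucleotide_seq: str, frames: Iterable[int] = VALID_FRAMES,
                     record_id: str = "seq") -> list[ProteinRecord]:
    """Translate a nucleotide sequence in the requested reading frames.

    Frame ``-k`` translates the reverse complement offset by ``k-1``.
    Characters outside {A,C,G,T,N} (case-insensitive) are rejected with
    their positions listed.
    """
    nt = nucleotide_seq.upper()
    bad = [i for i, c in enumerate(nt) if c not in "ACGTN"]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        raise ValueError(f"illegal nucleotide characters at positions: {shown}")
    frames = list(frames)
    for f in frames:
        if f not in VALID_FRAMES:
            raise ValueError(f"invalid frame {f}; must be one of {VALID_FRAMES}")
    rc = reverse_complement(nt)
    out = []
    for f in frames:
        template = nt if f > 0 else rc
        offset = abs(f) - 1
        pep = _translate_cds(template[offset:])
        if not pep:
            continue
        out.append(ProteinRecord(
            id=f"{record_id}_frame{f:+d}", sequence=pep,
            source="translated_frame", frame=f))
    return out


def _validate_gff_columns(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 columns")


def read_gff(path) -> list[GeneModel]:
    """Parse a GFF3 file into one GeneModel per mRNA.

    Exons/CDS are returned in transcription order. CDS features without a
    resolvable mRNA parent are skipped with a warning.
    """
    import gffutils

    _validate_gff_columns(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}

    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [])
        if not any(p in mrna_ids for p in parents):
            log.warning("CDS %s without mRNA parent skipped", feat.id or feat.start)

    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_parents = mrna.attributes.get("Parent", [mrna.id])
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        reverse = mrna.strand == "-"
        exons.sort(key=lambda t: t[0], reverse=reverse)
        cds.sort(key=lambda t: t[0], reverse=reverse)
        if not exons and cds:
            exons = list(cds)
        protein_id = mrna.attributes.get("protein_id", [mrna.id])[0]
        models.append(GeneModel(
            gene_id=gene_parents[0], seq_id=mrna.seqid, strand=mrna.strand,
            exons=exons, cds_segments=cds, protein_id=protein_id))
    return models


def read_ss_tracks(path) -> dict[str, str]:
    """Read per-residue secondary-structure strings (H/E/C alphabet).

    Format: one line per record, ``<id><whitespace><track>``.
    """
    tracks: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected '<id> <track>'")
            rid, track = parts
            track = track.upper()
            if set(track) - set("HEC"):
                raise ValueError(f"{path}: line {lineno}: track alphabet must be H/E/C")
            tracks[rid] = track
    return tracks


def write_nt_fasta(entries: dict[str, str], path) -> None:
    """Write nucleotide sequences (id → seq) as wrapped FASTA."""
    recs = [SeqRecord(Seq(s), id=k, description="") for k, s in entries.items()]
    SeqIO.write(recs, str(path), "fasta")
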
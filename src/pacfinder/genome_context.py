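"""Gene-structure diagnostics: the conserved intron position and tandem
gene duplication.

PDP genes typically carry either no intron across the PAC coding region
or exactly one, located between the codons for Cys1–Cys2 and those for
Cys3–Cys6; an intron anywhere else in the span is atypical. Tandemly
duplicated PDP genes are adjacent genes on one scaffold whose PAC domains
share more than 85% amino-acid identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

INTRON_NONE = "none"
INTRON_DIAGNOSTIC = "diagnostic"
INTRON_ATYPICAL = "atypical"


def _cds_junctions(gene_model) -> list[int]:
    """CDS-coordinate breakpoints: junction ``j`` means an intron sits
    between CDS nucleotides j-1 and j (0-based CDS coordinates)."""
    lengths = [e - s + 1 for s, e in gene_model.cds_segments]
    out = []
    acc = 0
    for ln in lengths[:-1]:
        acc += ln
        out.append(acc)
    return out


def intron_position(gene_model, match) -> str:
    """Classify the intron position of one PDP gene: none / diagnostic /
    atypical.

    Diagnostic means at least one intron falls strictly between the last
    nucleotide of the Cys2 codon and the first nucleotide of the Cys3
    codon; ``none`` means the PAC span is intronless; anything else is
    atypical. Protein position p occupies CDS nucleotides [3p, 3p+3).
    """
    protein_len_nt = gene_model.cds_length
    span_start, span_end = match.span
    if protein_len_nt < 3 * span_end:
        raise ValueError(
            f"gene {gene_model.gene_id}: CDS length {protein_len_nt} nt shorter than "
            f"PAC span end {span_end} aa")
    c2, c3 = match.cys_pos[1], match.cys_pos[2]
    if c2 is None or c3 is None:
        raise ValueError("intron_position requires Cys2 and Cys3 positions")
    junctions = _cds_junctions(gene_model)
    in_span = [j for j in junctions if 3 * span_start < j < 3 * span_end]
    if not in_span:
        return INTRON_NONE
    lo = 3 * c2 + 3  # first position after the Cys2 codon
    hi = 3 * c3      # first nucleotide of the Cys3 codon
    if any(lo <= j <= hi for j in in_span):
        return INTRON_DIAGNOSTIC
    return INTRON_ATYPICAL


@dataclass
class TandemGroup:
    """A chain of adjacent PDP genes with high PAC identity."""

    seq_id: str
    gene_ids: list
    orientations: list
    pairwise_identity: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.gene_ids) < 2:
            raise ValueError("a tandem group needs at least 2 genes")


def _lookup(identities: dict, a: str, b: str) -> float:
    if (a, b) in identities:
        return identities[(a, b)]
    if (b, a) in identities:
        return identities[(b, a)]
    return 0.0


def find_tandems(gene_models, pac_identities: dict, threshold: float = 85.0,
                 max_intervening: int = 1, pdp_gene_ids=None) -> list[TandemGroup]:
    """Detect tandem-duplicated PDP genes by single-linkage chaining.

    ``pac_identities`` maps (gene_id_a, gene_id_b) → percent identity of
    the PAC amino-acid spans (either key order). Genes not carrying a PAC
    match (absent from ``pdp_gene_ids``, which defaults to the ids seen in
    the identity table) count as intervening; consecutive PDP genes are
    chained when at most ``max_intervening`` such genes separate them and
    their PAC identity is strictly greater than ``threshold``. The result
    is invariant under reversal of the genomic coordinate direction.
    """
    if pdp_gene_ids is None:
        pdp_gene_ids = {g for pair in pac_identities for g in pair}

    def key_of(gm):
        """Identity-table key for a gene: its gene id, or its protein id
        (GFF-derived models carry the mRNA/protein id separately)."""
        if gm.gene_id in pdp_gene_ids:
            return gm.gene_id
        if gm.protein_id in pdp_gene_ids:
            return gm.protein_id
        return None

    by_seq: dict = {}
    for gm in gene_models:
        by_seq.setdefault(gm.seq_id, []).append(gm)

    groups = []
    for seq_id, genes in sorted(by_seq.items()):
        genes = sorted(genes, key=lambda g: (g.genomic_start, g.gene_id))
        pdp = [(rank, g) for rank, g in enumerate(genes) if key_of(g) is not None]
        for g in genes:
            if key_of(g) is None:
                log.warning("gene %s has no PAC match; treated as intervening", g.gene_id)
        chain: list = []
        for rank, gene in pdp:
            if chain:
                prev_rank, prev_gene = chain[-1]
                intervening = rank - prev_rank - 1
                ident = _lookup(pac_identities, key_of(prev_gene), key_of(gene))
                if intervening <= max_intervening and ident > threshold:
                    chain.append((rank, gene))
                    continue
                groups.extend(_close_chain(seq_id, chain, pac_identities, threshold, key_of))
                chain = []
            chain.append((rank, gene))
        groups.extend(_close_chain(seq_id, chain, pac_identities, threshold, key_of))
    return groups


def _close_chain(seq_id, chain, identities, threshold, key_of) -> list:
    if len(chain) < 2:
        return []
    genes = [g for _, g in chain]
    ids = [g.gene_id for g in genes]
    keys = [key_of(g) for g in genes]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _lookup(identities, keys[i], keys[j])
    for i in range(n - 1):
        assert mat[i, i + 1] > threshold, "chained pair below threshold"
    return [TandemGroup(seq_id=seq_id, gene_ids=ids,
                        orientations=[g.strand for g in genes],
                        pairwise_identity=pd.DataFrame(mat, index=ids, columns=ids))]
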
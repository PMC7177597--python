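"""Synthetic secreted multi-domain proteins with planted ground truth.

The generator emulates the statistical structure the pipeline assumes —
a cleavable signal peptide, a PAC domain whose Cys spacings are drawn
uniformly inside the canonical bounds, type-specific associated domains
(extensin blocks, His stretches, AGP-like repeats, W-X8-W anchors), gene
models with the diagnostic intron, tandem gene clusters, and coarse 3D
models with the expected disulfide geometry — plus single-fault
corruptions so that each bona fide gate can be exercised in isolation.

Residue alphabets are deliberately constrained so that planted truth is
unambiguous: spacers inside the PAC domain exclude Cys (strict domains
are Cys-free between anchors) and Gly (no decoy anchors), and both the
spacers and the inter-domain linkers exclude His/Pro/Trp so that the
associated-domain detectors fire only on the planted blocks. Spacers are
built from alternating β-strand-favouring and coil-favouring blocks so
that corruption-free domains pass the secondary-structure gate by
construction; the ``helix_decoy`` corruption swaps in strongly
helix-favouring residues instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .filters import DomainHit
from .io_formats import GeneModel, ProteinRecord
from .scanner import DEFAULT_RULE, PacSpacingRule
from .structure_qc import Atom, StructureModel

STRAND_RESIDUES = "VIYFT"   # β-favouring, no C/G/H/P/W
COIL_RESIDUES = "SND"       # coil/turn-favouring
HELIX_RESIDUES = "AELM"     # for the helix_decoy corruption
LINKER_RESIDUES = "ADEFGIKLMNQRSTVY"  # no C/H/P/W

CORRUPTIONS = ("none", "missing_cys", "extra_cys", "gap_violation",
               "missing_gly", "helix_decoy", "foreign_domain",
               "no_signal_peptide")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated record."""

    record_id: str
    planted_type: int
    pac_span: tuple       # 0-based half-open, Gly..Cys6
    cys_positions: tuple  # 6 absolute 0-based indices
    corruption: str = "none"
    signal_peptide_end: int = 0
    tandem_group_id: Optional[str] = None
    intron_class: Optional[str] = None
    planted_domains: list = field(default_factory=list)  # (kind, start, end)


def _blocks(rng, length: int, strand_first: bool = True) -> str:
    """Alternating strand/coil blocks totalling ``length`` residues."""
    out = []
    strand = strand_first
    while sum(len(b) for b in out) < length:
        if strand:
            n = int(rng.integers(4, 7))
            pool = STRAND_RESIDUES
        else:
            n = int(rng.integers(2, 5))
            pool = COIL_RESIDUES
        out.append("".join(rng.choice(list(pool), size=n)))
        strand = not strand
    return "".join(out)[:length]


def _helix_run(rng, length: int) -> str:
    return "".join(rng.choice(list(HELIX_RESIDUES), size=length))


def _linker(rng, length: int) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list(LINKER_RESIDUES), size=length))


def _signal_peptide(rng) -> str:
    """M + charged n-region + hydrophobic h-region + 'SSA' c-region;
    passes the built-in signal gate and is recovered exactly by
    ``find_signal_peptide``."""
    n_len = int(rng.integers(1, 4))
    h_len = int(rng.integers(8, 12))
    n_region = "".join(rng.choice(list("KR"), size=n_len))
    h_region = "".join(rng.choice(list("LAVFI"), size=h_len))
    return "M" + n_region + h_region + "SSA"


def _pac_domain(rng, rule: PacSpacingRule = DEFAULT_RULE,
                spacer_style: str = "strand",
                gap_override: Optional[dict] = None) -> tuple:
    """Build a PAC domain string; returns (seq, cys_offsets) with offsets
    relative to the domain's Gly at 0."""
    gaps = [rule.gap_gly_c1, rule.gap_c1_c2]
    for lo, hi in rule.ranged_gaps():
        gaps.append(int(rng.integers(lo, hi + 1)))
    if gap_override:
        for idx, value in gap_override.items():
            gaps[idx] = value

    def spacer(n, strand_first=True):
        if spacer_style == "helix":
            return _helix_run(rng, n)
        return _blocks(rng, n, strand_first)

    parts = ["G"]
    cys_offsets = []
    pos = 1
    for k, gap in enumerate(gaps):
        parts.append(spacer(gap))
        pos += gap
        parts.append("C")
        cys_offsets.append(pos)
        pos += 1
    return "".join(parts), tuple(cys_offsets)


def generate_pdp(pdp_type: int, rng_seed, corruption: str = "none",
                 rule: PacSpacingRule = DEFAULT_RULE,
                 record_id: Optional[str] = None) -> tuple:
    """Generate one synthetic PDP and its truth; deterministic per seed.

    ``rng_seed`` may be an int seed or a ``numpy.random.Generator``.
    """
    if pdp_type not in (1, 2, 3, 4):
        raise ValueError(f"pdp_type must be 1..4, got {pdp_type}")
    if corruption not in CORRUPTIONS:
        raise ValueError(f"unknown corruption {corruption!r}; choose from {CORRUPTIONS}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    rid = record_id or f"synth_t{pdp_type}_{corruption}"

    gap_override = None
    if corruption == "gap_violation":
        # Cys3–Cys4 spacer outside (20, 50): one residue below or above
        gap_override = {3: 19 if rng.random() < 0.5 else 51}
    spacer_style = "helix" if corruption == "helix_decoy" else "strand"
    pac, cys_offsets = _pac_domain(rng, rule, spacer_style, gap_override)

    if corruption == "no_signal_peptide":
        # a polar leader longer than the 35-residue gate search window
        sp = "M" + "".join(rng.choice(list("DENQST"), size=40))
    else:
        sp = _signal_peptide(rng)

    planted: list = []
    if pdp_type == 1:
        pre, post = "", _linker(rng, int(rng.integers(0, 4)))
    elif pdp_type == 2:
        pre = ""
        link = _linker(rng, int(rng.integers(5, 16)))
        if rng.random() < 0.5:
            body = "W" + _linker(rng, 8) + "W" + _linker(rng, int(rng.integers(20, 31)))
            tail_kind = "ww"
        else:
            body = "PPA" * int(rng.integers(8, 12))
            tail_kind = "pro_rich"
        post = link + body
        planted.append((tail_kind, None, None))
    elif pdp_type == 3:
        his = "H" * int(rng.integers(5, 9))
        agp = "AP" * int(rng.integers(10, 16))
        link = _linker(rng, int(rng.integers(5, 11)))
        pre = his + agp + link
        post = _linker(rng, int(rng.integers(0, 4)))
        planted.extend([("his_rich", None, None), ("agp_like", None, None)])
    else:  # type 4
        ext = lambda: "SPPPA" * int(rng.integers(4, 7))
        ext1, ext2 = ext(), ext()
        link1 = _linker(rng, int(rng.integers(5, 11)))
        link2 = _linker(rng, int(rng.integers(5, 11)))
        pre = ext1 + link1
        post = link2 + ext2 + _linker(rng, int(rng.integers(0, 4)))
        planted.extend([("extensin", None, None), ("extensin", None, None)])

    seq = sp + pre + pac + post
    pac_start = len(sp) + len(pre)
    cys_positions = tuple(pac_start + off for off in cys_offsets)
    pac_span = (pac_start, cys_positions[-1] + 1)

    # single-fault point corruptions applied on the assembled sequence
    chars = list(seq)
    if corruption == "missing_cys":
        chars[cys_positions[2]] = "S"  # Cys3, an interior ordinal
    elif corruption == "extra_cys":
        # inside the Cys5–Cys6 spacer, close enough to Cys5 that no
        # alternative strict chain can terminate on it (gap < 25)
        offset = int(rng.integers(3, 11))
        chars[cys_positions[4] + 1 + offset] = "C"
    elif corruption == "missing_gly":
        chars[pac_span[0]] = "A"
    seq = "".join(chars)

    record = ProteinRecord(id=rid, sequence=seq, description=f"synthetic type {pdp_type}")
    truth = SyntheticTruth(record_id=rid, planted_type=pdp_type,
                           pac_span=pac_span, cys_positions=cys_positions,
                           corruption=corruption,
                           signal_peptide_end=len(sp) if corruption != "no_signal_peptide" else 0,
                           planted_domains=planted)
    return record, truth


def domain_hits_for(record: ProteinRecord, truth: SyntheticTruth) -> list[DomainHit]:
    """External-annotation hits accompanying a synthetic record (a
    confident intracellular PF00171 hit for the foreign_domain
    corruption, none otherwise)."""
    if truth.corruption == "foreign_domain":
        end = min(len(record.sequence), truth.pac_span[1] + 40)
        return [DomainHit(record_id=record.id, accession="PF00171",
                          start=max(1, truth.pac_span[0] - 10), end=end, evalue=1e-30)]
    return []


# ---------------------------------------------------------------------------
# gene models

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_STOPS = ["TAA", "TAG", "TGA"]


def back_translate(protein: str, rng) -> str:
    """Random synonymous back-translation, with a stop codon appended."""
    codons = [str(rng.choice(_CODONS[c])) for c in protein]
    codons.append(str(rng.choice(_STOPS)))
    return "".join(codons)


def generate_gene_model(record: ProteinRecord, truth: SyntheticTruth,
                        intron_class: str = "none", rng_seed=0,
                        flank: int = 100) -> tuple:
    """Build a gene model (and its contig) whose CDS translates exactly to
    the record's protein, with an intron planted per ``intron_class``:
    ``diagnostic`` between the Cys2 and Cys3 codons, ``atypical`` between
    Cys4 and Cys5, ``none`` for an intronless gene."""
    if intron_class not in ("none", "diagnostic", "atypical"):
        raise ValueError(f"unknown intron_class {intron_class!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    cds = back_translate(record.sequence, rng)
    c2, c3 = truth.cys_positions[1], truth.cys_positions[2]
    c4, c5 = truth.cys_positions[3], truth.cys_positions[4]

    junction = None
    if intron_class == "diagnostic":
        junction = int(rng.integers(3 * c2 + 3, 3 * c3 + 1))
    elif intron_class == "atypical":
        junction = int(rng.integers(3 * c4 + 3, 3 * c5 + 1))

    def random_nt(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    gene_id = truth.record_id + "_g"
    if junction is None:
        contig = random_nt(flank) + cds + random_nt(flank)
        exons = [(flank + 1, flank + len(cds))]
    else:
        intron = "GT" + random_nt(60) + "AG"
        contig = random_nt(flank) + cds[:junction] + intron + cds[junction:] + random_nt(flank)
        exons = [(flank + 1, flank + junction),
                 (flank + junction + len(intron) + 1, flank + len(cds) + len(intron))]
    model = GeneModel(gene_id=gene_id, seq_id=truth.record_id + "_contig",
                      strand="+", exons=exons, cds_segments=list(exons),
                      protein_id=record.id)
    truth.intron_class = intron_class
    return model, contig


# ---------------------------------------------------------------------------
# tandem clusters


def generate_tandem_cluster(n: int, identity_target: float, rng_seed,
                            scaffold: str = "tandem_scaffold",
                            spacing: int = 300) -> tuple:
    """Duplicate a seed PAC gene into ``n`` adjacent copies whose pairwise
    PAC identity is within ±3 points of ``identity_target``.

    Each copy receives its own disjoint set of k spacer-site point
    mutations with k = round(L·(100−target)/200), so any two copies differ
    at exactly 2k sites: identity = (L−2k)/L·100.
    Returns (records, truths, gene_models).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 50 < identity_target <= 100:
        raise ValueError("identity_target must be in (50, 100]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    seed_record, seed_truth = generate_pdp(1, rng, record_id="tandem_seed")
    span = seed_truth.pac_span
    L = span[1] - span[0]
    k = int(round(L * (100.0 - identity_target) / 200.0))
    anchors = {seed_truth.pac_span[0], *seed_truth.cys_positions}
    eligible = [p for p in range(span[0], span[1]) if p not in anchors]
    if n * k > len(eligible):
        raise ValueError("identity target too low for the domain length")
    sites = rng.permutation(eligible)

    spacer_pool = list(STRAND_RESIDUES + COIL_RESIDUES)
    records, truths, models = [], [], []
    offset = 1
    for g in range(n):
        chars = list(seed_record.sequence)
        for p in sites[g * k:(g + 1) * k]:
            choices = [c for c in spacer_pool if c != chars[p]]
            chars[p] = str(rng.choice(choices))
        rid = f"tandem_{g + 1}"
        rec = ProteinRecord(id=rid, sequence="".join(chars),
                            description="synthetic tandem copy")
        truth = SyntheticTruth(record_id=rid, planted_type=1,
                               pac_span=span, cys_positions=seed_truth.cys_positions,
                               signal_peptide_end=seed_truth.signal_peptide_end,
                               tandem_group_id=f"{scaffold}_tg1")
        cds = back_translate(rec.sequence, rng)
        exons = [(offset, offset + len(cds) - 1)]
        models.append(GeneModel(gene_id=rid + "_g", seq_id=scaffold, strand="+",
                                exons=exons, cds_segments=exons, protein_id=rid))
        offset += len(cds) + spacing
        records.append(rec)
        truths.append(truth)
    return records, truths, models


# ---------------------------------------------------------------------------
# coarse structures


def generate_structure(truth: SyntheticTruth, rng_seed=0,
                       swap: bool = False) -> StructureModel:
    """Coarse 3D model realising the expected disulfide geometry.

    SG atoms of the bridge partners sit 2.05 Å apart at three well
    separated sites; all other SG–SG pairs are > 6 Å. ``swap=True``
    instead pairs (1,2), (3,4), (5,6) — a wrong topology that the bridge
    check must reject. CA atoms trace a simple extended backbone.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    pairs = [(1, 2), (3, 4), (5, 6)] if swap else [(1, 5), (3, 4), (2, 6)]
    centers = {0: np.array([0.0, 20.0, 0.0]),
               1: np.array([20.0, 20.0, 0.0]),
               2: np.array([40.0, 20.0, 0.0])}
    sg_pos: dict = {}
    for idx, (a, b) in enumerate(pairs):
        c = centers[idx]
        sg_pos[a] = c + np.array([-1.025, 0.0, 0.0])
        sg_pos[b] = c + np.array([+1.025, 0.0, 0.0])

    span_start, span_end = truth.pac_span
    cys_res = {p + 1 for p in truth.cys_positions}  # 1-based residue indices
    ordinal_of = {p + 1: k + 1 for k, p in enumerate(truth.cys_positions)}
    atoms = []
    for res in range(span_start + 1, span_end + 1):
        x = (res - span_start) * 3.8
        is_cys = res in cys_res
        atoms.append(Atom(res, "CYS" if is_cys else "GLY", "CA", x, 0.0, 0.0))
        if is_cys:
            sx, sy, sz = sg_pos[ordinal_of[res]]
            atoms.append(Atom(res, "CYS", "SG", float(sx), float(sy), float(sz)))
    return StructureModel(atoms=atoms)


def cys_residue_indices(truth: SyntheticTruth) -> dict:
    """Ordinal → 1-based residue index mapping for generated structures."""
    return {k + 1: p + 1 for k, p in enumerate(truth.cys_positions)}
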
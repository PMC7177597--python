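"""Structure-level QC: disulfide topology validation and solvent
accessibility on coordinate models.

The PAC fold is a disulfide-stabilised β-barrel with a specific branched
topology — Cys1–Cys5, Cys3–Cys4 and Cys2–Cys6 — so a model is accepted
only when those three SG–SG pairs are bonded and no other Cys pair is
within bonding distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

log = logging.getLogger(__name__)

EXPECTED_PAIRS = frozenset({(1, 5), (3, 4), (2, 6)})

#: van der Waals radii (Å) by element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4

#: theoretical Gly-X-Gly maximum accessible surface areas (Å², Tien 2013)
MAX_ASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class Atom:
    residue_index: int  # 1-based
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def element(self) -> str:
        name = self.atom_name.strip()
        return name[0] if name else "C"


@dataclass
class StructureModel:
    """A coordinate model as a flat atom list (single chain)."""

    atoms: list
    chain_id: str = "A"

    def __post_init__(self):
        prev = None
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates at residue {a.residue_index}")
            if prev is not None and a.residue_index < prev:
                raise ValueError("residue indices must be non-decreasing")
            prev = a.residue_index

    def residues(self) -> dict:
        out: dict = {}
        for a in self.atoms:
            out.setdefault(a.residue_index, []).append(a)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        rot = np.asarray(rotation)
        tr = np.asarray(translation)
        atoms = []
        for a in self.atoms:
            xyz = rot @ a.coords + tr
            atoms.append(Atom(a.residue_index, a.residue_name, a.atom_name, *xyz))
        return StructureModel(atoms=atoms, chain_id=self.chain_id)


def read_pdb(path, chain_id: Optional[str] = None) -> StructureModel:
    """Read ATOM records from a PDB file into a StructureModel."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model = next(structure.get_models())
    atoms = []
    picked_chain = None
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        picked_chain = chain.id
        for residue in chain:
            for atom in residue:
                x, y, z = atom.coord
                atoms.append(Atom(residue.id[1], residue.resname.strip(),
                                  atom.name, float(x), float(y), float(z)))
        break
    if not atoms:
        raise ValueError(f"no ATOM records read from {path}")
    return StructureModel(atoms=atoms, chain_id=picked_chain or "A")


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal single-chain PDB file (ATOM records only)."""
    with open(path, "w") as fh:
        for serial, a in enumerate(model.atoms, start=1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {serial:5d} {name:<4s}{a.residue_name:>4s} {model.chain_id}"
                f"{a.residue_index:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                f"  1.00  0.00          {a.element:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# disulfide topology


@dataclass
class BridgeReport:
    """Observed SG–SG contacts against the expected PAC topology."""

    expected_pairs: frozenset
    observed: list  # [((ordinal_a, ordinal_b), distance), ...]
    verdict: str
    missing: list = field(default_factory=list)
    extra: list = field(default_factory=list)


def check_disulfides(model: StructureModel, cys_ordinals,
                     threshold: float = 2.5) -> BridgeReport:
    """Validate the Cys1–Cys5 / Cys3–Cys4 / Cys2–Cys6 bridge topology.

    ``cys_ordinals`` maps PAC Cys ordinal 1–6 to the residue index in the
    model (a dict, or a sequence in ordinal order). The verdict is pass
    only when all three expected pairs have SG atoms within ``threshold``
    Å and no other ordinal pair does; the default 2.5 Å is the ~2.05 Å
    covalent S–S length plus model slack.
    """
    if not isinstance(cys_ordinals, dict):
        cys_ordinals = {i + 1: r for i, r in enumerate(cys_ordinals)}
    if sorted(cys_ordinals) != [1, 2, 3, 4, 5, 6]:
        raise ValueError("cys_ordinals must cover ordinals 1..6")
    sg: dict = {}
    by_res = model.residues()
    for ordinal, res_idx in cys_ordinals.items():
        atoms = by_res.get(res_idx, [])
        sg_atom = next((a for a in atoms if a.atom_name.strip() == "SG"), None)
        if sg_atom is None:
            raise ValueError(f"missing SG atom for Cys {ordinal} (residue {res_idx})")
        sg[ordinal] = sg_atom.coords

    observed = []
    within = set()
    for i in range(1, 7):
        for j in range(i + 1, 7):
            d = float(np.linalg.norm(sg[i] - sg[j]))
            if d <= threshold:
                observed.append(((i, j), d))
                within.add((i, j))
    missing = sorted(p for p in EXPECTED_PAIRS if p not in within)
    extra = sorted(p for p in within if p not in EXPECTED_PAIRS)
    verdict = "pass" if not missing and not extra else "fail"
    return BridgeReport(expected_pairs=EXPECTED_PAIRS, observed=observed,
                        verdict=verdict, missing=missing, extra=extra)


# ---------------------------------------------------------------------------
# Shrake–Rupley solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_asa(model: StructureModel, n_points: int = 960,
                      probe: float = PROBE_RADIUS) -> dict:
    """Per-residue accessible surface area (Å²) by Shrake–Rupley.

    Each atom's solvent-accessible sphere (vdW radius + probe) is sampled
    at ``n_points`` test points; points inside any neighbouring atom's
    accessible sphere are occluded.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    atoms = model.atoms
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.empty(len(atoms))
    warned: set = set()
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in VDW_RADII and el not in warned:
            log.warning("unknown element %r: using default radius %.2f Å", el, DEFAULT_RADIUS)
            warned.add(el)
        radii[i] = VDW_RADII.get(el, DEFAULT_RADIUS)
    acc = radii + probe
    unit = _sphere_points(n_points)

    residue_asa: dict = {}
    for i, a in enumerate(atoms):
        pts = coords[i] + acc[i] * unit
        d2 = np.sum((coords[None, :, :] - pts[:, None, :]) ** 2, axis=2)
        thr2 = acc ** 2
        occluded = d2 < thr2[None, :]
        occluded[:, i] = False
        free = ~occluded.any(axis=1)
        area = 4.0 * math.pi * acc[i] ** 2 * free.mean()
        residue_asa[a.residue_index] = residue_asa.get(a.residue_index, 0.0) + area
    return residue_asa


def shrake_rupley_rsa(model: StructureModel, n_points: int = 960,
                      probe: float = PROBE_RADIUS,
                      reference: str = "self") -> dict:
    """Per-residue relative solvent accessibility, clipped to [0, 1.2].

    ``reference="self"`` (default) normalises by each residue's own
    surface computed in isolation with the same algorithm, which is exact
    for coarse synthetic models; ``reference="gxg"`` uses the bundled
    Gly-X-Gly theoretical maxima and is the conventional choice for
    full-atom models.
    """
    asa = shrake_rupley_asa(model, n_points=n_points, probe=probe)
    by_res = model.residues()
    rsa: dict = {}
    for res_idx, area in asa.items():
        if reference == "self":
            iso = StructureModel(atoms=by_res[res_idx])
            ref = sum(shrake_rupley_asa(iso, n_points=n_points, probe=probe).values())
        elif reference == "gxg":
            resname = by_res[res_idx][0].residue_name
            ref = MAX_ASA_GXG.get(resname)
            if ref is None:
                log.warning("no Gly-X-Gly reference for %s; using 200 Å²", resname)
                ref = 200.0
        else:
            raise ValueError("reference must be 'self' or 'gxg'")
        rsa[res_idx] = float(np.clip(area / ref, 0.0, 1.2))
    return rsa


# ---------------------------------------------------------------------------
# strand counting


def count_strands(ss_track, span: Optional[tuple] = None, min_len: int = 2) -> int:
    """Number of maximal E-runs of length ≥ ``min_len`` over ``span``
    (whole track when omitted). Accepts a track object or plain string."""
    ss = ss_track.ss if hasattr(ss_track, "ss") else str(ss_track)
    if span is not None:
        ss = ss[span[0]:span[1]]
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
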
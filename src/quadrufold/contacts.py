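"""Geometric protein-RNA contact counting on structure frames.

Counts hydrogen bonds, salt bridges, and stacking interactions between a
protein (e.g. an Arg/Ser-rich region) and an RNA across the frames of a
trajectory sampled into a multi-model PDB. Criteria follow standard MD
practice:

* hydrogen bond: donor-acceptor distance <= 3.5 A and donor-H-acceptor
  angle >= 120 deg (the inclusive boundary is deliberate and tested);
* salt bridge: minimum N-O distance between a cationic side-chain group
  (Arg guanidinium N, Lys NZ) and an anionic group (phosphate OP1/OP2)
  strictly below 4.0 A;
* stacking: ring-centroid to ring-centroid distance strictly below 4.0 A
  with the angle between ring-plane normals within 30 deg. The Arg
  guanidinium is treated as a planar cation-pi partner alongside aromatic
  rings.

H-bonds are attributed to the RNA moiety they touch (base, ribose or
phosphate) and all classes to the protein residue type (Arg/Ser/Tyr/other),
matching how per-frame interaction budgets of arginine-rich peptides bound
to unfolded quadruplexes are usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "AtomRecord",
    "ContactCriteria",
    "HBond",
    "SaltBridge",
    "Stacking",
    "ContactReport",
    "read_frames",
    "write_frames",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_stacking",
    "contact_report",
    "backbone_rmsd",
]

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_RNA_BASES = {"A", "G", "C", "U"}


def _rna_base(res_name: str) -> Optional[str]:
    """Base letter for RNA residue names (A/G/C/U, RA/RG/.., G5/G3 ..)."""
    n = res_name.strip().upper()
    if n in _RNA_BASES:
        return n
    if len(n) == 2 and n[0] == "R" and n[1] in _RNA_BASES:
        return n[1]
    if len(n) == 2 and n[0] in _RNA_BASES and n[1] in "53":
        return n[0]
    return None


# RNA moieties by atom name (primes normalized from * to ')
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
RIBOSE_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O4'"}

# H-bond chemistry table: heavy-atom donors and acceptors
PROTEIN_DONORS = {
    "*": {"N"},  # backbone amide
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "CYS": {"SG"},
}
PROTEIN_ACCEPTORS = {
    "*": {"O", "OXT"},  # backbone carbonyl
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
RNA_DONORS = {
    "G": {"N1", "N2", "O2'"},
    "A": {"N6", "O2'"},
    "C": {"N4", "O2'"},
    "U": {"N3", "O2'"},
}
RNA_ACCEPTORS = {
    "G": {"O6", "N3", "N7", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
    "A": {"N1", "N3", "N7", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
    "C": {"O2", "N3", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
    "U": {"O2", "O4", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
}

# cationic / anionic side-chain groups for salt bridges
CATIONIC_GROUPS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
ANIONIC_RNA_ATOMS = ("OP1", "OP2", "OP3")
ANIONIC_PROTEIN_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

# planar groups for stacking
PROTEIN_RINGS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "ARG": ("CZ", "NE", "NH1", "NH2"),  # guanidinium cation-pi plane
}
PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

MAX_DH_BOND = 1.25  # A; H considered covalently attached to its donor


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure frame (coordinates in Angstrom)."""

    name: str
    element: str
    res_name: str
    res_id: int
    chain_id: str
    coord: tuple[float, float, float]

    @property
    def is_protein(self) -> bool:
        return self.res_name.upper() in PROTEIN_RESIDUES

    @property
    def base(self) -> Optional[str]:
        return _rna_base(self.res_name)

    @property
    def is_rna(self) -> bool:
        return self.base is not None

    @property
    def moiety(self) -> Optional[str]:
        """RNA moiety: 'phosphate', 'ribose' or 'base' (None for protein)."""
        if not self.is_rna:
            return None
        n = self.name
        if n in PHOSPHATE_ATOMS:
            return "phosphate"
        if n in RIBOSE_ATOMS or (n.startswith("H") and "'" in n):
            return "ribose"
        return "base"


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs; defaults are the standard MD-analysis values."""

    hbond_distance_max: float = 3.5   # A, donor-acceptor, inclusive
    hbond_angle_min: float = 120.0    # deg, donor-H-acceptor, inclusive
    saltbridge_distance_max: float = 4.0  # A, min N-O, strict
    stacking_distance_max: float = 4.0    # A, centroid-centroid, strict
    stacking_angle_max: float = 30.0      # deg, between plane normals, incl.

    def __post_init__(self):
        for f in (
            "hbond_distance_max", "saltbridge_distance_max",
            "stacking_distance_max",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not (0 < self.hbond_angle_min <= 180):
            raise ValueError("hbond_angle_min must be in (0, 180]")
        if not (0 < self.stacking_angle_max <= 180):
            raise ValueError("stacking_angle_max must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    donor: AtomRecord
    hydrogen: AtomRecord
    acceptor: AtomRecord
    distance: float
    angle: float
    target: str  # base | ribose | phosphate (RNA side)
    residue_type: str  # protein residue 3-letter code


@dataclass(frozen=True)
class SaltBridge:
    cation_res: tuple[str, str, int]  # (res_name, chain, res_id)
    anion_res: tuple[str, str, int]
    distance: float


@dataclass(frozen=True)
class Stacking:
    protein_res: tuple[str, str, int]
    base_res: tuple[str, str, int]
    distance: float
    angle: float


# ---------------------------------------------------------------------------
# frame I/O

def _normalize_name(name: str) -> str:
    return name.strip().replace("*", "'")


def read_frames(path: Union[str, Path]) -> list[list[AtomRecord]]:
    """Read a multi-model PDB into one frame (atom list) per model.

    Atom order is preserved. Models with atom counts differing from the
    first model are flagged with a warning but still returned.
    """
    path = Path(path)
    _prescan_pdb(path)
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    frames = []
    for i in range(1, n_models + 1):
        arr = pdb_file.get_structure(model=i)
        frame = []
        for j in range(arr.array_length()):
            name = _normalize_name(str(arr.atom_name[j]))
            element = str(arr.element[j]).strip() or name[0]
            frame.append(
                AtomRecord(
                    name=name,
                    element=element,
                    res_name=str(arr.res_name[j]).strip(),
                    res_id=int(arr.res_id[j]),
                    chain_id=str(arr.chain_id[j]).strip(),
                    coord=tuple(float(x) for x in arr.coord[j]),
                )
            )
        frames.append(frame)
    n0 = len(frames[0]) if frames else 0
    for i, f in enumerate(frames):
        if len(f) != n0:
            warnings.warn(
                f"model {i + 1} has {len(f)} atoms (first model has {n0})"
            )
    if not frames:
        raise ValueError(f"no models found in {path}")
    return frames


def _prescan_pdb(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                raise ValueError(
                    f"{path}:{lineno}: truncated coordinate record"
                )


def write_frames(
    frames: Sequence[Sequence[AtomRecord]], path: Union[str, Path]
) -> None:
    """Write frames as a multi-model PDB (one MODEL per frame)."""
    arrays = []
    for frame in frames:
        arr = struc.AtomArray(len(frame))
        for j, a in enumerate(frame):
            arr.coord[j] = a.coord
            arr.atom_name[j] = a.name
            arr.element[j] = a.element
            arr.res_name[j] = a.res_name
            arr.res_id[j] = a.res_id
            arr.chain_id[j] = a.chain_id
        arr.hetero[:] = False
        arrays.append(arr)
    stack = struc.stack(arrays)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# detection

def _coords(frame: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.coord for a in frame], dtype=float)


def _donor_atoms(frame, protein: bool):
    """(donor atom, attached hydrogens) pairs on one side of the interface."""
    out = []
    # index hydrogens by (chain, res_id)
    hydro: dict[tuple, list[AtomRecord]] = {}
    for a in frame:
        if a.element.upper() == "H":
            hydro.setdefault((a.chain_id, a.res_id), []).append(a)
    for a in frame:
        if a.element.upper() == "H":
            continue
        if protein:
            if not a.is_protein:
                continue
            names = PROTEIN_DONORS.get(a.res_name.upper(), set()) | PROTEIN_DONORS["*"]
        else:
            if not a.is_rna:
                continue
            names = RNA_DONORS.get(a.base, set())
        if a.name not in names:
            continue
        hs = [
            h for h in hydro.get((a.chain_id, a.res_id), [])
            if np.linalg.norm(np.subtract(h.coord, a.coord)) <= MAX_DH_BOND
        ]
        if hs:
            out.append((a, hs))
    return out


def _acceptor_atoms(frame, protein: bool):
    out = []
    for a in frame:
        if a.element.upper() == "H":
            continue
        if protein:
            if not a.is_protein:
                continue
            names = PROTEIN_ACCEPTORS.get(a.res_name.upper(), set()) | PROTEIN_ACCEPTORS["*"]
        else:
            if not a.is_rna:
                continue
            names = RNA_ACCEPTORS.get(a.base, set())
        if a.name in names:
            out.append(a)
    return out


def _angle_deg(p1, p2, p3) -> float:
    """Angle at p2 (deg) of the p1-p2-p3 triple."""
    v1 = np.subtract(p1, p2)
    v2 = np.subtract(p3, p2)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(
    frame: Sequence[AtomRecord], criteria: ContactCriteria = ContactCriteria()
) -> list[HBond]:
    """Protein-RNA hydrogen bonds in one frame (both donor directions).

    One H-bond per unique donor-acceptor atom pair: the best (largest
    angle) attached hydrogen is reported. Frames without any hydrogens
    cannot be assessed and raise.
    """
    if not any(a.element.upper() == "H" for a in frame):
        raise ValueError(
            "frame contains no hydrogens; supply MD-protonated frames"
        )
    bonds = []
    for protein_is_donor in (True, False):
        donors = _donor_atoms(frame, protein=protein_is_donor)
        acceptors = _acceptor_atoms(frame, protein=not protein_is_donor)
        if not donors or not acceptors:
            continue
        d_xyz = np.array([d.coord for d, _ in donors])
        a_xyz = np.array([a.coord for a in acceptors])
        dmat = cdist(d_xyz, a_xyz)
        for di, ai in zip(*np.nonzero(dmat <= criteria.hbond_distance_max)):
            donor, hs = donors[di]
            acceptor = acceptors[ai]
            best = None
            for h in hs:
                ang = _angle_deg(donor.coord, h.coord, acceptor.coord)
                if ang >= criteria.hbond_angle_min and (
                    best is None or ang > best[1]
                ):
                    best = (h, ang)
            if best is None:
                continue
            rna_atom = acceptor if protein_is_donor else donor
            prot_atom = donor if protein_is_donor else acceptor
            bonds.append(
                HBond(
                    donor=donor,
                    hydrogen=best[0],
                    acceptor=acceptor,
                    distance=float(dmat[di, ai]),
                    angle=best[1],
                    target=rna_atom.moiety,
                    residue_type=prot_atom.res_name.upper(),
                )
            )
    return bonds


def _group_atoms(frame, spec: dict, protein: bool):
    """Collect residue groups: {(res_name, chain, res_id): [atoms]}."""
    groups: dict[tuple, list[AtomRecord]] = {}
    for a in frame:
        if protein and not a.is_protein:
            continue
        if not protein and not a.is_rna:
            continue
        key_res = a.res_name.upper() if protein else a.base
        names = spec.get(key_res)
        if names and a.name in names:
            groups.setdefault((a.res_name.upper(), a.chain_id, a.res_id), []).append(a)
    return groups


def detect_salt_bridges(
    frame: Sequence[AtomRecord], criteria: ContactCriteria = ContactCriteria()
) -> list[SaltBridge]:
    """Cationic protein group vs RNA phosphate contacts, one per group pair.

    A bridge exists when the minimum nitrogen-oxygen distance between the
    groups is strictly below the cutoff.
    """
    cations = _group_atoms(frame, {k: set(v) for k, v in CATIONIC_GROUPS.items()}, True)
    anions = _group_atoms(
        frame, {b: set(ANIONIC_RNA_ATOMS) for b in _RNA_BASES}, False
    )
    bridges = []
    for ckey, catoms in cations.items():
        c_xyz = np.array([a.coord for a in catoms])
        for akey, aatoms in anions.items():
            a_xyz = np.array([a.coord for a in aatoms])
            dmin = float(cdist(c_xyz, a_xyz).min())
            if dmin < criteria.saltbridge_distance_max:
                bridges.append(SaltBridge(ckey, akey, dmin))
    return bridges


def _plane_normal(xyz: np.ndarray) -> Optional[np.ndarray]:
    """Unit normal of the least-squares plane; None when degenerate."""
    centered = xyz - xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-6:  # collinear points define no plane
        return None
    return vt[2]


def detect_stacking(
    frame: Sequence[AtomRecord], criteria: ContactCriteria = ContactCriteria()
) -> list[Stacking]:
    """Planar-group stacking between protein rings/guanidinium and bases.

    Contact when ring-centroid distance is strictly below the cutoff and
    the angle between the plane normals (folded to [0, 90] deg) is within
    the angular tolerance. Degenerate (collinear) groups are skipped with
    a warning.
    """
    prings = _group_atoms(frame, {k: set(v) for k, v in PROTEIN_RINGS.items()}, True)
    base_spec = {
        "G": set(PURINE_RING), "A": set(PURINE_RING),
        "C": set(PYRIMIDINE_RING), "U": set(PYRIMIDINE_RING),
    }
    brings = _group_atoms(frame, base_spec, False)

    def plane(atoms, key):
        if len(atoms) < 3:
            return None, None
        xyz = _coords(atoms)
        n = _plane_normal(xyz)
        if n is None:
            warnings.warn(f"degenerate planar group {key}; skipped")
            return None, None
        return xyz.mean(axis=0), n

    contacts = []
    for pkey, patoms in prings.items():
        pc, pn = plane(patoms, pkey)
        if pc is None:
            continue
        for bkey, batoms in brings.items():
            bc, bn = plane(batoms, bkey)
            if bc is None:
                continue
            dist = float(np.linalg.norm(pc - bc))
            if dist >= criteria.stacking_distance_max:
                continue
            cosang = abs(float(np.dot(pn, bn)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if ang <= criteria.stacking_angle_max:
                contacts.append(Stacking(pkey, bkey, dist, ang))
    return contacts


# ---------------------------------------------------------------------------
# reporting

RESIDUE_TYPES = ("ARG", "SER", "TYR")


def _restype(res_name: str) -> str:
    return res_name if res_name in RESIDUE_TYPES else "other"


@dataclass
class ContactReport:
    """Per-frame contact counts with residue-type attribution.

    ``per_frame`` has one row per frame with columns hbond_base,
    hbond_backbone, salt_bridge, stacking. ``base_hbond_by_residue``
    counts only base-targeting H-bonds, split by Arg/Ser/Tyr/other —
    the view used when asking which residue type reads out the bases.
    """

    per_frame: pd.DataFrame
    by_residue: dict
    base_hbond_by_residue: dict
    n_frames: int

    def means(self) -> dict:
        return {c: float(self.per_frame[c].mean()) for c in self.per_frame.columns}

    def sds(self) -> dict:
        ddof = 1 if self.n_frames > 1 else 0
        return {c: float(self.per_frame[c].std(ddof=ddof)) for c in self.per_frame.columns}

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "per_frame_mean": self.means(),
            "per_frame_sd": self.sds(),
            "by_residue": self.by_residue,
            "base_hbond_by_residue": self.base_hbond_by_residue,
        }


def contact_report(
    frames: Sequence[Sequence[AtomRecord]],
    criteria: ContactCriteria = ContactCriteria(),
) -> ContactReport:
    """Count all three contact classes in every frame and attribute them."""
    if not frames:
        raise ValueError("no frames")
    rows = []
    by_res = {t: {"hbond": 0, "salt_bridge": 0, "stacking": 0}
              for t in (*RESIDUE_TYPES, "other")}
    base_hb = {t: 0 for t in (*RESIDUE_TYPES, "other")}
    for frame in frames:
        hbonds = detect_hbonds(frame, criteria)
        sbs = detect_salt_bridges(frame, criteria)
        stacks = detect_stacking(frame, criteria)
        n_base = sum(1 for b in hbonds if b.target == "base")
        rows.append(
            {
                "hbond_base": n_base,
                "hbond_backbone": len(hbonds) - n_base,
                "salt_bridge": len(sbs),
                "stacking": len(stacks),
            }
        )
        for b in hbonds:
            t = _restype(b.residue_type)
            by_res[t]["hbond"] += 1
            if b.target == "base":
                base_hb[t] += 1
        for s in sbs:
            by_res[_restype(s.cation_res[0])]["salt_bridge"] += 1
        for s in stacks:
            by_res[_restype(s.protein_res[0])]["stacking"] += 1
    return ContactReport(
        per_frame=pd.DataFrame(rows),
        by_residue=by_res,
        base_hbond_by_residue=base_hb,
        n_frames=len(frames),
    )


def aggregate_replicates(reports: Sequence[ContactReport]) -> dict:
    """Mean +/- SD of per-frame means across replicate trajectories."""
    if not reports:
        raise ValueError("no replicate reports")
    cols = reports[0].per_frame.columns
    out = {}
    for c in cols:
        vals = np.array([r.means()[c] for r in reports])
        out[c] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
        }
    return out


BACKBONE_NAMES = {"N", "CA", "C", "O", "P", "O5'", "C5'", "C4'", "C3'", "O3'"}


def backbone_rmsd(
    frames: Sequence[Sequence[AtomRecord]],
    atom_names: Optional[set] = None,
) -> np.ndarray:
    """Backbone RMSD of every frame to the first, after Kabsch superposition.

    A quick equilibration check: a flat tail indicates a settled system.
    ``atom_names`` overrides the default backbone selection; pass an empty
    set to superpose on all non-hydrogen atoms.
    """
    names = BACKBONE_NAMES if atom_names is None else atom_names
    idx = [
        i for i, a in enumerate(frames[0])
        if (a.name in names) or (not names and a.element.upper() != "H")
    ]
    if not idx:
        raise ValueError("no backbone atoms found")
    ref = _coords(frames[0])[idx]
    ref0 = ref - ref.mean(axis=0)
    out = []
    for frame in frames:
        xyz = _coords(frame)[idx]
        x0 = xyz - xyz.mean(axis=0)
        h = x0.T @ ref0
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        out.append(float(np.sqrt(np.mean(np.sum((x0 @ rot - ref0) ** 2, axis=1)))))
    return np.array(out)
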
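"""Per-residue structural features from a protein structure.

Parses a PDB file into a light-weight residue/atom model and computes the
per-residue properties used as classifier features: solvent-accessible
surface area (Shrake-Rupley), an approximate solvent-excluded area,
Kyte-Doolittle hydropathy, backbone torsions (phi/psi), the mean
crystallographic B-factor, and an evolutionary conservation score joined
from an external per-position file (lower = more conserved).

Missing values are represented as ``math.nan`` / pandas ``NaN`` — that is
the explicit missing marker throughout; a feature is never silently zero.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "StructureFormatError",
    "EmptyStructureError",
    "RadiusConfigurationError",
    "parse_structure",
    "shrake_rupley",
    "compute_surfaces",
    "compute_torsions",
    "assemble_residue_features",
    "load_conservation",
    "KD_HYDROPATHY",
    "VDW_RADII",
    "FEATURE_COLUMNS",
]


class StructureFormatError(ValueError):
    """Raised when the PDB text cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a structure contains no standard amino-acid residue."""


class RadiusConfigurationError(ValueError):
    """Raised when an atom's element has no van der Waals radius."""


# Kyte & Doolittle (1982) hydropathy scale, one-letter codes.
KD_HYDROPHATHY_DOC = "positive = hydrophobic"
KD_HYDROPATHY: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Van der Waals radii (Bondi), Angstrom; heavy atoms of proteins plus
# common ligand elements.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20, "D": 1.20,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Modified residues mapped onto their standard parent; anything else
# non-standard is skipped with a warning.
NONSTANDARD_MAP: dict[str, str] = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS"}

FEATURE_COLUMNS = [
    "areaSAS", "areaSES", "kdHydrophobicity", "PSI", "PHI",
    "bFactor", "conservation",
]

# Peptide C-N bond beyond this distance is treated as a chain break.
CHAIN_BREAK_CN = 2.5


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    bfactor: float
    occupancy: float


@dataclass
class Residue:
    """One standard amino-acid residue with its heavy atoms."""

    chain: str
    seq_position: int
    insertion_code: str  # "" when absent
    aa: str  # one-letter code
    resname: str  # original three-letter name
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_position, self.insertion_code)

    @property
    def node_id(self) -> str:
        return f"{self.chain}:{self.seq_position}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def bfactor(self) -> float:
        if not self.atoms:
            return math.nan
        return float(np.mean([a.bfactor for a in self.atoms]))


def _pick_altloc(bio_atom):
    """Resolve a disordered atom: highest occupancy, then alphabetical altloc."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def parse_structure(pdb_text: str) -> list[Residue]:
    """Parse PDB text into an ordered list of standard residues.

    First model only; alternate locations resolved to the highest-occupancy
    conformer; selenomethionine (and other mapped modified residues) are
    treated as their standard parent; waters, ligands and hydrogens are
    dropped.  Residues are sorted by (chain, seq_position, insertion_code).
    """
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises assorted exceptions
        raise StructureFormatError(f"unparseable PDB input: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError("structure contains no model")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            resname = res.get_resname().strip()
            if resname in NONSTANDARD_MAP:
                resname = NONSTANDARD_MAP[resname]
            elif hetfield.strip():
                continue  # water / ligand
            one = THREE_TO_ONE.get(resname)
            if one is None:
                logger.warning(
                    "skipping non-standard residue %s %s%s", resname, resseq, icode
                )
                continue
            atoms = []
            for bio_atom in res:
                a = _pick_altloc(bio_atom)
                element = (a.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=a.get_name().strip(),
                        element=element,
                        coord=tuple(float(x) for x in a.get_coord()),
                        bfactor=float(a.get_bfactor() or 0.0),
                        occupancy=float(a.get_occupancy() or 1.0),
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain=chain.id.strip() or "A",
                    seq_position=int(resseq),
                    insertion_code=icode.strip(),
                    aa=one,
                    resname=resname,
                    atoms=atoms,
                )
            )
    if not residues:
        raise EmptyStructureError("no standard amino-acid residues with coordinates")
    residues.sort(key=lambda r: (r.chain, r.seq_position, r.insertion_code))
    return residues


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Shrake-Rupley algorithm.

    Each atom's expanded sphere (vdW + probe) is sampled with a fixed
    deterministic point set; a point is exposed when it lies outside every
    neighbouring atom's expanded sphere.  Deterministic for a fixed
    ``n_sphere_points``; accuracy improves as the point count grows.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    unit = _sphere_points(n_sphere_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_r = expanded.max() if n else 0.0
    areas = np.empty(n)
    for i in range(n):
        neigh = tree.query_ball_point(coords[i], expanded[i] + max_r)
        neigh = [j for j in neigh if j != i]
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= expanded[i] + expanded[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.sum() / n_sphere_points
    return areas


def _atom_radii(residues: list[Residue], overrides: dict[str, float] | None):
    table = dict(VDW_RADII)
    if overrides:
        table.update({k.upper(): v for k, v in overrides.items()})
    radii = []
    for res in residues:
        for a in res.atoms:
            r = table.get(a.element)
            if r is None:
                raise RadiusConfigurationError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.name} in {res.node_id}); pass radius_overrides"
                )
            radii.append(r)
    return np.array(radii)


def compute_surfaces(
    residues: list[Residue],
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    ses_backend: str | None = "probe0",
    radius_overrides: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue areaSAS and areaSES.

    areaSAS is the Shrake-Rupley solvent-accessible area with the given
    probe.  areaSES has no exact closed algorithm here; ``ses_backend``
    selects either the documented fallback approximation ``"probe0"``
    (the same point-sampled area on the bare van der Waals envelope,
    probe 0 — an upper-bound proxy of the true solvent-excluded surface),
    a callable ``residues -> {key: area}`` adapter to an external tool,
    or ``None`` to leave areaSES missing.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    coords = np.concatenate([r.coords() for r in residues])
    radii = _atom_radii(residues, radius_overrides)
    atom_res = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(residues)]
    )
    sas_atom = shrake_rupley(coords, radii, probe_radius, n_sphere_points)
    sas = np.bincount(atom_res, weights=sas_atom, minlength=len(residues))

    if ses_backend is None:
        ses = np.full(len(residues), np.nan)
    elif callable(ses_backend):
        by_key = ses_backend(residues)
        ses = np.array([by_key.get(r.key, np.nan) for r in residues])
    elif ses_backend == "probe0":
        ses_atom = shrake_rupley(coords, radii, 0.0, n_sphere_points)
        ses = np.bincount(atom_res, weights=ses_atom, minlength=len(residues))
    else:
        raise ValueError(f"unknown ses_backend {ses_backend!r}")

    return pd.DataFrame(
        {"areaSAS": sas, "areaSES": ses},
        index=pd.Index([r.node_id for r in residues], name="residue"),
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    # atan2 returns (-180, 180]; -180.0 can appear from rounding
    if ang <= -180.0:
        ang += 360.0
    return ang


def compute_torsions(residues: list[Residue]) -> pd.DataFrame:
    """Backbone phi/psi per residue; undefined torsions are NaN, never 0.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1).  Torsions are missing at chain termini, across chain breaks
    (peptide C-N distance > 2.5 A), and wherever a backbone atom is absent
    (logged as a warning, not an exception).
    """
    phi = np.full(len(residues), np.nan)
    psi = np.full(len(residues), np.nan)

    def bonded(prev: Residue, nxt: Residue) -> bool:
        c, n = prev.atom("C"), nxt.atom("N")
        if c is None or n is None:
            return False
        d = np.linalg.norm(np.subtract(c.coord, n.coord))
        return d <= CHAIN_BREAK_CN

    for i, res in enumerate(residues):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if n is None or ca is None or c is None:
            logger.warning("missing backbone atom in %s; torsions undefined",
                           res.node_id)
            continue
        prev = residues[i - 1] if i > 0 and residues[i - 1].chain == res.chain else None
        nxt = (residues[i + 1]
               if i + 1 < len(residues) and residues[i + 1].chain == res.chain
               else None)
        if prev is not None and bonded(prev, res):
            phi[i] = dihedral(prev.atom("C").coord, n.coord, ca.coord, c.coord)
        if nxt is not None and nxt.atom("N") is not None and bonded(res, nxt):
            psi[i] = dihedral(n.coord, ca.coord, c.coord, nxt.atom("N").coord)
    return pd.DataFrame(
        {"PHI": phi, "PSI": psi},
        index=pd.Index([r.node_id for r in residues], name="residue"),
    )


class DuplicateConservationError(ValueError):
    """Two conservation rows map to the same sequence position."""


def load_conservation(
    text: str,
    pos_col: int = 0,
    score_col: int = 2,
    comment: str = "#",
) -> dict[int, float]:
    """Parse a whitespace/tab-delimited per-position conservation file.

    Expects one row per position with at least a position column and a
    score column (lower score = more conserved; the input direction is
    preserved, never re-normalised).  Column indices are configurable to
    absorb dialect differences.
    """
    scores: dict[int, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(comment):
            continue
        parts = line.replace(",", " ").split()
        try:
            pos = int(parts[pos_col])
            score = float(parts[score_col])
        except (ValueError, IndexError):
            continue  # header or malformed line
        if pos in scores:
            raise DuplicateConservationError(f"duplicate conservation position {pos}")
        scores[pos] = score
    return scores


def assemble_residue_features(
    residues: list[Residue],
    surfaces: pd.DataFrame,
    torsions: pd.DataFrame,
    conservation: dict[int, float] | None = None,
    hydropathy: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One feature row per structure residue.

    Joins surfaces and torsions by residue, assigns hydropathy by residue
    type, and joins conservation by sequence position.  Positions present
    in the conservation map but absent from the structure raise a warning
    and are skipped; residues without a conservation entry carry NaN.
    """
    hydropathy = hydropathy or KD_HYDROPATHY
    ids = [r.node_id for r in residues]
    df = pd.DataFrame(
        {
            "chain": [r.chain for r in residues],
            "position": [r.seq_position for r in residues],
            "insertion_code": [r.insertion_code for r in residues],
            "aa": [r.aa for r in residues],
        },
        index=pd.Index(ids, name="residue"),
    )
    df["areaSAS"] = surfaces["areaSAS"].reindex(ids).to_numpy()
    df["areaSES"] = surfaces["areaSES"].reindex(ids).to_numpy()
    df["kdHydrophobicity"] = [hydropathy[r.aa] for r in residues]
    df["PSI"] = torsions["PSI"].reindex(ids).to_numpy()
    df["PHI"] = torsions["PHI"].reindex(ids).to_numpy()
    df["bFactor"] = [r.bfactor for r in residues]
    if conservation is not None:
        present = {r.seq_position for r in residues}
        for pos in conservation:
            if pos not in present:
                warnings.warn(
                    f"conservation position {pos} absent from structure; skipped",
                    stacklevel=2,
                )
        df["conservation"] = [
            conservation.get(r.seq_position, np.nan) for r in residues
        ]
    else:
        df["conservation"] = np.nan
    df = df.sort_values(["chain", "position", "insertion_code"], kind="stable")
    return df
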
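"""Seeded synthetic fixtures: toy structures, property tables, mutations.

Everything the pipeline consumes can be generated here without any
download: an ideal-geometry backbone written as PDB text, a ConSurf-style
conservation file, a random (optionally low-rank) amino-acid property
table, and a labeled mutation table whose severity labels follow a known
logistic-style model in (degree, conservation, substitution distance) —
mirroring the empirical pattern that buried, conserved, highly connected
residues are the ones whose substitution is most damaging.  Generators
are pure functions of (spec, seed): identical inputs give byte-identical
outputs, and the generating coefficients are logged so recovery tests
have a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aadist import AA_ORDER, PropertyTable

__all__ = [
    "SyntheticSpec",
    "make_toy_structure",
    "make_conservation_file",
    "make_toy_property_table",
    "make_synthetic_mutations",
    "make_demo_workspace",
]

# Ideal backbone geometry (lengths in Angstrom, angles in degrees).
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.231
ANGLE_C_N_CA, ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_CA_C_O = 121.7, 111.2, 116.2, 120.8
OMEGA = 180.0

GEOMETRIES = ("ideal_helix", "extended", "random_coil")

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror a small single-domain protein and the class balance
    of curated hemophilia registries (~37% severe among ~440 usable
    reports, i.e. roughly 1 severe : 1.7 mild/moderate).  The label model
    is logistic-style in network degree (positive), conservation score
    (negative: low score = conserved = fragile) and substitution distance
    (positive), with Gaussian noise on the linear predictor.
    """

    n_residues: int = 80
    geometry: str = "ideal_helix"
    sequence: str | None = None
    n_properties: int = 40
    planted_rank: int | None = None
    n_mutations: int = 440
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "degree": 1.0, "conservation": -1.2, "aa_distance": 1.0,
        }
    )
    noise_sd: float = 0.5
    severe_fraction: float = 0.37
    seed: int = 0


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Internal-to-Cartesian (NeRF): position d from three reference atoms."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.cos(tor) * math.sin(ang),
        bond * math.sin(tor) * math.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _phi_psi_for(spec: SyntheticSpec, rng: np.random.Generator):
    if spec.geometry == "ideal_helix":
        return [(-57.0, -47.0)] * spec.n_residues
    if spec.geometry == "extended":
        return [(-180.0, 180.0)] * spec.n_residues
    if spec.geometry == "random_coil":
        out = []
        for _ in range(spec.n_residues):
            if rng.random() < 0.5:  # alpha region
                out.append((rng.normal(-60, 12), rng.normal(-45, 12)))
            else:  # beta region
                out.append((rng.normal(-120, 20), rng.normal(135, 20)))
        return out
    raise ValueError(f"unknown geometry {spec.geometry!r}; "
                     f"choose from {GEOMETRIES}")


def _sequence_for(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    if spec.sequence is not None:
        if len(spec.sequence) != spec.n_residues:
            raise ValueError("sequence length must equal n_residues")
        return spec.sequence
    return "".join(rng.choice(list(AA_ORDER), size=spec.n_residues))


def make_toy_structure(spec: SyntheticSpec) -> str:
    """Ideal-geometry backbone (N, CA, C, O per residue) as PDB text."""
    if spec.n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(spec.seed)
    torsions = _phi_psi_for(spec, rng)
    seq = _sequence_for(spec, rng)

    # first residue laid out in the xy-plane
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, spec.n_residues):
        phi_i, _ = torsions[i]
        _, psi_prev = torsions[i - 1]
        prev = coords[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"],
                        BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = _place_atom(prev["CA"], prev["C"], n,
                         BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(coords):
        _, psi = torsions[i]
        res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                               BOND_C_O, ANGLE_CA_C_O, psi + 180.0)

    bfactors = np.round(rng.uniform(10.0, 50.0, size=spec.n_residues), 2)
    lines = []
    serial = 1
    for i, res in enumerate(coords):
        resname = ONE_TO_THREE[seq[i]]
        for name in ("N", "CA", "C", "O"):
            x, y, z = res[name]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactors[i]:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_conservation_file(spec: SyntheticSpec) -> str:
    """ConSurf-style grades for the toy structure (lower = more conserved)."""
    rng = np.random.default_rng(spec.seed + 1)
    seq = _sequence_for(spec, np.random.default_rng(spec.seed))
    lines = ["# pos aa score"]
    for i in range(spec.n_residues):
        score = rng.normal(0.0, 1.0)
        lines.append(f"{i + 1} {seq[i]} {score:.4f}")
    return "\n".join(lines) + "\n"


def make_toy_property_table(spec: SyntheticSpec) -> PropertyTable:
    """Random 20-row property table, optionally with planted low rank."""
    if spec.n_properties < 1:
        raise ValueError("need at least one property")
    rng = np.random.default_rng(spec.seed + 2)
    if spec.planted_rank is not None:
        r = spec.planted_rank
        scores = rng.normal(size=(20, r))
        loadings = rng.normal(size=(r, spec.n_properties))
        values = scores @ loadings
    else:
        values = rng.normal(size=(20, spec.n_properties))
    df = pd.DataFrame(
        values, index=list(AA_ORDER),
        columns=[f"P{j + 1:03d}" for j in range(spec.n_properties)],
    )
    return PropertyTable(values=df)


def make_synthetic_mutations(
    spec: SyntheticSpec,
    residue_features: pd.DataFrame,
    centralities: pd.DataFrame,
    distance_matrix,
) -> pd.DataFrame:
    """Labeled mutation table drawn from a known generative label model.

    Positions are sampled from feature-complete residues; each draw picks
    a random non-wild-type target amino acid.  The linear predictor is
    the stated coefficients applied to standardised (degree,
    conservation, aa_distance) plus Gaussian noise; the severe class is
    the top ``severe_fraction`` of that predictor, so zero noise makes
    the classes separable in feature space.  The generating coefficients
    and threshold are logged in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(spec.seed + 3)
    feats = residue_features.join(centralities, how="left")
    feats = feats.dropna(subset=["conservation", "degree"])
    if feats.empty:
        raise ValueError("no feature-complete residues to mutate")

    idx = rng.integers(len(feats), size=spec.n_mutations)
    rows = []
    for i in idx:
        feat = feats.iloc[int(i)]
        wt = feat["aa"]
        mut = str(rng.choice([a for a in AA_ORDER if a != wt]))
        rows.append({
            "position": int(feat["position"]), "wt_aa": wt, "mut_aa": mut,
            "degree": float(feat["degree"]),
            "conservation": float(feat["conservation"]),
            "aa_distance": float(distance_matrix[wt, mut]),
        })
    df = pd.DataFrame(rows)

    z = {}
    for col in ("degree", "conservation", "aa_distance"):
        v = df[col].to_numpy(float)
        sd = v.std()
        z[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    eta = sum(spec.coefficients.get(c, 0.0) * z[c] for c in z)
    eta = np.asarray(eta, dtype=float)
    if spec.noise_sd > 0:
        eta = eta + rng.normal(0.0, spec.noise_sd, size=len(df))
    threshold = float(np.quantile(eta, 1.0 - spec.severe_fraction))
    label = (eta > threshold).astype(int)
    if label.sum() < 2 or (1 - label).sum() < 2:
        raise ValueError("severe_fraction leaves fewer than 2 examples in a class")

    activity = np.where(
        label == 1,
        rng.uniform(0.0, 1.0, size=len(df)),
        rng.uniform(1.0, 40.0, size=len(df)),
    )
    df["activity"] = np.round(activity, 2)
    df["severity"] = np.where(
        label == 1, "severe",
        np.where(df["activity"] < 5, "moderate", "mild"),
    )
    df["label"] = label
    df = df.drop(columns=["degree", "conservation"])
    df.attrs["coefficients"] = dict(spec.coefficients)
    df.attrs["noise_sd"] = spec.noise_sd
    df.attrs["threshold"] = threshold
    return df


def make_demo_workspace(spec: SyntheticSpec, out_dir) -> dict[str, str]:
    """Write a complete demo input set; returns the file paths."""
    from pathlib import Path

    from . import pipeline

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_text = make_toy_structure(spec)
    cons_text = make_conservation_file(spec)
    table = make_toy_property_table(spec)

    paths = {
        "structure": str(out / "structure.pdb"),
        "conservation": str(out / "conservation.txt"),
        "properties": str(out / "properties.csv"),
        "mutations": str(out / "mutations.csv"),
    }
    (out / "structure.pdb").write_text(pdb_text)
    (out / "conservation.txt").write_text(cons_text)
    table.values.to_csv(paths["properties"])

    prep = pipeline.prepare_inputs(pdb_text, cons_text, table)
    mutations = make_synthetic_mutations(
        spec, prep.residue_features, prep.centralities, prep.distance_matrix
    )
    mutations.to_csv(paths["mutations"], index=False)
    return paths
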
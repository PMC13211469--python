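"""Quantitative geometry on 3-D protein models.

Operates on :class:`StructureModel` — an ordered atom table parsed from a
PDB file, with per-residue model confidence (pLDDT, 0-100) carried in the
temperature-factor column as AlphaFold-style models do. Provides:

* optimal rigid-body superposition (Kabsch, reflections excluded) and RMSD;
* backbone dihedrals and Ramachandran favored/allowed/outlier summaries;
* solvent-accessible surface area by Shrake-Rupley point sampling with a
  deterministic golden-spiral point set, and helix burial
  (isolated-minus-in-context SASA of a residue span);
* geometric disulfide detection from SG-SG distances;
* hydrophobic moment / helical-wheel geometry for amphipathicity analysis;
* per-chain confidence summaries and a dihedral-bin secondary-structure
  fraction (a coarse surrogate for predictor-based assignments).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: van der Waals radii (Angstrom) used for SASA
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}

#: Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: five-class residue coloring used on helical wheels
RESIDUE_CLASSES = {
    **{r: "hydrophobic" for r in "AVLIMPGC"},
    **{r: "positive" for r in "KRH"},
    **{r: "negative" for r in "DE"},
    **{r: "polar" for r in "STNQ"},
    **{r: "aromatic" for r in "FWY"},
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ATOM_COLUMNS = [
    "chain", "resnum", "icode", "resname", "atname",
    "element", "x", "y", "z", "confidence", "is_hydrogen",
]

_CHAIN_BREAK_CN = 2.5  # Angstrom; larger C-N distances are chain breaks


class PDBParseError(ValueError):
    pass


@dataclass
class StructureModel:
    """Ordered atom table for one model of one structure file."""

    atoms: pd.DataFrame
    model_index: int = 1

    def __post_init__(self):
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.isfinite(xyz).all():
            raise ValueError("non-finite coordinates in atom table")
        self.atoms = self.atoms.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def heavy(self) -> "StructureModel":
        return StructureModel(
            self.atoms[~self.atoms.is_hydrogen].copy(), self.model_index
        )

    def chain(self, chain_id: str) -> "StructureModel":
        return StructureModel(
            self.atoms[self.atoms.chain == chain_id].copy(), self.model_index
        )

    def residue_span(self, start: int, end: int, chain: str | None = None
                     ) -> "StructureModel":
        """Atoms of residues ``start``..``end`` inclusive (optionally one chain)."""
        mask = (self.atoms.resnum >= start) & (self.atoms.resnum <= end)
        if chain is not None:
            mask &= self.atoms.chain == chain
        return StructureModel(self.atoms[mask].copy(), self.model_index)

    def span_mask(self, start: int, end: int, chain: str | None = None) -> np.ndarray:
        mask = (self.atoms.resnum >= start) & (self.atoms.resnum <= end)
        if chain is not None:
            mask &= self.atoms.chain == chain
        return mask.to_numpy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        out = self.atoms.copy()
        xyz = out[["x", "y", "z"]].to_numpy(float) @ rotation.T + translation
        out[["x", "y", "z"]] = xyz
        return StructureModel(out, self.model_index)

    def write_pdb(self, dest: str | Path) -> None:
        """Write the atom table in fixed-column PDB format."""
        lines = []
        for i, row in enumerate(self.atoms.itertuples(), start=1):
            name = row.atname if len(row.atname) == 4 else f" {row.atname:<3}"
            lines.append(
                f"ATOM  {i % 100000:5d} {name}{'':1}{row.resname:>3} "
                f"{row.chain[:1]}{int(row.resnum) % 10000:4d}{row.icode or '':1}   "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{1.0:6.2f}"
                f"{row.confidence:6.2f}          {row.element:>2}"
            )
        lines.append("END")
        Path(dest).write_text("\n".join(lines) + "\n")


def read_pdb_model(
    path: str | Path,
    model_index: int = 1,
    altloc_policy: str = "first",
    skip_waters: bool = True,
) -> StructureModel:
    """Parse one model from a PDB file into a :class:`StructureModel`.

    Per-residue confidence is read from the temperature-factor column.
    Hydrogens are retained but flagged; waters are skipped by default; under
    the default altloc policy only the first alternate location of each atom
    is kept.
    """
    import gemmi

    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if model_index < 1 or model_index > len(structure):
        raise PDBParseError(
            f"{path}: model {model_index} not present ({len(structure)} models)"
        )
    model = structure[model_index - 1]
    rows = []
    for chain in model:
        for residue in chain:
            if skip_waters and residue.name in ("HOH", "WAT"):
                continue
            seen: set[str] = set()
            for atom in residue:
                if altloc_policy == "first":
                    if atom.name in seen:
                        continue
                    seen.add(atom.name)
                element = atom.element.name.upper()
                rows.append(
                    (
                        chain.name, residue.seqid.num, residue.seqid.icode.strip(),
                        residue.name, atom.name, element,
                        atom.pos.x, atom.pos.y, atom.pos.z,
                        atom.b_iso, element == "H",
                    )
                )
    if not rows:
        raise PDBParseError(f"{path}: no ATOM records found")
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return StructureModel(atoms, model_index=model_index)


# ---------------------------------------------------------------------------
# superposition


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of two paired point sets.

    Returns the proper rotation (reflections excluded by determinant
    correction) and translation mapping ``mobile`` onto ``reference``, with
    the minimal RMSD over all rigid motions.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 atom pairs are required")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = rc - rotation @ mc
    moved = (mobile @ rotation.T) + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_atoms=n)


def superpose_ca(mobile: StructureModel, reference: StructureModel
                 ) -> SuperpositionResult:
    """Superpose two models on their shared count of CA atoms, in order."""
    ma = mobile.atoms[mobile.atoms.atname == "CA"]
    ra = reference.atoms[reference.atoms.atname == "CA"]
    n = min(len(ma), len(ra))
    if len(ma) != len(ra):
        logger.warning("CA counts differ (%d vs %d); using first %d", len(ma), len(ra), n)
    return kabsch_superpose(
        ma[["x", "y", "z"]].to_numpy(float)[:n],
        ra[["x", "y", "z"]].to_numpy(float)[:n],
    )


# ---------------------------------------------------------------------------
# dihedrals and Ramachandran analysis


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
              ) -> float:
    """Signed torsion angle in degrees, IUPAC convention, in (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 else angle


def backbone_dihedrals(model: StructureModel, chain: str | None = None
                       ) -> pd.DataFrame:
    """Per-residue (phi, psi) in degrees for one chain.

    phi is undefined for the first residue and psi for the last; a C(i)-N(i+1)
    distance above 2.5 Angstrom is treated as a chain break, leaving the
    angles across it undefined. Residues missing a backbone atom get NaN for
    every dependent angle, with a logged warning.
    """
    atoms = model.atoms
    if chain is None:
        chains = atoms.chain.unique()
        if len(chains) != 1:
            raise ValueError(f"model has chains {list(chains)}; specify one")
        chain = chains[0]
    sub = atoms[atoms.chain == chain]
    residues = []
    for (resnum, icode), group in sub.groupby(["resnum", "icode"], sort=False):
        pos = {}
        for name in ("N", "CA", "C"):
            sel = group[group.atname == name]
            if len(sel):
                pos[name] = sel.iloc[0][["x", "y", "z"]].to_numpy(float)
        resname = group.iloc[0]["resname"]
        if len(pos) < 3:
            logger.warning("chain %s residue %s%s: missing backbone atom",
                           chain, resnum, icode)
        residues.append((resnum, icode, resname, pos))

    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def linked(i: int) -> bool:
        """C(i)-N(i+1) present and within the chain-break cutoff."""
        pos_i, pos_j = residues[i][3], residues[i + 1][3]
        if "C" not in pos_i or "N" not in pos_j:
            return False
        return float(np.linalg.norm(pos_j["N"] - pos_i["C"])) <= _CHAIN_BREAK_CN

    for i in range(n):
        pos = residues[i][3]
        if len(pos) < 3:
            continue
        if i > 0 and linked(i - 1) and "C" in residues[i - 1][3]:
            phi[i] = _dihedral(residues[i - 1][3]["C"], pos["N"], pos["CA"], pos["C"])
        if i < n - 1 and linked(i) and "N" in residues[i + 1][3]:
            psi[i] = _dihedral(pos["N"], pos["CA"], pos["C"], residues[i + 1][3]["N"])

    return pd.DataFrame(
        {
            "chain": chain,
            "resnum": [r[0] for r in residues],
            "icode": [r[1] for r in residues],
            "resname": [r[2] for r in residues],
            "phi": phi,
            "psi": psi,
        }
    )


def load_rama_map() -> dict:
    """The shipped coarse rectangular Ramachandran region map."""
    return json.loads(
        resources.files("killerkit.data").joinpath("rama_map.json").read_text()
    )


def _in_rects(phi: float, psi: float, rects: list[list[float]]) -> bool:
    return any(
        lo_f <= phi <= hi_f and lo_s <= psi <= hi_s
        for lo_f, hi_f, lo_s, hi_s in rects
    )


def _submap_for(resname: str, next_resname: str | None) -> str:
    if resname == "GLY":
        return "glycine"
    if resname == "PRO":
        return "proline"
    if next_resname == "PRO":
        return "preproline"
    return "general"


@dataclass
class RamachandranSummary:
    dihedrals: pd.DataFrame  # with an added 'rama_class' column
    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def ramachandran_summary(dihedrals: pd.DataFrame,
                         region_map: dict | None = None) -> RamachandranSummary:
    """Classify residues with both angles defined as favored/allowed/outlier."""
    region_map = region_map or load_rama_map()
    classes = []
    resnames = dihedrals["resname"].tolist()
    for i, row in enumerate(dihedrals.itertuples()):
        if np.isnan(row.phi) or np.isnan(row.psi):
            classes.append(None)
            continue
        nxt = resnames[i + 1] if i + 1 < len(resnames) else None
        sub = region_map[_submap_for(row.resname, nxt)]
        if _in_rects(row.phi, row.psi, sub["favored"]):
            classes.append("favored")
        elif _in_rects(row.phi, row.psi, sub["allowed"]):
            classes.append("allowed")
        else:
            classes.append("outlier")
    out = dihedrals.copy()
    out["rama_class"] = classes
    counts = {k: classes.count(k) for k in ("favored", "allowed", "outlier")}
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return RamachandranSummary(dihedrals=out, counts=counts, fractions=fractions)


#: coarse dihedral bins for the secondary-structure fraction surrogate
DEFAULT_SS_BINS = {
    "helix": [[-100, -30, -80, -5]],
    "strand": [[-180, -45, 90, 180], [-180, -45, -180, -150]],
}


def ss_fraction(dihedrals: pd.DataFrame,
                bin_map: dict | None = None) -> dict[str, float]:
    """Helix/strand/other fractions from backbone dihedral bins.

    A coarse surrogate for predictor-based secondary-structure assignment:
    each residue with both angles defined falls in exactly one class.
    Returns all-zero fractions (with a warning) when no residue qualifies.
    """
    bin_map = bin_map or DEFAULT_SS_BINS
    counts = {"helix": 0, "strand": 0, "other": 0}
    for row in dihedrals.itertuples():
        if np.isnan(row.phi) or np.isnan(row.psi):
            continue
        if _in_rects(row.phi, row.psi, bin_map["helix"]):
            counts["helix"] += 1
        elif _in_rects(row.phi, row.psi, bin_map["strand"]):
            counts["strand"] += 1
        else:
            counts["other"] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no residues with both dihedral angles defined", stacklevel=2)
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Angstrom^2, aligned with the model's atom table
    per_residue: pd.DataFrame  # chain, resnum, sasa
    total: float
    probe: float
    n_points: int


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    points: int = 960,
    radii: dict[str, float] | None = None,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA with a deterministic golden-spiral point set.

    Each atom's accessible area is the fraction of its probe-inflated sphere
    points not covered by any neighbour, times 4 pi (r + probe)^2. Hydrogens
    are excluded by default.
    """
    radii = radii or DEFAULT_RADII
    work = model if include_hydrogens else model.heavy()
    atoms = work.atoms
    if len(atoms) == 0:
        raise ValueError("no atoms to compute SASA on")
    unknown = sorted(set(atoms.element) - set(radii))
    if unknown:
        raise ValueError(f"no radius for element(s): {unknown}")
    xyz = work.coords()
    r = atoms.element.map(radii).to_numpy(float) + probe
    sphere = golden_spiral_points(points)

    tree = cKDTree(xyz)
    max_r = float(r.max())
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + r[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], r[i] + max_r)
                      if j != i]
        if neighbours:
            nb_xyz = xyz[neighbours]
            nb_r = r[neighbours]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            exposed = (d2 >= (nb_r**2)[None, :]).all(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * math.pi * r[i] ** 2

    table = atoms[["chain", "resnum"]].copy()
    table["sasa"] = per_atom
    per_residue = table.groupby(["chain", "resnum"], as_index=False).sasa.sum()
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe=probe,
        n_points=points,
    )


@dataclass
class HelixBurialResult:
    span: tuple[int, int]
    isolated_sasa: float  # Angstrom^2, span atoms alone
    context_sasa: float  # same atoms within the full model
    buried_area: float
    percent_buried: float


def helix_burial(
    model: StructureModel,
    span: tuple[int, int],
    chain: str | None = None,
    probe: float = 1.4,
    points: int = 960,
    radii: dict[str, float] | None = None,
) -> HelixBurialResult:
    """Buried surface of a residue span: isolated minus in-context SASA.

    The area a span (typically the central alpha-helix of the toxin's alpha
    domain) loses to the rest of the structure, in squared Angstrom and as a
    percentage of its isolated surface.
    """
    start, end = span
    span_model = model.residue_span(start, end, chain)
    if len(span_model) == 0:
        raise ValueError(f"span {start}-{end} selects no atoms")
    isolated = shrake_rupley_sasa(span_model, probe, points, radii)
    if isolated.total <= 0:
        raise ValueError("isolated SASA of the span is zero (degenerate span)")
    full = shrake_rupley_sasa(model, probe, points, radii)
    mask = model.heavy().span_mask(start, end, chain)
    context = float(full.per_atom[mask].sum())
    buried = isolated.total - context
    return HelixBurialResult(
        span=span,
        isolated_sasa=isolated.total,
        context_sasa=context,
        buried_area=buried,
        percent_buried=100.0 * buried / isolated.total,
    )


# ---------------------------------------------------------------------------
# disulfides


@dataclass
class DisulfideBond:
    residue_a: tuple[str, int]  # (chain, resnum)
    residue_b: tuple[str, int]
    distance: float
    kind: str  # bonded | near


def detect_disulfides(
    model: StructureModel,
    bonded_cutoff: float = 2.5,
    near_cutoff: float = 3.0,
) -> list[DisulfideBond]:
    """Geometric disulfide detection from cysteine SG-SG distances.

    Greedy nearest-pair matching: each SG joins at most one pair; pairs
    within ``bonded_cutoff`` are bonded, within ``near_cutoff`` "near"
    (predicted models often leave real pairs slightly long). Sorted by
    distance.
    """
    sg = model.atoms[(model.atoms.resname == "CYS") & (model.atoms.atname == "SG")]
    if len(sg) < 2:
        return []
    xyz = sg[["x", "y", "z"]].to_numpy(float)
    ids = list(zip(sg.chain.tolist(), sg.resnum.tolist()))
    pairs = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d <= near_cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    bonds: list[DisulfideBond] = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(
            DisulfideBond(
                residue_a=ids[i], residue_b=ids[j], distance=d,
                kind="bonded" if d <= bonded_cutoff else "near",
            )
        )
    return bonds


# ---------------------------------------------------------------------------
# amphipathicity


@dataclass
class HelixGeometry:
    sequence: str
    delta: float  # degrees per residue
    wheel_angles: list[float]  # degrees, modulo 360
    mean_hydrophobicity: float
    hydrophobic_moment: float
    residue_classes: list[str]


def hydrophobic_moment(
    sequence_window: str,
    scale: dict[str, float] | None = None,
    delta: float = 100.0,
) -> HelixGeometry:
    """Eisenberg hydrophobic moment of a helical window.

    Residue n sits at angle n*delta on the helical wheel (100 degrees per
    residue for an ideal alpha-helix); the moment is the magnitude of the
    vector sum of hydrophobicities at those angles. High moment with
    moderate mean hydrophobicity marks an amphipathic helix.
    """
    scale = scale or EISENBERG
    seq = sequence_window.upper()
    if not seq:
        raise ValueError("empty sequence window")
    missing = sorted(set(seq) - set(scale))
    if missing:
        raise ValueError(f"residue(s) absent from scale: {missing}")
    h = np.array([scale[c] for c in seq])
    n = np.arange(len(seq))
    angles = np.deg2rad(n * delta)
    mu = math.hypot(float((h * np.cos(angles)).sum()),
                    float((h * np.sin(angles)).sum()))
    return HelixGeometry(
        sequence=seq,
        delta=delta,
        wheel_angles=[(i * delta) % 360.0 for i in n],
        mean_hydrophobicity=float(h.mean()),
        hydrophobic_moment=mu,
        residue_classes=[RESIDUE_CLASSES[c] for c in seq],
    )


# ---------------------------------------------------------------------------
# confidence


@dataclass
class ConfidenceSummary:
    per_chain: pd.DataFrame  # chain, n_residues, mean, min, max
    mean: float
    min: float
    max: float


def confidence_summary(model: StructureModel) -> ConfidenceSummary:
    """Per-chain mean/min/max of the per-residue confidence (CA atoms)."""
    ca = model.atoms[model.atoms.atname == "CA"]
    if len(ca) == 0:
        raise ValueError("no CA atoms; cannot summarize per-residue confidence")
    grouped = ca.groupby("chain").confidence.agg(["count", "mean", "min", "max"])
    per_chain = grouped.reset_index().rename(columns={"count": "n_residues"})
    return ConfidenceSummary(
        per_chain=per_chain,
        mean=float(ca.confidence.mean()),
        min=float(ca.confidence.min()),
        max=float(ca.confidence.max()),
    )
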
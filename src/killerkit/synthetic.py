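"""Deterministic synthetic-data generators with exact ground truth.

Every generator is a pure function of its spec (same spec, same seed ->
byte-identical output) and returns, alongside the data, the ground truth it
planted. The round-trip suite checks that each pipeline stage recovers that
truth exactly:

* :func:`gen_preprotoxin` — preprotoxins with a planted signal region
  (positively charged n-region, hydrophobic h-region, small-residue
  cleavage context), dibasic Kex2 motifs at chosen domain boundaries, and
  chosen cysteine positions. Filler residues never include K, R or C, so
  the planted motifs and cysteines are the only ones present.
* :func:`gen_ideal_backbone` — N/CA/C backbones built by internal
  coordinates (NeRF chaining) at chosen (phi, psi), the analytic oracle for
  dihedral recovery and secondary-structure binning.
* sphere scenes — single atoms, atom pairs and an occluding shell around a
  small cluster, with closed-form or by-construction SASA expectations.
* :func:`gen_hit_tables` — homolog hit tables with a planted family
  partition, out-of-range hit lengths and a planted taxon split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_core import ProteinRecord
from .set_analytics import HitTable
from .struct_metrics import ATOM_COLUMNS, StructureModel, golden_spiral_points

# filler alphabet: no K/R (no accidental Kex motifs), no C (no accidental
# cysteines), no strongly hydrophobic letters (no accidental h-regions:
# every Kyte-Doolittle value here is negative)
FILLER_RESIDUES = "DEGHNPQSTWY"
HYDROPHOBIC_RESIDUES = "LIVF"


class InfeasibleSpec(ValueError):
    """The requested planted features cannot coexist."""


@dataclass(frozen=True)
class PreprotoxinSpec:
    seed: int = 0
    length: int = 316
    n_positives: int = 2  # K residues right after the initial M
    h_start: int = 6  # first residue of the hydrophobic h-region
    h_len: int = 12
    boundaries: tuple[int, ...] = (44, 149, 233)  # Kex2 P1 positions
    domain_names: tuple[str, ...] = ("delta", "alpha", "gamma", "beta")
    cysteines: tuple[int, ...] = (95, 107, 239, 312)
    name: str = "synthetic_pptox"


@dataclass
class PreprotoxinTruth:
    h_span: tuple[int, int]
    signal_cleavage: int  # P1 of the planted signal-peptidase site
    sites: list[tuple[int, str]]  # (P1 position, motif)
    domains: list[tuple[str, int, int]]
    cysteines: tuple[int, ...]


def gen_preprotoxin(spec: PreprotoxinSpec) -> tuple[ProteinRecord, PreprotoxinTruth]:
    """Generate a preprotoxin with planted maturation features.

    Layout: M + K...K n-region, filler, hydrophobic h-region, an A-S-A
    signal-peptidase context (cleavage after the final A), then filler with
    dibasic KR/RR motifs planted so each boundary P1 falls on the motif's
    second residue, and cysteines at the requested positions.
    """
    rng = np.random.default_rng(spec.seed)
    h_end = spec.h_start + spec.h_len - 1
    signal_cleavage = h_end + 3  # ...h-region | A S A | core

    if spec.h_start < 2 + spec.n_positives:
        raise InfeasibleSpec("h-region overlaps the n-region")
    if spec.boundaries != tuple(sorted(set(spec.boundaries))):
        raise InfeasibleSpec("boundaries must be strictly ascending")
    if len(spec.domain_names) != len(spec.boundaries) + 1:
        raise InfeasibleSpec("need exactly one more domain name than boundaries")
    if spec.boundaries and spec.boundaries[0] <= signal_cleavage + 1:
        raise InfeasibleSpec("first boundary collides with the signal region")
    if spec.boundaries and spec.boundaries[-1] >= spec.length:
        raise InfeasibleSpec("boundary at or beyond sequence end")
    for a, b in zip(spec.boundaries, spec.boundaries[1:]):
        if b - a < 3:
            raise InfeasibleSpec("boundaries too dense: planted motifs would merge")

    motif_positions = set()
    for p1 in spec.boundaries:
        motif_positions.update((p1 - 1, p1))
    reserved = motif_positions | set(range(1, signal_cleavage + 1))
    for c in spec.cysteines:
        if c in reserved or c > spec.length:
            raise InfeasibleSpec(f"cysteine position {c} collides with another feature")

    seq = [""] * (spec.length + 1)  # 1-based
    seq[1] = "M"
    for i in range(2, 2 + spec.n_positives):
        seq[i] = "K"
    for i in range(2 + spec.n_positives, spec.h_start):
        seq[i] = str(rng.choice(list(FILLER_RESIDUES)))
    # the h-region is a homogeneous run of one hydrophobic letter: every
    # subwindow then has the same mean hydropathy, so the detection heuristic
    # (max mean, ties to longest) recovers the planted span exactly
    h_letter = str(rng.choice(list(HYDROPHOBIC_RESIDUES)))
    for i in range(spec.h_start, h_end + 1):
        seq[i] = h_letter
    seq[h_end + 1], seq[h_end + 2], seq[h_end + 3] = "A", "S", "A"
    sites = []
    for p1 in spec.boundaries:
        motif = str(rng.choice(["KR", "RR"]))
        seq[p1 - 1], seq[p1] = motif[0], motif[1]
        sites.append((p1, motif))
    for i in range(signal_cleavage + 1, spec.length + 1):
        if not seq[i]:
            seq[i] = str(rng.choice(list(FILLER_RESIDUES)))
    for c in spec.cysteines:
        seq[c] = "C"

    sequence = "".join(seq[1:])
    bounds = [signal_cleavage] + list(spec.boundaries) + [spec.length]
    domains = [
        (name, bounds[i] + 1, bounds[i + 1])
        for i, name in enumerate(spec.domain_names)
    ]
    record = ProteinRecord(
        id=spec.name, description=f"synthetic preprotoxin seed={spec.seed}",
        sequence=sequence,
    )
    truth = PreprotoxinTruth(
        h_span=(spec.h_start, h_end),
        signal_cleavage=signal_cleavage,
        sites=sites,
        domains=domains,
        cysteines=spec.cysteines,
    )
    return record, truth


# ---------------------------------------------------------------------------
# ideal backbones (internal-coordinate / NeRF construction)

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position d given the a-b-c frame, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # sign of the n-component chosen so that dihedral(a, b, c, d) == torsion
    # under the IUPAC convention used by backbone_dihedrals
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            -bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_ideal_backbone(
    n_residues: int,
    phi: float,
    psi: float,
    chain: str = "A",
    resname: str = "ALA",
    confidence: float = 100.0,
) -> StructureModel:
    """Build an N/CA/C backbone at fixed (phi, psi) by internal coordinates.

    Standard bond lengths (N-CA 1.458, CA-C 1.525, C-N 1.329 Angstrom),
    standard angles, omega fixed at 180 degrees. Recomputing the dihedrals
    of the built chain returns the inputs to numerical precision, making the
    construction its own oracle.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    coords: list[tuple[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.extend([("N", n0), ("CA", ca0), ("C", c0)])
    prev_n, prev_ca, prev_c = n0, ca0, c0
    for _ in range(1, n_residues):
        n_i = _place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place_atom(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.extend([("N", n_i), ("CA", ca_i), ("C", c_i)])
        prev_n, prev_ca, prev_c = n_i, ca_i, c_i
    rows = []
    for idx, (atname, xyz) in enumerate(coords):
        resnum = idx // 3 + 1
        rows.append(
            (chain, resnum, "", resname, atname, atname[0], *map(float, xyz),
             confidence, False)
        )
    return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))


# ---------------------------------------------------------------------------
# sphere scenes for SASA oracles


def _atom_rows(points: np.ndarray, chain: str, element: str = "C",
               start_resnum: int = 1, confidence: float = 100.0) -> list[tuple]:
    rows = []
    for i, (x, y, z) in enumerate(points):
        rows.append(
            (chain, start_resnum + i, "", "SPH", element, element,
             float(x), float(y), float(z), confidence, False)
        )
    return rows


def gen_single_atom(element: str = "C") -> StructureModel:
    """One isolated atom: SASA must equal 4*pi*(r+probe)^2 analytically."""
    rows = _atom_rows(np.zeros((1, 3)), chain="A", element=element)
    return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))


def gen_atom_pair(separation: float, element: str = "C") -> StructureModel:
    """Two atoms on the z-axis at the given separation (Angstrom)."""
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(separation)]])
    rows = _atom_rows(pts, chain="A", element=element)
    return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))


def two_sphere_sasa_analytic(separation: float, radius: float = 1.70,
                             probe: float = 1.4) -> float:
    """Closed-form SASA of two equal overlapping spheres.

    Each inflated sphere (R = radius + probe) loses a cap of height
    h = R - d/2 to the other; total = 2 * (4 pi R^2 - 2 pi R h).
    """
    big_r = radius + probe
    if separation >= 2 * big_r:
        return 2 * 4 * math.pi * big_r**2
    h = big_r - separation / 2.0
    return 2 * (4 * math.pi * big_r**2 - 2 * math.pi * big_r * h)


def gen_occlusion_scene(
    n_inner: int = 5,
    inner_spacing: float = 1.5,
    shell_radius: float = 6.0,
    shell_spacing: float = 1.0,
) -> StructureModel:
    """A small inner cluster (chain A) enclosed by a dense spherical shell
    of atoms (chain B).

    With the default geometry every probe-inflated inner sphere lies within
    reach of shell atoms in all directions, so the burial of chain A is
    near-total by construction (>= 95%).
    """
    z = (np.arange(n_inner) - (n_inner - 1) / 2.0) * inner_spacing
    inner = np.column_stack([np.zeros(n_inner), np.zeros(n_inner), z])
    n_shell = int(math.ceil(4 * math.pi * shell_radius**2 / shell_spacing**2))
    shell = shell_radius * golden_spiral_points(n_shell)
    rows = _atom_rows(inner, chain="A") + _atom_rows(shell, chain="B",
                                                     start_resnum=n_inner + 1)
    return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))


# ---------------------------------------------------------------------------
# hit tables


@dataclass(frozen=True)
class HitTableSpec:
    seed: int = 0
    #: family -> member query ids
    families: tuple[tuple[str, ...], ...] = (("K1", "K1L"), ("K2", "K21", "KHS"), ("K45",))
    shared_core: int = 30  # hit ids shared by every member of a family
    unique_per_query: int = 20  # hit ids private to each query
    query_len: int = 320
    out_of_range_per_query: int = 0  # planted length-filter casualties
    #: taxon group -> fraction of hits (applied per query, rounded)
    taxon_fractions: tuple[tuple[str, float], ...] = (
        ("Fungi; Ascomycota; Saccharomycotina", 0.96),
        ("Bacteria; Pseudomonadota", 0.02),
        ("Eukaryota; Viridiplantae", 0.02),
    )


@dataclass
class HitTableTruth:
    families: list[list[str]]
    kept_per_query: dict[str, int]
    removed_per_query: dict[str, int]
    percent_shared_per_family: dict[int, float]


def gen_hit_tables(spec: HitTableSpec) -> tuple[list[HitTable], HitTableTruth]:
    """Hit tables with a planted family structure.

    Members of a family share ``shared_core`` hit ids and carry
    ``unique_per_query`` private ids each, so families are exactly the
    connected components of nonzero overlap. ``out_of_range_per_query``
    extra hits per query get lengths strictly outside the 75%-150% band.
    """
    for _, frac in spec.taxon_fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("taxon fractions must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    tables: list[HitTable] = []
    kept: dict[str, int] = {}
    removed: dict[str, int] = {}
    pct_shared: dict[int, float] = {}

    for f_idx, members in enumerate(spec.families):
        core_ids = [f"fam{f_idx}_core{i}" for i in range(spec.shared_core)]
        for query in members:
            unique_ids = [f"{query}_uniq{i}" for i in range(spec.unique_per_query)]
            ids = core_ids + unique_ids
            lengths = rng.integers(
                int(0.75 * spec.query_len), int(1.5 * spec.query_len) + 1, len(ids)
            ).tolist()
            bad_ids = [f"{query}_bad{i}" for i in range(spec.out_of_range_per_query)]
            bad_lengths = [
                int(spec.query_len * (0.5 if i % 2 == 0 else 2.0))
                for i in range(spec.out_of_range_per_query)
            ]
            all_ids = ids + bad_ids
            all_lengths = lengths + bad_lengths
            taxa = _assign_taxa(len(all_ids), spec.taxon_fractions, rng)
            hits = pd.DataFrame(
                {"hit_id": all_ids, "hit_len": all_lengths, "taxon": taxa}
            )
            tables.append(HitTable(query, spec.query_len, hits))
            kept[query] = len(ids)
            removed[query] = len(bad_ids)
        # planted in-band union/intersection (out-of-range hits removed first)
        union = spec.shared_core + len(members) * spec.unique_per_query
        pct_shared[f_idx] = 100.0 * spec.shared_core / union
    truth = HitTableTruth(
        families=[sorted(m) for m in spec.families],
        kept_per_query=kept,
        removed_per_query=removed,
        percent_shared_per_family=pct_shared,
    )
    return tables, truth


def _assign_taxa(n: int, fractions: tuple[tuple[str, float], ...],
                 rng: np.random.Generator) -> list[str]:
    counts = [int(round(frac * n)) for _, frac in fractions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    labels = []
    for (lineage, _), count in zip(fractions, counts):
        labels.extend([lineage] * count)
    labels.extend(["unclassified"] * (n - len(labels)))
    perm = rng.permutation(n)
    return [labels[i] for i in perm]
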
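"""Preprotoxin maturation annotation.

Secreted killer toxins of *Saccharomyces* yeasts are translated as
preprotoxins (ppTox): an N-terminal signal region followed by up to four
domains (canonically delta-alpha-gamma-beta) delimited by proteolytic
processing sites. Signal peptidase removes the signal region in the ER;
the Golgi endopeptidase Kex2 cleaves after basic residues (usually dibasic
KR/RR motifs) at the domain boundaries; Kex1 carboxypeptidase trims
C-terminal basic residues. The mature secreted toxin is typically the
alpha/beta chain pair, sometimes disulfide-linked.

Conventions: all coordinates are 1-based inclusive; a cleavage site is
reported by the index of its P1 residue, i.e. cleavage occurs AFTER that
residue ("cleaved after R44" -> position 44).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .seq_core import ProteinRecord, default_mass_table, molecular_mass

BASIC_RESIDUES = frozenset("KR")

#: Kyte-Doolittle hydropathy values, used by the signal-region heuristic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: small residues accepted at the -1/-3 positions of a signal peptidase site
SMALL_RESIDUES = frozenset("AGSC")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class CleavageSite:
    """A proteolytic site: ``position`` is the 1-based P1 residue index."""

    position: int
    kind: str  # signal | kex2_dibasic | kex2_monobasic | kex1_trim
    motif: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("P1 position must be >= 1")


@dataclass(frozen=True)
class DomainSegment:
    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment {self.name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class DomainPartition:
    """Ordered, non-overlapping named segments of a preprotoxin."""

    segments: list[DomainSegment]

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names in partition")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"segments {a.name} and {b.name} overlap or are out of order"
                )

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, name: str) -> DomainSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.segments]


@dataclass
class MatureChain:
    name: str
    start: int
    end: int
    mass: float  # Da


@dataclass
class MatureProduct:
    """Chains retained in the secreted toxin and their masses (Da)."""

    chains: list[MatureChain]
    interchain_disulfides: int
    total_mass: float

    def total_kda(self, ndigits: int = 1) -> float:
        return round(self.total_mass / 1000.0, ndigits)


@dataclass(frozen=True)
class MotifPolicy:
    """Which Kex cleavage motifs are scanned for.

    The default dibasic set is {KR, RR}; KK/RK and monobasic-R candidates
    are opt-in because they are less common (though experimentally confirmed
    at some boundaries).
    """

    dibasic: frozenset[str] = frozenset({"KR", "RR"})
    include_monobasic: bool = False

    def __post_init__(self):
        for motif in self.dibasic:
            if len(motif) != 2 or motif[1] not in BASIC_RESIDUES:
                raise ValueError(f"dibasic motif {motif!r} must end in a basic residue")


DEFAULT_POLICY = MotifPolicy()
EXTENDED_POLICY = MotifPolicy(
    dibasic=frozenset({"KR", "RR", "KK", "RK"}), include_monobasic=True
)


@dataclass(frozen=True)
class SignalHeuristicParams:
    """Tunables of the in-house signal-region heuristic.

    An h-region is a hydrophobic window of at least ``h_min_len`` residues
    with mean Kyte-Doolittle hydropathy >= ``h_threshold``, allowed to start
    anywhere in the first ``h_search_limit`` residues (some toxins carry
    ~30 extra residues before the hydrophobic stretch, so the h-region is
    deliberately not anchored at the N-terminus). Cleavage candidates are
    scored by small residues (A/G/S/C) at the -1 and -3 positions within
    ``cleavage_window`` residues downstream of the h-region.
    """

    h_min_len: int = 8
    h_threshold: float = 1.6
    h_search_limit: int = 60
    cleavage_window: int = 15


@dataclass
class SignalCandidate:
    h_start: int
    h_end: int
    mean_hydropathy: float
    n_region_positives: int
    cleavage_candidates: list[tuple[int, int]]  # (P1 position, small-residue score)
    score: float

    @property
    def h_span(self) -> tuple[int, int]:
        return (self.h_start, self.h_end)

    @property
    def best_cleavage(self) -> int | None:
        return self.cleavage_candidates[0][0] if self.cleavage_candidates else None


@dataclass
class ToxinConfig:
    """Curated maturation annotation for one toxin (shipped package data)."""

    name: str
    domain_order: list[str]
    domains: list[DomainSegment]
    signal_cleavage: int | None
    kex2_sites: list[int]
    kex1_trim: dict[str, int] | None
    mature_chains: list[DomainSegment]
    disulfide_pairs: list[tuple[int, int]]
    interchain_disulfides: int
    length: int | None = None
    notes: str = ""

    def partition(self) -> DomainPartition:
        return DomainPartition(list(self.domains))


@dataclass
class BoundaryCheck:
    domain: str
    boundary: int
    supported: bool
    matched_site: CleavageSite | None


@dataclass
class ValidationReport:
    """Findings from checking curated boundaries against a real sequence.

    Mismatches are reported, never raised: a curated boundary without a
    scanned motif nearby is a finding about the annotation, not an error.
    """

    toxin: str
    record_id: str
    boundary_checks: list[BoundaryCheck]
    cysteine_findings: list[str]

    @property
    def all_supported(self) -> bool:
        return all(c.supported for c in self.boundary_checks)


# ---------------------------------------------------------------------------
# operations


def scan_cleavage_motifs(
    record: ProteinRecord, policy: MotifPolicy = DEFAULT_POLICY
) -> list[CleavageSite]:
    """Scan every 2-residue window for Kex2 motifs.

    Every occurrence is reported (overlapping motifs included), sorted by
    position. The final residue is never reported as a P1 site: cleavage
    after it would release nothing.
    """
    seq = record.sequence
    if not seq:
        raise ValueError("empty sequence")
    sites: list[CleavageSite] = []
    for p1 in range(2, len(seq)):  # 1-based P1 in [2, len-1]
        window = seq[p1 - 2 : p1]
        if window in policy.dibasic:
            sites.append(CleavageSite(position=p1, kind="kex2_dibasic", motif=window))
    if policy.include_monobasic:
        dibasic_positions = {s.position for s in sites}
        for p1 in range(1, len(seq)):
            if seq[p1 - 1] == "R" and p1 not in dibasic_positions:
                motif = seq[max(0, p1 - 4) : p1]
                sites.append(
                    CleavageSite(position=p1, kind="kex2_monobasic", motif=motif)
                )
    sites.sort(key=lambda s: (s.position, s.kind))
    return sites


def detect_signal_candidates(
    record: ProteinRecord,
    params: SignalHeuristicParams = SignalHeuristicParams(),
) -> list[SignalCandidate]:
    """Rank candidate signal regions by a hydropathy/charge heuristic.

    Returns candidates sorted by descending score; an empty list is a legal
    outcome (no hydrophobic window passes the threshold). This is a ranked
    heuristic, never a hard call.
    """
    seq = record.sequence
    n = len(seq)
    if n < 20:
        raise ValueError("sequence shorter than 20 residues")
    kd = [KYTE_DOOLITTLE[c] for c in seq]

    # all windows of length >= h_min_len starting within the search limit
    windows: list[tuple[float, int, int]] = []  # (mean_kd, start, end) 1-based
    max_start = min(params.h_search_limit, n - params.h_min_len + 1)
    prefix = [0.0]
    for v in kd:
        prefix.append(prefix[-1] + v)
    for start in range(1, max_start + 1):
        for end in range(start + params.h_min_len - 1, n + 1):
            mean = (prefix[end] - prefix[start - 1]) / (end - start + 1)
            if mean >= params.h_threshold:
                windows.append((mean, start, end))

    # prefer high mean hydropathy (rounded so float noise cannot split ties
    # between subwindows of a homogeneous stretch), then longer, then more
    # N-terminal; keep non-overlapping survivors so each hydrophobic stretch
    # yields exactly one candidate
    windows.sort(key=lambda w: (-round(w[0], 9), -(w[2] - w[1]), w[1]))
    chosen: list[tuple[float, int, int]] = []
    for mean, start, end in windows:
        if all(end < s or start > e for _, s, e in chosen):
            chosen.append((mean, start, end))

    candidates: list[SignalCandidate] = []
    for mean, h_start, h_end in chosen:
        n_pos = sum(1 for c in seq[: h_start - 1] if c in BASIC_RESIDUES)
        cleavages: list[tuple[int, int]] = []
        for p1 in range(h_end + 1, min(h_end + params.cleavage_window, n - 1) + 1):
            score = 0
            if seq[p1 - 1] in SMALL_RESIDUES:
                score += 1
            if p1 - 2 >= 1 and seq[p1 - 3] in SMALL_RESIDUES:
                score += 1
            if score > 0:
                cleavages.append((p1, score))
        cleavages.sort(key=lambda c: (-c[1], c[0]))
        best = cleavages[0][1] if cleavages else 0
        candidates.append(
            SignalCandidate(
                h_start=h_start,
                h_end=h_end,
                mean_hydropathy=mean,
                n_region_positives=n_pos,
                cleavage_candidates=cleavages,
                score=mean + 0.5 * n_pos + best,
            )
        )
    candidates.sort(key=lambda c: -c.score)
    return candidates


def propose_partition(
    sequence_length: int,
    sites: Sequence[CleavageSite | int],
    name_order: Sequence[str],
) -> DomainPartition:
    """Partition 1..length into segments delimited by cleavage P1 sites.

    Segment k runs from the previous site's P1 + 1 through the next site's
    P1; the last segment ends at ``sequence_length``. The segments tile the
    sequence exactly.
    """
    positions = [s.position if isinstance(s, CleavageSite) else int(s) for s in sites]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise ValueError("sites must be strictly ascending")
    if positions and (positions[0] < 1 or positions[-1] >= sequence_length):
        raise ValueError("site positions must lie in [1, length)")
    n_segments = len(positions) + 1
    if n_segments != len(name_order):
        raise ValueError(
            f"{n_segments} segments but {len(name_order)} names supplied"
        )
    bounds = [0] + positions + [sequence_length]
    segments = [
        DomainSegment(name=name, start=bounds[i] + 1, end=bounds[i + 1])
        for i, name in enumerate(name_order)
    ]
    return DomainPartition(segments)


def validate_partition(
    config: ToxinConfig,
    record: ProteinRecord,
    policy: MotifPolicy = EXTENDED_POLICY,
    slack: int = 2,
) -> ValidationReport:
    """Check curated boundaries and cysteines against the actual sequence.

    Each internal boundary (segment end that is not the sequence end) is
    "supported" when a scanned Kex motif has its P1 within ``slack``
    residues of it. Declared disulfide residues must be cysteines.
    """
    n = len(record.sequence)
    for seg in config.domains:
        if seg.end > n:
            raise ValueError(
                f"curated boundary {seg.name}:{seg.end} beyond sequence end ({n})"
            )
    sites = scan_cleavage_motifs(record, policy)
    checks: list[BoundaryCheck] = []
    for seg in config.domains:
        if seg.end >= n:
            continue  # the final segment end is not a cleavage boundary
        match = None
        for site in sites:
            if abs(site.position - seg.end) <= slack:
                if match is None or abs(site.position - seg.end) < abs(
                    match.position - seg.end
                ):
                    match = site
        checks.append(
            BoundaryCheck(
                domain=seg.name, boundary=seg.end,
                supported=match is not None, matched_site=match,
            )
        )
    cys_findings: list[str] = []
    for pair in config.disulfide_pairs:
        for pos in pair:
            if pos > n:
                cys_findings.append(f"declared cysteine {pos} beyond sequence end")
            elif record.sequence[pos - 1] != "C":
                cys_findings.append(
                    f"declared cysteine {pos} is {record.sequence[pos - 1]!r}"
                )
    return ValidationReport(
        toxin=config.name,
        record_id=record.id,
        boundary_checks=checks,
        cysteine_findings=cys_findings,
    )


def derive_mature_products(
    config: ToxinConfig,
    record: ProteinRecord | None = None,
    chain_masses: dict[str, float] | None = None,
) -> MatureProduct:
    """Build the secreted product from curated chain spans.

    With a sequence attached, per-chain masses are computed from the curated
    (post-Kex1-trim) spans. Alternatively ``chain_masses`` (Da) may be
    supplied directly for the pure arithmetic path. The total is the chain
    sum minus 2.016 Da per interchain disulfide bond.
    """
    table = default_mass_table()
    chains: list[MatureChain] = []
    if chain_masses is not None:
        for name, mass in chain_masses.items():
            chains.append(MatureChain(name=name, start=0, end=0, mass=float(mass)))
    else:
        if record is None:
            raise ValueError("either a record or chain_masses is required")
        partition = config.partition()
        names = partition.names()
        for seg in config.mature_chains:
            if seg.name not in names:
                raise ValueError(
                    f"mature chain {seg.name!r} absent from the domain partition"
                )
            parent = partition[seg.name]
            if not (parent.start <= seg.start and seg.end <= parent.end):
                raise ValueError(
                    f"mature chain {seg.name} span {seg.start}-{seg.end} lies "
                    f"outside its domain {parent.start}-{parent.end}"
                )
            mass = molecular_mass(record.subsequence(seg.start, seg.end), table=table)
            chains.append(MatureChain(seg.name, seg.start, seg.end, mass))
    if not chains:
        raise ValueError(f"config {config.name!r} declares no mature chains")
    total = sum(c.mass for c in chains) - config.interchain_disulfides * table.disulfide
    return MatureProduct(
        chains=chains,
        interchain_disulfides=config.interchain_disulfides,
        total_mass=total,
    )


def inventory_cysteines(
    record: ProteinRecord, partition: DomainPartition | None = None
) -> dict[str, list[int]]:
    """Group every cysteine position by the domain that contains it.

    Cysteines outside every segment (or all of them, when no partition is
    given) are grouped under ``"unassigned"``. Every C appears exactly once.
    """
    positions = [i for i, c in enumerate(record.sequence, start=1) if c == "C"]
    inventory: dict[str, list[int]] = {}
    for pos in positions:
        name = "unassigned"
        if partition is not None:
            for seg in partition:
                if pos in seg:
                    name = seg.name
                    break
        inventory.setdefault(name, []).append(pos)
    return inventory


# ---------------------------------------------------------------------------
# curated configuration data


def _load_config_payload() -> dict:
    return json.loads(
        resources.files("killerkit.data").joinpath("toxin_configs.json").read_text()
    )


def list_toxin_configs() -> list[str]:
    return sorted(_load_config_payload()["toxins"])


def load_toxin_config(name: str) -> ToxinConfig:
    """Load the curated annotation for one toxin (e.g. ``"K1"``)."""
    payload = _load_config_payload()["toxins"]
    if name not in payload:
        raise KeyError(
            f"unknown toxin {name!r}; available: {', '.join(sorted(payload))}"
        )
    raw = payload[name]
    return ToxinConfig(
        name=name,
        domain_order=list(raw["domain_order"]),
        domains=[DomainSegment(n, s, e) for n, s, e in raw["domains"]],
        signal_cleavage=raw["signal_cleavage"],
        kex2_sites=list(raw["kex2_sites"]),
        kex1_trim=raw["kex1_trim"],
        mature_chains=[DomainSegment(n, s, e) for n, s, e in raw["mature_chains"]],
        disulfide_pairs=[tuple(p) for p in raw["disulfide_pairs"]],
        interchain_disulfides=raw["interchain_disulfides"],
        length=raw.get("length"),
        notes=raw.get("notes", ""),
    )


def annotate_record(
    record: ProteinRecord,
    config: ToxinConfig | None = None,
    policy: MotifPolicy = DEFAULT_POLICY,
) -> dict:
    """Full annotation of one preprotoxin as a JSON-serializable dict.

    With a curated config the partition, mature products and validation come
    from it; otherwise the partition is proposed from scanned dibasic sites
    with generic segment names.
    """
    sites = scan_cleavage_motifs(record, policy)
    result: dict = {
        "id": record.id,
        "length": len(record.sequence),
        "sites": [
            {"position": s.position, "kind": s.kind, "motif": s.motif} for s in sites
        ],
    }
    try:
        signal = detect_signal_candidates(record)
    except ValueError:
        signal = []
    result["signal_candidates"] = [
        {
            "h_region": list(c.h_span),
            "mean_hydropathy": round(c.mean_hydropathy, 3),
            "n_region_positives": c.n_region_positives,
            "best_cleavage": c.best_cleavage,
            "score": round(c.score, 3),
        }
        for c in signal[:3]
    ]
    if config is not None and config.domains:
        partition = config.partition()
        report = validate_partition(config, record)
        result["toxin"] = config.name
        result["validation"] = {
            "all_supported": report.all_supported,
            "boundaries": [
                {
                    "domain": c.domain,
                    "boundary": c.boundary,
                    "supported": c.supported,
                    "matched_position": c.matched_site.position if c.matched_site else None,
                }
                for c in report.boundary_checks
            ],
            "cysteine_findings": report.cysteine_findings,
        }
        if config.mature_chains:
            product = derive_mature_products(config, record)
            result["mature_product"] = {
                "chains": [
                    {"name": c.name, "start": c.start, "end": c.end,
                     "mass_da": round(c.mass, 3)}
                    for c in product.chains
                ],
                "interchain_disulfides": product.interchain_disulfides,
                "total_mass_da": round(product.total_mass, 3),
                "total_kda": product.total_kda(),
            }
    else:
        names = [f"segment_{i + 1}" for i in range(len(sites) + 1)]
        partition = propose_partition(len(record.sequence), sites, names)
    result["partition"] = [
        {"name": s.name, "start": s.start, "end": s.end} for s in partition
    ]
    result["cysteines"] = inventory_cysteines(record, partition)
    return result
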
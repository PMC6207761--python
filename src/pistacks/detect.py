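"""Face-to-face pi-stacking detection.

Two rings form a face-to-face stacking pair when their centroid-centroid
distance is strictly below 6 A and the angle between their face normals is
within 20 degrees of parallel or antiparallel. Because a ring normal's sign
is arbitrary, the angle theta between unit normals is folded to
min(theta, 180 - theta), which maps "0 +/- 20 or 180 +/- 20 degrees" onto a
single sign-invariant test: folded angle <= 20.

Boundary behaviour, tested explicitly: the distance comparison is strict
(<), the angle comparison inclusive (<=).

Maximal stacks are the connected components of the graph whose vertices are
rings and whose edges are accepted pairs. A stack is inter-chain when any
of its rings sit on different chains (equivalently, when any pair crosses
two chain IDs — the two readings coincide on a connected component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from pistacks.rings import AromaticRing

__all__ = [
    "DetectionConfig", "StackPair", "PiStack", "SurveyRecord",
    "is_stacking_pair", "folded_normal_angle", "find_pairs",
    "assemble_stacks", "classify_and_filter",
    "CURATION_PRESET", "INTERCHAIN_PRESET",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the detection rule.

    distance_threshold : A, centroid separation must be strictly below.
    angle_threshold : degrees, folded normal angle must not exceed.
    min_rings_report : smallest stack size kept in the survey report.
    """

    distance_threshold: float = 6.0
    angle_threshold: float = 20.0
    min_rings_report: int = 6

    def __post_init__(self):
        if self.distance_threshold <= 0 or self.angle_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_rings_report < 2:
            raise ValueError("min_rings_report must be >= 2")


#: stacks of more than 5 rings, the curation threshold for survey hits
CURATION_PRESET = DetectionConfig(min_rings_report=6)
#: the inter-chain analysis considers stacks of 4 or more rings
INTERCHAIN_PRESET = DetectionConfig(min_rings_report=4)


def folded_normal_angle(normal_a, normal_b) -> float:
    """Angle between two unit normals folded into [0, 90] degrees.

    Sign-invariant in both arguments: flipping either normal leaves the
    folded angle unchanged.
    """
    cos_theta = float(np.clip(abs(np.dot(normal_a, normal_b)), -1.0, 1.0))
    return math.degrees(math.acos(cos_theta))


@dataclass(frozen=True)
class StackPair:
    """An accepted face-to-face interaction between two rings (unordered)."""

    ring_a: AromaticRing
    ring_b: AromaticRing
    distance: float
    angle: float

    @property
    def key(self) -> frozenset:
        return frozenset((self.ring_a, self.ring_b))

    def __eq__(self, other):
        if not isinstance(other, StackPair):
            return NotImplemented
        return self.key == other.key

    def __hash__(self):
        return hash(self.key)


@dataclass
class PiStack:
    """A maximal connected set of rings linked by stacking pairs."""

    rings: frozenset
    pairs: frozenset
    chains: frozenset = field(init=False)
    size: int = field(init=False)
    interchain: bool = field(init=False)

    def __post_init__(self):
        self.chains = frozenset(r.chain_id for r in self.rings)
        self.size = len(self.rings)
        self.interchain = len(self.chains) >= 2

    @property
    def mean_distance(self) -> float:
        return float(np.mean([p.distance for p in self.pairs]))

    @property
    def mean_angle(self) -> float:
        return float(np.mean([p.angle for p in self.pairs]))


def is_stacking_pair(
    a: AromaticRing, b: AromaticRing, cfg: DetectionConfig = DetectionConfig()
) -> tuple[bool, float, float]:
    """Evaluate the detection rule on one ring pair.

    Returns ``(accepted, distance_A, folded_angle_deg)``. Symmetric in its
    arguments and invariant under flipping either normal.
    """
    distance = float(np.linalg.norm(a.centroid_array - b.centroid_array))
    angle = folded_normal_angle(a.normal_array, b.normal_array)
    accepted = distance < cfg.distance_threshold and angle <= cfg.angle_threshold
    return accepted, distance, angle


def find_pairs(
    rings: list[AromaticRing], cfg: DetectionConfig = DetectionConfig()
) -> list[StackPair]:
    """All stacking pairs among ``rings`` — exact all-pairs evaluation.

    Distances and folded angles are computed for every unordered pair; no
    spatial index prunes candidates, so the result is identical to a
    brute-force oracle by construction.
    """
    n = len(rings)
    if n < 2:
        return []
    centroids = np.array([r.centroid for r in rings])
    normals = np.array([r.normal for r in rings])
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cos = np.clip(np.abs(normals @ normals.T), -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    accepted = (dist < cfg.distance_threshold) & (ang <= cfg.angle_threshold)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if accepted[i, j]:
                pairs.append(StackPair(rings[i], rings[j],
                                       float(dist[i, j]), float(ang[i, j])))
    return pairs


def assemble_stacks(pairs: list[StackPair]) -> list[PiStack]:
    """Group pairs into maximal stacks (connected components).

    Every ring appearing in at least one pair belongs to exactly one stack.
    Output order is deterministic: by chain, residue number of the first
    ring of each stack.
    """
    graph = nx.Graph()
    by_ring: dict[AromaticRing, list[StackPair]] = {}
    for pair in pairs:
        graph.add_edge(pair.ring_a, pair.ring_b)
        by_ring.setdefault(pair.ring_a, []).append(pair)
        by_ring.setdefault(pair.ring_b, []).append(pair)
    stacks = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        stack_pairs = frozenset(
            p for ring in members for p in by_ring[ring]
            if p.ring_a in members and p.ring_b in members
        )
        stacks.append(PiStack(rings=members, pairs=stack_pairs))
    stacks.sort(key=lambda s: min((r.chain_id, r.residue_seq) for r in s.rings))
    return stacks


@dataclass(frozen=True)
class SurveyRecord:
    """One reportable stack, flattened for the survey TSV."""

    structure_id: str
    stack_id: int
    size: int
    interchain: bool
    chains: str          # sorted, comma-joined
    residues: str        # chain:resname:resnum;... sorted
    mean_distance_A: float
    mean_angle_deg: float


def classify_and_filter(
    stacks: list[PiStack],
    cfg: DetectionConfig = DetectionConfig(),
    structure_id: str = "",
    interchain_only: bool = False,
) -> list[SurveyRecord]:
    """Label stacks intra-/inter-chain and keep those of reportable size.

    Only stacks with ``size >= cfg.min_rings_report`` are retained (the
    full stack list remains available from :func:`assemble_stacks`).
    Records are ordered by size descending, then residue labels.
    """
    records = []
    for stack in stacks:
        if stack.size < cfg.min_rings_report:
            continue
        if interchain_only and not stack.interchain:
            continue
        ordered = sorted(stack.rings, key=lambda r: (r.chain_id, r.residue_seq))
        records.append(SurveyRecord(
            structure_id=structure_id,
            stack_id=0,  # assigned after sorting
            size=stack.size,
            interchain=stack.interchain,
            chains=",".join(sorted(stack.chains)),
            residues=";".join(r.label for r in ordered),
            mean_distance_A=stack.mean_distance,
            mean_angle_deg=stack.mean_angle,
        ))
    records.sort(key=lambda r: (-r.size, r.residues))
    return [
        SurveyRecord(**{**vars(rec), "stack_id": i + 1})
        for i, rec in enumerate(records)
    ]
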
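"""Active-site geometry of the proteasome core particle.

The CP stacks two beta rings of seven subunits each, so one particle
carries 14 catalytic threonines (Thr1).  An already-activated subunit can
cleave the propeptide of a neighbour only if the flexible glycine-rich
linker (region III) can physically span from its last structured residue
(the Arg at propeptide position -24, the "anchor") to the neighbouring
active site.  This module extracts the 14 Thr1 reference atoms and their
anchors from a PDB-format structure, classifies site neighbour pairs,
and evaluates that contour-length feasibility.

Distance convention (per the cross-cutting geometry): for a central site
and one of its neighbours,

    l1      = |Thr1_central - Thr1_neighbor|
    l2      = |Thr1_neighbor - anchor_central|
    l_total = l1 + l2

and the linker of ``n`` flexible residues can reach at most
``(n - occlusion) * per_residue_span`` angstrom, with 3.63 A per residue
(the trans Calpha-Calpha virtual bond, i.e. the fully extended contour)
and ``occlusion`` residues assumed buried in the cutting groove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance_matrix as _scipy_distance_matrix

RING_LABELS = ("A", "B")
N_PER_RING = 7
N_SITES = 14

#: Fully extended Calpha-Calpha span per residue (trans peptide), angstrom.
PER_RESIDUE_SPAN = 3.63


class StructureModelError(ValueError):
    """The coordinate file does not describe a 14-active-site CP."""


@dataclass(frozen=True)
class Site:
    ring: str  # "A" or "B"
    index: int  # 0..6 around the ring
    xyz: tuple[float, float, float]

    @property
    def site_id(self) -> str:
        return f"{self.ring}{self.index}"

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class ActiveSiteSet:
    """The 14 catalytic Thr1 reference atoms, labelled by ring and index."""

    sites: list[Site]

    def __post_init__(self) -> None:
        if len(self.sites) != N_SITES:
            raise StructureModelError(
                f"expected {N_SITES} active sites, got {len(self.sites)}"
            )
        keys = {(s.ring, s.index) for s in self.sites}
        if len(keys) != N_SITES:
            raise StructureModelError("duplicate (ring, index) labels among sites")

    def __iter__(self):
        return iter(self.sites)

    def get(self, site_id: str) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site {site_id!r}")

    def coords(self) -> np.ndarray:
        """(14, 3) coordinate array in the canonical A0..A6,B0..B6 order."""
        ordered = sorted(self.sites, key=lambda s: (s.ring, s.index))
        return np.vstack([s.coord for s in ordered])

    def ordered_ids(self) -> list[str]:
        return [s.site_id for s in sorted(self.sites, key=lambda s: (s.ring, s.index))]


@dataclass
class AnchorSet:
    """Per-site coordinates of the last structured propeptide residue.

    Anchors may be absent for structures of the mature CP whose
    propeptides are no longer resolved.
    """

    anchors: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.anchors

    def coord(self, site_id: str) -> np.ndarray:
        if site_id not in self.anchors:
            raise KeyError(f"no anchor recorded for site {site_id!r}")
        return np.asarray(self.anchors[site_id], dtype=float)


@dataclass(frozen=True)
class AtomSelector:
    """Selects one reference atom per subunit from a coordinate file.

    ``chains`` restricts the search to the named chains (None = all),
    ``residue_name`` / ``residue_seqid`` pick the residue (seqid None =
    every residue of that name), ``atom`` names the reference atom.
    """

    residue_name: str = "THR"
    atom: str = "CA"
    residue_seqid: int | None = None
    chains: tuple[str, ...] | None = None


DEFAULT_THR1_SELECTOR = AtomSelector(residue_name="THR", atom="CA")
DEFAULT_ANCHOR_SELECTOR = AtomSelector(residue_name="ARG", atom="CA")


def _collect_atoms(structure, selector: AtomSelector) -> list[tuple[str, np.ndarray]]:
    hits: list[tuple[str, np.ndarray]] = []
    model = structure[0]
    for chain in model:
        if selector.chains is not None and chain.name not in selector.chains:
            continue
        for residue in chain:
            if residue.name != selector.residue_name:
                continue
            if selector.residue_seqid is not None and residue.seqid.num != selector.residue_seqid:
                continue
            for atom in residue:
                if atom.name == selector.atom:
                    hits.append((chain.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
                    break
    return hits


def _label_rings(points: np.ndarray) -> tuple[list[str], list[int]]:
    """Split 14 points into two rings of 7 and index them azimuthally.

    Ring membership is decided along the principal (pseudo-symmetry) axis
    of the point cloud; within each ring, indices 0..6 run by azimuth
    around that axis.
    """
    center = points.mean(axis=0)
    centered = points - center
    # Axis = eigenvector of the covariance with the *largest* spread between
    # the two ring planes: use the direction maximising bimodal separation,
    # i.e. the principal axis orthogonal to the ring planes.  For two
    # parallel rings that is the eigenvector of smallest in-plane variance
    # unless separation is large; pick the axis whose projections split
    # cleanly into two groups of seven.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    best = None
    for axis in vt:
        proj = centered @ axis
        order = np.argsort(proj)
        gap = proj[order[7]] - proj[order[6]]
        if best is None or gap > best[0]:
            best = (gap, axis, proj)
    _, axis, proj = best
    order = np.argsort(proj)
    lower, upper = order[:7], order[7:]
    if proj[upper].min() - proj[lower].max() <= 0:
        raise StructureModelError("cannot separate the two beta rings along any axis")
    # Azimuthal ordering within each ring.
    e1 = vt[0] if abs(np.dot(vt[0], axis)) < 0.9 else vt[1]
    e1 = e1 - np.dot(e1, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rings = [""] * len(points)
    indices = [0] * len(points)
    for ring_label, members in zip(RING_LABELS, (lower, upper)):
        az = np.arctan2(centered[members] @ e2, centered[members] @ e1)
        for idx, member in enumerate(members[np.argsort(az)]):
            rings[member] = ring_label
            indices[member] = idx
    return rings, indices


def load_structure(
    path: str,
    thr1_selector: AtomSelector = DEFAULT_THR1_SELECTOR,
    anchor_selector: AtomSelector | None = DEFAULT_ANCHOR_SELECTOR,
) -> tuple[ActiveSiteSet, AnchorSet]:
    """Extract the 14 Thr1 sites (and anchors, where resolved) from a PDB file.

    Site chains are identified by ``thr1_selector``; if the file does not
    yield exactly 14 matches a :class:`StructureModelError` names the
    deficit.  Anchors are matched to sites by chain when the anchor lies in
    a chain holding exactly one site, otherwise by spatial proximity.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    hits = _collect_atoms(structure, thr1_selector)
    if len(hits) != N_SITES:
        raise StructureModelError(
            f"found {len(hits)} catalytic-residue matches, expected {N_SITES} "
            f"(selector {thr1_selector})"
        )
    points = np.vstack([p for _, p in hits])
    rings, indices = _label_rings(points)
    sites = [
        Site(ring=r, index=i, xyz=tuple(map(float, p)))
        for r, i, (_, p) in zip(rings, indices, hits)
    ]
    site_set = ActiveSiteSet(sites=sites)

    anchors = AnchorSet()
    if anchor_selector is not None:
        anchor_hits = _collect_atoms(structure, anchor_selector)
        chain_sites: dict[str, list[Site]] = {}
        for (chain, _), site in zip(hits, sites):
            chain_sites.setdefault(chain, []).append(site)
        for chain, coord in anchor_hits:
            owners = chain_sites.get(chain, [])
            if len(owners) == 1:
                site = owners[0]
            else:
                dists = [np.linalg.norm(coord - s.coord) for s in sites]
                site = sites[int(np.argmin(dists))]
            anchors.anchors[site.site_id] = tuple(map(float, coord))
    return site_set, anchors


def pairwise_site_distances(
    site_set: ActiveSiteSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Euclidean distances plus a neighbour classification.

    Returns ``(matrix, pairs)`` where ``matrix`` is the symmetric 14x14
    distance table indexed by site id, and ``pairs`` is a tidy table with
    one row per unordered pair, classified as ``intra_ring_adjacent``
    (ring index +/-1 mod 7), ``inter_ring_nearest`` (minimum-distance
    partner on the other ring, from either side) or ``other``.
    """
    ids = site_set.ordered_ids()
    coords = site_set.coords()
    mat = _scipy_distance_matrix(coords, coords)
    matrix = pd.DataFrame(mat, index=ids, columns=ids)

    by_id = {sid: k for k, sid in enumerate(ids)}
    nearest_partner: dict[str, str] = {}
    for sid in ids:
        other_ring = [t for t in ids if t[0] != sid[0]]
        d = [matrix.loc[sid, t] for t in other_ring]
        nearest_partner[sid] = other_ring[int(np.argmin(d))]

    records = []
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1 :]:
            ring_a, idx_a = a[0], int(a[1:])
            ring_b, idx_b = b[0], int(b[1:])
            if ring_a == ring_b and (idx_a - idx_b) % 7 in (1, 6):
                kind = "intra_ring_adjacent"
            elif ring_a != ring_b and (nearest_partner[a] == b or nearest_partner[b] == a):
                kind = "inter_ring_nearest"
            else:
                kind = "other"
            records.append(
                {"site_a": a, "site_b": b, "distance": float(mat[by_id[a], by_id[b]]), "kind": kind}
            )
    return matrix, pd.DataFrame(records)


def min_neighbor_distance(site_set: ActiveSiteSet) -> float:
    """Minimum Thr1-Thr1 distance over neighbour pairs.

    Neighbour pairs are the intra-ring adjacent pairs plus each site's
    nearest partner on the opposite ring.
    """
    _, pairs = pairwise_site_distances(site_set)
    neigh = pairs[pairs["kind"].isin(["intra_ring_adjacent", "inter_ring_nearest"])]
    return float(neigh["distance"].min())


@dataclass(frozen=True)
class SpanRequirement:
    """Distances the flexible linker must cover to reach one neighbour."""

    central: str
    neighbor: str
    l1: float  # central Thr1 -> neighbor Thr1
    l2: float  # neighbor Thr1 -> central anchor (Arg -24)
    l_total: float

    def __post_init__(self) -> None:
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("distances must be non-negative")
        if not np.isclose(self.l_total, self.l1 + self.l2, atol=1e-9):
            raise ValueError("l_total inconsistent with l1 + l2")


def required_span(
    central: str,
    neighbor: str,
    site_set: ActiveSiteSet,
    anchors: AnchorSet,
) -> SpanRequirement:
    """Span requirement for the central subunit's linker to reach a neighbour."""
    if central not in anchors:
        raise KeyError(f"no anchor for central site {central!r}")
    t_c = site_set.get(central).coord
    t_n = site_set.get(neighbor).coord
    a_c = anchors.coord(central)
    l1 = float(np.linalg.norm(t_c - t_n))
    l2 = float(np.linalg.norm(t_n - a_c))
    return SpanRequirement(central=central, neighbor=neighbor, l1=l1, l2=l2, l_total=l1 + l2)


@dataclass(frozen=True)
class LoopSpanModel:
    """Contour-length model of the flexible region III linker.

    ``n_residues`` flexible residues reach at most
    ``(n_residues - occlusion) * per_residue_span`` angstrom; ``occlusion``
    residues (default 4, the P4-P1 stretch) are assumed engaged in the
    neighbour's substrate groove and unavailable for spanning.
    """

    n_residues: int = 26
    per_residue_span: float = PER_RESIDUE_SPAN
    occlusion: int = 4

    def __post_init__(self) -> None:
        if self.n_residues < 0:
            raise ValueError("n_residues must be >= 0")
        if self.per_residue_span <= 0:
            raise ValueError("per_residue_span must be > 0")
        if self.occlusion < 0:
            raise ValueError("occlusion must be >= 0")

    @property
    def max_reach(self) -> float:
        return max(self.n_residues - self.occlusion, 0) * self.per_residue_span


@dataclass(frozen=True)
class SpanVerdict:
    feasible: bool
    slack: float  # max reach - l_total (negative when infeasible)
    max_reach: float


def span_feasibility(req: SpanRequirement, loop: LoopSpanModel) -> SpanVerdict:
    """Can the linker span ``l_total``?  Ties count as feasible."""
    reach = loop.max_reach
    slack = reach - req.l_total
    return SpanVerdict(feasible=slack >= 0, slack=slack, max_reach=reach)


def span_table(
    site_set: ActiveSiteSet,
    anchors: AnchorSet,
    loop: LoopSpanModel,
    central: str | None = None,
) -> pd.DataFrame:
    """Feasibility table over neighbour pairs (one row per directed pair).

    When ``central`` is given, only that subunit's linker is evaluated
    against every neighbour (the layout used for the published distance
    table); otherwise every site with an anchor is evaluated.
    """
    _, pairs = pairwise_site_distances(site_set)
    neigh = pairs[pairs["kind"] != "other"]
    rows = []
    for _, rec in neigh.iterrows():
        for c, n in ((rec["site_a"], rec["site_b"]), (rec["site_b"], rec["site_a"])):
            if central is not None and c != central:
                continue
            if c not in anchors:
                continue
            req = required_span(c, n, site_set, anchors)
            verdict = span_feasibility(req, loop)
            rows.append(
                {
                    "central": c,
                    "neighbor": n,
                    "kind": rec["kind"],
                    "l1": req.l1,
                    "l2": req.l2,
                    "l_total": req.l_total,
                    "max_reach": verdict.max_reach,
                    "feasible": verdict.feasible,
                    "slack": verdict.slack,
                }
            )
    return pd.DataFrame(rows)


def feasible_cross_edges(
    site_set: ActiveSiteSet,
    anchors: AnchorSet,
    loop: LoopSpanModel,
) -> list[tuple[str, str]]:
    """Inter-ring site pairs reachable by at least one partner's linker.

    These are the geometry-derived edges over which cross-cutting across
    the half-proteasome dimer interface is considered possible.
    """
    table = span_table(site_set, anchors, loop)
    if table.empty:
        return []
    inter = table[(table["kind"] == "inter_ring_nearest") & table["feasible"]]
    edges = {tuple(sorted((r["central"], r["neighbor"]))) for _, r in inter.iterrows()}
    return sorted(edges)
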
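"""A-Bruijn assembly of spectral-network components into meta-contigs.

Matched peak pairs of all edges in a connected component are glued by
union-find into vertices; each spectrum's coordinate frame is propagated from
an anchor node along a maximum-score spanning tree using the edge shifts.
A union that would place two peaks of one spectrum in one vertex, or whose
frame-propagated masses disagree by more than ``frame_tol``, is refused and
the offending pair dropped.  The contig is the heaviest path (by summed vertex
score) through the DAG whose edges come from consecutive peaks of member
spectra; its vertices' (consensus mass, total score) pairs form the consensus
PRM spectrum, or meta-contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import RESIDUE_MASS
from .model import PRMSpectrum
from .network import PairwiseAlignment

log = logging.getLogger(__name__)

DEFAULT_FRAME_TOL = 0.35
DEFAULT_MIN_COMPONENT_SIZE = 2


@dataclass
class AbruijnVertex:
    """A glued set of peaks, at most one per member spectrum."""

    members: list[tuple[str, int]]          # (spectrum id, peak index)
    consensus_mass: float                   # score-weighted mean frame mass
    total_score: float


@dataclass
class Contig:
    contig_id: str
    vertices: list[AbruijnVertex]           # ordered by consensus mass
    member_ids: list[str]
    anchor: str
    offsets: dict[str, float]               # spectrum frame offset (normalised)
    span: float
    path: list[int] = field(default_factory=list)  # indices of heaviest-path vertices


@dataclass
class MetaContig:
    contig_id: str
    masses: np.ndarray                      # consensus PRM masses, contig frame
    scores: np.ndarray
    n_spectra: int
    span: float
    member_ids: list[str] = field(default_factory=list)
    offsets: dict[str, float] = field(default_factory=dict)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)


def glue(
    prms: dict[str, PRMSpectrum],
    edges: list[PairwiseAlignment],
    frame_tol: float = DEFAULT_FRAME_TOL,
) -> tuple[list[AbruijnVertex], dict[str, float], str]:
    """Glue one connected component; returns (vertices, offsets, anchor id).

    ``prms`` maps spectrum id to its (possibly score-filtered) PRM spectrum;
    ``edges`` are the component's alignments.  Unmatched peaks are kept as
    singleton vertices — they may carry true ladder masses.  Offsets are
    normalised so the smallest frame offset is 0 (the N-terminal boundary of
    the earliest peptide in the region).
    """
    g = nx.Graph()
    for sid in prms:
        g.add_node(sid)
    for al in edges:
        g.add_edge(al.id_a, al.id_b, weight=al.score, alignment=al)
    if g.number_of_nodes() == 0:
        return [], {}, ""
    if not nx.is_connected(g):
        raise ValueError("glue expects a connected component")
    anchor = max(prms, key=lambda sid: (prms[sid].total_score, sid))
    offsets: dict[str, float] = {anchor: 0.0}
    if g.number_of_edges():
        tree = nx.maximum_spanning_tree(g, weight="weight")
        for parent, child in nx.bfs_edges(tree, anchor):
            al: PairwiseAlignment = g.edges[parent, child]["alignment"]
            # mass_a ~ mass_b + shift, so frame(b) = frame(a) + shift
            if al.id_a == parent:
                offsets[child] = offsets[parent] + al.shift
            else:
                offsets[child] = offsets[parent] - al.shift
    for sid in prms:
        offsets.setdefault(sid, 0.0)

    uf = _UnionFind()
    # cluster bookkeeping: root -> (spectrum ids, min/max frame mass)
    meta: dict[tuple, dict] = {}

    def info(key):
        root = uf.find(key)
        if root not in meta:
            sid, idx = root
            fm = offsets[sid] + float(prms[sid].masses[idx])
            meta[root] = {"sids": {sid}, "lo": fm, "hi": fm}
        return root, meta[root]

    dropped = 0
    for al in sorted(edges, key=lambda e: -e.score):
        for ia, ib in al.matched_pairs:
            ka, kb = (al.id_a, ia), (al.id_b, ib)
            ra, ma = info(ka)
            rb, mb = info(kb)
            if ra == rb:
                continue
            if ma["sids"] & mb["sids"]:
                dropped += 1  # would glue two peaks of one spectrum
                continue
            lo, hi = min(ma["lo"], mb["lo"]), max(ma["hi"], mb["hi"])
            if hi - lo > frame_tol:
                dropped += 1  # frame propagation disagrees across this edge
                continue
            uf.union(ka, kb)
            root = uf.find(ka)
            merged = {"sids": ma["sids"] | mb["sids"], "lo": lo, "hi": hi}
            meta.pop(ra, None)
            meta.pop(rb, None)
            meta[root] = merged
    if dropped:
        log.info("glue: dropped %d conflicting matched pairs", dropped)

    clusters: dict = {}
    for sid, p in prms.items():
        for idx in range(len(p)):
            clusters.setdefault(uf.find((sid, idx)), []).append((sid, idx))
    vertices = []
    for members in clusters.values():
        fm = np.array([offsets[sid] + prms[sid].masses[idx] for sid, idx in members])
        sc = np.array([prms[sid].scores[idx] for sid, idx in members])
        w = np.clip(sc, 1e-9, None)
        vertices.append(
            AbruijnVertex(
                members=sorted(members),
                consensus_mass=float(np.average(fm, weights=w)),
                total_score=float(sc.sum()),
            )
        )
    vertices.sort(key=lambda v: v.consensus_mass)
    shift0 = min(offsets.values())
    offsets = {sid: off - shift0 for sid, off in offsets.items()}
    for v in vertices:
        v.consensus_mass -= shift0
    return vertices, offsets, anchor


def heaviest_path(
    scores: np.ndarray,
    edges: set[tuple[int, int]],
    n_members: np.ndarray,
    edge_penalty: dict[tuple[int, int], float] | None = None,
) -> list[int]:
    """Heaviest path through a DAG of mass-ordered vertices.

    ``edges`` contain (u, v) with u < v in mass order.  Maximises the summed
    vertex score minus any per-edge penalties; ties broken toward paths
    through vertices with more member spectra, then toward lower consensus
    mass (lower index).
    """
    n = len(scores)
    preds: dict[int, list[int]] = {v: [] for v in range(n)}
    for u, v in edges:
        preds[v].append(u)
    penalty = edge_penalty or {}
    # dp key: (score, member count along path, -start index for determinism)
    dp = [(float(scores[v]), int(n_members[v]), -v) for v in range(n)]
    parent = [-1] * n
    for v in range(n):
        best = None
        arg = -1
        for u in sorted(preds[v]):
            cand = (dp[u][0] - penalty.get((u, v), 0.0), dp[u][1], dp[u][2])
            if best is None or cand > best:
                best = cand
                arg = u
        if best is not None and best[0] + float(scores[v]) > dp[v][0]:
            dp[v] = (
                best[0] + float(scores[v]),
                best[1] + int(n_members[v]),
                best[2],
            )
            parent[v] = arg
    end = max(range(n), key=lambda v: dp[v])
    path = []
    v = end
    while v >= 0:
        path.append(v)
        v = parent[v]
    path.reverse()
    return path


DEFAULT_GAP_PENALTY = 10.0
RESIDUE_STEP_TOL = 0.03

_RESIDUE_MASSES = np.array(sorted(set(RESIDUE_MASS.values())))


def _is_residue_step(delta: float, tol: float = RESIDUE_STEP_TOL) -> bool:
    i = int(np.searchsorted(_RESIDUE_MASSES, delta))
    for j in (i - 1, i):
        if 0 <= j < len(_RESIDUE_MASSES) and abs(_RESIDUE_MASSES[j] - delta) <= tol:
            return True
    return False


def consensus_path(
    vertices: list[AbruijnVertex],
    prms: dict[str, PRMSpectrum],
    offsets: dict[str, float],
    anchor: str,
    contig_id: str,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> Contig:
    """Select the heaviest path and package the contig.

    The DAG has an edge u -> v whenever some member spectrum has consecutive
    peaks in u then v (in its own mass order).  Steps whose mass difference is
    not a single residue mass carry ``gap_penalty`` (log-odds units), so the
    path detours through a weakly supported non-residue vertex only when the
    vertex's own evidence outweighs two gap steps.
    """
    if not vertices:
        raise ValueError("empty vertex set")
    index_of: dict[tuple[str, int], int] = {}
    for vi, v in enumerate(vertices):
        for member in v.members:
            index_of[member] = vi
    edges: set[tuple[int, int]] = set()
    for sid, p in prms.items():
        seq = [index_of[(sid, idx)] for idx in range(len(p))]
        for u, v in zip(seq[:-1], seq[1:]):
            if u != v and vertices[u].consensus_mass < vertices[v].consensus_mass:
                edges.add((u, v))
    penalties = {
        (u, v): 0.0
        if _is_residue_step(vertices[v].consensus_mass - vertices[u].consensus_mass)
        else gap_penalty
        for u, v in edges
    }
    scores = np.array([v.total_score for v in vertices])
    n_members = np.array([len(v.members) for v in vertices])
    path = heaviest_path(scores, edges, n_members, penalties)
    on_path = [vertices[i] for i in path]
    contributions: dict[str, int] = {}
    for v in on_path:
        for sid, _ in v.members:
            contributions[sid] = contributions.get(sid, 0) + 1
    member_ids = sorted(sid for sid, c in contributions.items() if c >= 2)
    span = max(offsets[sid] + prms[sid].M for sid in prms) - min(offsets.values())
    return Contig(
        contig_id=contig_id,
        vertices=vertices,
        member_ids=member_ids,
        anchor=anchor,
        offsets=dict(offsets),
        span=float(span),
        path=path,
    )


def to_meta_contig(
    contig: Contig, min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE
) -> MetaContig | None:
    """Consensus PRM spectrum of a contig; None when too few member spectra."""
    if len(contig.member_ids) < min_component_size:
        return None
    path_vertices = [contig.vertices[i] for i in contig.path]
    masses = np.array([v.consensus_mass for v in path_vertices])
    scores = np.array([v.total_score for v in path_vertices])
    return MetaContig(
        contig_id=contig.contig_id,
        masses=masses,
        scores=scores,
        n_spectra=len(contig.member_ids),
        span=contig.span,
        member_ids=list(contig.member_ids),
        offsets=dict(contig.offsets),
    )


def assemble(
    network: nx.Graph,
    frame_tol: float = DEFAULT_FRAME_TOL,
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
) -> tuple[list[MetaContig], list[Contig]]:
    """Assemble every network component into contigs and meta-contigs.

    The network's node attribute ``prm`` holds the (score-filtered) PRM
    spectrum each alignment's peak indices refer to.
    """
    metas: list[MetaContig] = []
    contigs: list[Contig] = []
    for ci, component in enumerate(
        sorted(nx.connected_components(network), key=lambda c: sorted(c)[0]), start=1
    ):
        if len(component) < 2:
            continue
        sub = {sid: network.nodes[sid]["prm"] for sid in component}
        edges = [
            network.edges[u, v]["alignment"]
            for u, v in network.subgraph(component).edges
        ]
        vertices, offsets, anchor = glue(sub, edges, frame_tol)
        if not vertices:
            continue
        contig = consensus_path(vertices, sub, offsets, anchor, f"contig{ci:04d}")
        contigs.append(contig)
        mc = to_meta_contig(contig, min_component_size)
        if mc is not None:
            metas.append(mc)
    return metas, contigs
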
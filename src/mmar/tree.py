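"""Coronary centerline trees and their densified sample form.

A centerline tree is a rooted polyline forest in world millimetres: one root
per artery (RCA, LAD, LCx), every other node linked to a parent, each node
tagged with an artery and a free-form branch label.  Territories are computed
against a *densified* version of the tree in which every polyline edge is
subdivided so that consecutive samples are no further apart than a stated
spacing; the samples, not the sparse nodes, act as Voronoi seeds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

ARTERIES = ("RCA", "LAD", "LCx")


@dataclass
class Node:
    node_id: int
    position: np.ndarray  # (3,) world mm
    parent_id: Optional[int]
    artery: str
    branch: str


@dataclass
class CenterlineTree:
    """Rooted forest of coronary artery centerlines.

    Invariants (checked by :meth:`validate`): the graph is a forest with one
    root per artery, the artery label is constant within each component, all
    coordinates are finite and parent-child edges have positive length.
    """

    nodes: list[Node] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {n.node_id: n for n in self.nodes}
        if len(self._by_id) != len(self.nodes):
            raise ValueError("duplicate node ids")

    def node(self, node_id: int) -> Node:
        return self._by_id[node_id]

    @property
    def roots(self) -> list[Node]:
        return [n for n in self.nodes if n.parent_id is None]

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                ch[n.parent_id].append(n.node_id)
        return ch

    def validate(self) -> None:
        if not self.nodes:
            raise ValueError("empty centerline tree")
        roots_per_artery: dict[str, int] = {}
        for n in self.nodes:
            if not np.all(np.isfinite(n.position)):
                raise ValueError(f"node {n.node_id}: non-finite coordinates")
            if n.parent_id is None:
                roots_per_artery[n.artery] = roots_per_artery.get(n.artery, 0) + 1
            else:
                if n.parent_id not in self._by_id:
                    raise ValueError(f"node {n.node_id}: missing parent {n.parent_id}")
                parent = self._by_id[n.parent_id]
                if parent.artery != n.artery:
                    raise ValueError(
                        f"node {n.node_id}: artery differs from parent's"
                    )
        for artery, k in roots_per_artery.items():
            if k != 1:
                raise ValueError(f"artery {artery}: {k} roots (expected 1)")
        # cycle check: walk to root from every node
        for n in self.nodes:
            seen = set()
            cur: Optional[int] = n.node_id
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle detected in centerline tree")
                seen.add(cur)
                cur = self._by_id[cur].parent_id

    # ------------------------------------------------------------------ JSON
    @classmethod
    def from_json(cls, path_or_str) -> "CenterlineTree":
        """Load from the centerline JSON schema.

        ``{"arteries": [{"name": "LAD", "nodes": [{"id": 0, "xyz": [x, y, z],
        "parent": null, "branch": "main"}, ...]}, ...]}``
        """
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("{"):
            doc = json.loads(path_or_str)
        else:
            with open(path_or_str) as fh:
                doc = json.load(fh)
        nodes = []
        for artery in doc["arteries"]:
            name = artery["name"]
            for nd in artery["nodes"]:
                nodes.append(
                    Node(
                        node_id=int(nd["id"]),
                        position=np.asarray(nd["xyz"], dtype=float),
                        parent_id=None if nd["parent"] is None else int(nd["parent"]),
                        artery=name,
                        branch=str(nd.get("branch", "main")),
                    )
                )
        tree = cls(nodes)
        tree.validate()
        return tree

    def to_json(self, path=None) -> str:
        arteries = []
        for name in sorted({n.artery for n in self.nodes}):
            arteries.append(
                {
                    "name": name,
                    "nodes": [
                        {
                            "id": n.node_id,
                            "xyz": [float(v) for v in n.position],
                            "parent": n.parent_id,
                            "branch": n.branch,
                        }
                        for n in self.nodes
                        if n.artery == name
                    ],
                }
            )
        text = json.dumps({"arteries": arteries}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class LesionPoint:
    """A culprit-lesion location on the tree.

    ``anchor`` is either an original node id or a ``(branch, arc_mm)`` pair;
    arc length is measured along the tree from the most proximal sample
    carrying that branch label.  Arc anchors snap to the nearest densified
    sample at-or-distal to the requested arc length.
    """

    artery: str
    anchor: Union[int, tuple]


@dataclass
class SampledTree:
    """Densified centerline tree: the Voronoi seed set.

    Sample ``i`` has position ``positions[i]``, predecessor ``parent[i]``
    (-1 for artery roots), labels ``artery[i]``/``branch[i]``, the original
    node id ``node_id[i]`` (-1 for interior samples) and ``arc[i]``, the
    along-tree distance in mm from the first sample of its branch.
    """

    positions: np.ndarray        # (n, 3)
    parent: np.ndarray           # (n,) int, -1 at roots
    artery: np.ndarray           # (n,) object
    branch: np.ndarray           # (n,) object
    node_id: np.ndarray          # (n,) int, -1 for interior samples
    arc: np.ndarray              # (n,) float mm

    def __len__(self) -> int:
        return len(self.parent)

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(len(self))}
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[int(p)].append(i)
        return ch

    def sample_for_node(self, node_id: int) -> int:
        idx = np.nonzero(self.node_id == node_id)[0]
        if len(idx) == 0:
            raise KeyError(f"node {node_id} not present in sampled tree")
        return int(idx[0])


def densify_centerline(tree: CenterlineTree, max_spacing: float) -> SampledTree:
    """Subdivide every edge so consecutive samples are <= ``max_spacing`` apart.

    Original nodes are preserved as samples and sample connectivity mirrors
    the tree topology.  Zero-length edges are skipped with a warning (the
    child node aliases its parent's sample).
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be > 0")
    if not tree.nodes:
        raise ValueError("empty centerline tree")
    tree.validate()

    order = _topological_order(tree)
    positions: list[np.ndarray] = []
    parent: list[int] = []
    artery: list[str] = []
    branch: list[str] = []
    node_id: list[int] = []
    node_sample: dict[int, int] = {}

    def add(pos, par, art, br, nid) -> int:
        positions.append(np.asarray(pos, dtype=float))
        parent.append(par)
        artery.append(art)
        branch.append(br)
        node_id.append(nid)
        return len(positions) - 1

    for n in order:
        if n.parent_id is None:
            node_sample[n.node_id] = add(n.position, -1, n.artery, n.branch, n.node_id)
            continue
        p = tree.node(n.parent_id)
        start = node_sample[p.node_id]
        edge = n.position - p.position
        length = float(np.linalg.norm(edge))
        if length == 0.0:
            warnings.warn(
                f"zero-length edge {p.node_id}->{n.node_id}: skipped", stacklevel=2
            )
            node_sample[n.node_id] = start
            continue
        nseg = max(1, math.ceil(length / max_spacing))
        prev = start
        for i in range(1, nseg):
            pos = p.position + edge * (i / nseg)
            prev = add(pos, prev, n.artery, n.branch, -1)
        node_sample[n.node_id] = add(n.position, prev, n.artery, n.branch, n.node_id)

    st = SampledTree(
        positions=np.vstack(positions),
        parent=np.asarray(parent, dtype=int),
        artery=np.asarray(artery, dtype=object),
        branch=np.asarray(branch, dtype=object),
        node_id=np.asarray(node_id, dtype=int),
        arc=np.zeros(len(positions)),
    )
    _fill_arc_lengths(st)
    return st


def _topological_order(tree: CenterlineTree) -> list[Node]:
    out: list[Node] = []
    ch = tree.children_map()
    stack = [r.node_id for r in tree.roots]
    while stack:
        nid = stack.pop()
        out.append(tree.node(nid))
        stack.extend(reversed(ch[nid]))
    return out

def _fill_arc_lengths(st: SampledTree) -> None:
    # parents precede children by construction, so one forward pass suffices
    for i in range(len(st)):
        p = int(st.parent[i])
        if p < 0 or st.branch[p] != st.branch[i]:
            st.arc[i] = 0.0
        else:
            st.arc[i] = st.arc[p] + float(
                np.linalg.norm(st.positions[i] - st.positions[p])
            )


def resolve_anchor(st: SampledTree, lesion: LesionPoint) -> int:
    """Map a lesion anchor to the single densified sample it denotes."""
    if isinstance(lesion.anchor, (int, np.integer)):
        s = st.sample_for_node(int(lesion.anchor))
        if st.artery[s] != lesion.artery:
            raise ValueError(
                f"node {lesion.anchor} belongs to {st.artery[s]}, not {lesion.artery}"
            )
        return s
    branch_label, arc_mm = lesion.anchor
    mask = (st.artery == lesion.artery) & (st.branch == branch_label)
    if not mask.any():
        raise ValueError(f"no branch {branch_label!r} in artery {lesion.artery}")
    idx = np.nonzero(mask)[0]
    arcs = st.arc[idx]
    if arc_mm > arcs.max():
        raise ValueError(
            f"arc {arc_mm} mm beyond branch {branch_label!r} length {arcs.max():.2f} mm"
        )
    at_or_distal = idx[arcs >= arc_mm]
    return int(at_or_distal[np.argmin(st.arc[at_or_distal])])


def distal_sample_set(st: SampledTree, lesion: LesionPoint) -> set[int]:
    """The lesion sample plus all samples downstream of it (away from the root)."""
    start = resolve_anchor(st, lesion)
    ch = st.children_map()
    out = set()
    stack = [start]
    while stack:
        s = stack.pop()
        if s in out:
            continue
        out.add(s)
        stack.extend(ch[s])
    return out
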
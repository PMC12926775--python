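"""Individualized ROI construction from W-score maps on a surface mesh.

Two masks drive the longitudinal analysis:

- the *core atrophy* ROI: connected clusters of vertices with W < -2,
  filtered by a minimum cluster size and an allowed-parcel rule that stands
  in (reproducibly) for manual anatomical curation;
- the *control* ROI: pre/postcentral (sensorimotor) vertices after removing
  any vertex with W < -0.25, a region expected to show minimal decline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from clusterscan.io import MeshGraph, ValidationError
from clusterscan.wscore import WScoreMap

DEFAULT_CONTROL_PARCELS = ("precentral", "postcentral")


@dataclass(frozen=True)
class ROIMask:
    """Named vertex set on a shared mesh with provenance of how it was built."""

    name: str
    vertices: frozenset[int]
    source: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "vertices", frozenset(int(v) for v in self.vertices))
        if not self.vertices:
            raise ValidationError(f"ROI mask '{self.name}' is empty")
        if any(v < 0 for v in self.vertices):
            raise ValidationError(f"ROI mask '{self.name}' has negative vertex index")

    def __len__(self) -> int:
        return len(self.vertices)

    def index_array(self) -> np.ndarray:
        return np.array(sorted(self.vertices), dtype=int)

    def validate_on(self, mesh: MeshGraph) -> None:
        if max(self.vertices) >= mesh.n_vertices:
            raise ValidationError(
                f"ROI mask '{self.name}' has vertex >= mesh size {mesh.n_vertices}")


def threshold_wmap(wmap: WScoreMap, threshold: float) -> frozenset[int]:
    """Vertices whose W-score is strictly below ``threshold``.

    NaN W-scores (degenerate units) never pass the threshold.
    """
    w = np.asarray(wmap.w, dtype=float)
    with np.errstate(invalid="ignore"):
        sel = np.flatnonzero(w < threshold)
    return frozenset(int(v) for v in sel)


def extract_clusters(vertexset, mesh: MeshGraph, min_size: int = 1,
                     allowed_parcels=None) -> list[ROIMask]:
    """Connected components of the thresholded vertex set on the mesh.

    Components are kept when they have at least ``min_size`` vertices and
    (if ``allowed_parcels`` is given) when their majority parcel is allowed.
    This rule replaces manual cluster curation; the criteria used are
    recorded in each mask's ``source``.  Clusters are returned largest
    first, ties broken by smallest vertex index.
    """
    vertexset = set(int(v) for v in vertexset)
    if vertexset and max(vertexset) >= mesh.n_vertices:
        raise ValidationError("vertex set not on mesh")
    g = nx.Graph()
    g.add_nodes_from(vertexset)
    e = mesh.edges
    if e.size:
        inset = np.array([a in vertexset and b in vertexset for a, b in e])
        g.add_edges_from(map(tuple, e[inset]))
    masks: list[ROIMask] = []
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            continue
        if allowed_parcels is not None:
            counts = Counter(mesh.parcel_of.get(v, "unknown") for v in comp)
            majority = counts.most_common(1)[0][0]
            if majority not in allowed_parcels:
                continue
        masks.append(ROIMask(
            name=f"cluster{len(masks)}",
            vertices=frozenset(comp),
            source={"rule": "connected-component", "min_size": min_size,
                    "allowed_parcels": list(allowed_parcels) if allowed_parcels else None,
                    "size": len(comp)}))
    masks.sort(key=lambda m: (-len(m), min(m.vertices)))
    return [ROIMask(name=f"cluster{i}", vertices=m.vertices, source=m.source)
            for i, m in enumerate(masks)]


def make_core_roi(wmap: WScoreMap, mesh: MeshGraph, threshold: float = -2.0,
                  min_size: int = 1, allowed_parcels=None) -> ROIMask:
    """Core atrophy ROI: union of retained W < threshold clusters."""
    clusters = extract_clusters(threshold_wmap(wmap, threshold), mesh,
                                min_size=min_size, allowed_parcels=allowed_parcels)
    if not clusters:
        raise ValidationError(
            f"no clusters survive W < {threshold} with min_size={min_size}")
    vertices = frozenset().union(*(c.vertices for c in clusters))
    return ROIMask(name="core", vertices=vertices,
                   source={"threshold": threshold, "min_size": min_size,
                           "allowed_parcels": list(allowed_parcels) if allowed_parcels else None,
                           "cluster_sizes": [len(c) for c in clusters]})


def make_control_roi(mesh: MeshGraph, wmap: WScoreMap,
                     parcels=DEFAULT_CONTROL_PARCELS,
                     exclusion: float = -0.25) -> ROIMask:
    """Control ROI: named parcels minus vertices with W strictly below ``exclusion``.

    A vertex with W exactly equal to the exclusion value is kept (the
    removal rule is a strict inequality).
    """
    missing = [p for p in parcels if p not in set(mesh.parcel_of.values())]
    if missing:
        raise ValidationError(f"parcel(s) not in parcellation: {missing}")
    w = np.asarray(wmap.w, dtype=float)
    keep = []
    for p in parcels:
        for v in mesh.parcel_vertices(p):
            if v >= len(w):
                raise ValidationError("W-score map does not cover the mesh")
            if np.isnan(w[v]):
                continue  # degenerate unit: no reliable W, leave it out
            if not (w[v] < exclusion):  # strict removal: W == exclusion is kept
                keep.append(int(v))
    if not keep:
        raise ValidationError(
            f"control ROI empty: all vertices of {list(parcels)} have W < {exclusion}")
    return ROIMask(name="control", vertices=frozenset(keep),
                   source={"parcels": list(parcels), "exclusion": exclusion})


def roi_mean_thickness(thickness_map: np.ndarray, mask: ROIMask,
                       vertex_areas: np.ndarray | None = None) -> float:
    """Mean thickness over the mask's vertices.

    Plain (unweighted) arithmetic mean by default; pass ``vertex_areas`` to
    get an area-weighted mean instead.
    """
    thickness_map = np.asarray(thickness_map, dtype=float)
    idx = mask.index_array()
    if idx.max() >= thickness_map.shape[-1]:
        raise ValidationError(
            f"mask '{mask.name}' extends beyond thickness map of size "
            f"{thickness_map.shape[-1]}")
    vals = thickness_map[..., idx]
    if vertex_areas is None:
        return float(vals.mean())
    w = np.asarray(vertex_areas, dtype=float)[idx]
    return float((vals * w).sum() / w.sum())
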
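"""Areal adjacency structures, study-area filtering and GAL/GeoJSON I/O.

The spatial support of the analysis is a set of areal units (suburbs) with a
symmetric, irreflexive neighbour structure.  Contiguity follows the queen
criterion (shared boundary *or* vertex); edges severed by a river running
through the study area can be restored with flagged supplementary edges
between near-facing units, mirroring how disease-mapping studies reconnect
units across estuaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.strtree import STRtree

__all__ = [
    "Adjacency",
    "ExclusionLog",
    "contiguity_adjacency",
    "add_supplementary_edges",
    "apply_study_area_filters",
    "read_gal",
    "write_gal",
    "read_geojson_polygons",
]

CONTIGUITY = "contiguity"
SUPPLEMENTARY = "supplementary"


class AdjacencyError(ValueError):
    """Raised for malformed neighbour structures."""


@dataclass
class Adjacency:
    """Symmetric, irreflexive neighbour lists over an ordered set of unit ids.

    Parameters
    ----------
    ids
        Ordered unique unit identifiers.
    neighbors
        Mapping id -> iterable of neighbouring ids.  Must be symmetric.
    edge_flags
        Optional mapping frozenset({i, j}) -> provenance flag
        (``"contiguity"`` or ``"supplementary"``).  Missing edges default to
        contiguity.
    """

    ids: list
    neighbors: dict
    edge_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise AdjacencyError("unit ids must be unique")
        known = set(self.ids)
        nbrs = {}
        for i in self.ids:
            nbrs[i] = sorted(set(self.neighbors.get(i, ())), key=str)
        self.neighbors = nbrs
        offending = []
        for i in self.ids:
            for j in self.neighbors[i]:
                if j == i:
                    raise AdjacencyError(f"unit {i!r} listed as its own neighbour")
                if j not in known:
                    raise AdjacencyError(f"neighbour {j!r} of {i!r} is not a unit")
                if i not in self.neighbors[j]:
                    offending.append((i, j))
        if offending:
            raise AdjacencyError(f"asymmetric adjacency; offending pairs: {offending}")

    # -- basic queries -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def degree(self, i) -> int:
        return len(self.neighbors[i])

    def edges(self) -> list[frozenset]:
        seen = set()
        for i in self.ids:
            for j in self.neighbors[i]:
                seen.add(frozenset((i, j)))
        return sorted(seen, key=lambda e: tuple(sorted(map(str, e))))

    def edge_flag(self, i, j) -> str:
        return self.edge_flags.get(frozenset((i, j)), CONTIGUITY)

    def to_sparse(self) -> sp.csr_matrix:
        """Binary symmetric weights matrix in the stored id order."""
        index = {u: k for k, u in enumerate(self.ids)}
        rows, cols = [], []
        for i in self.ids:
            for j in self.neighbors[i]:
                rows.append(index[i])
                cols.append(index[j])
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        for e in self.edges():
            i, j = tuple(e)
            g.add_edge(i, j)
        return g

    def connected_components(self) -> list[list]:
        comps = nx.connected_components(self.to_graph())
        return [sorted(c, key=str) for c in comps]

    def islands(self) -> list:
        return [i for i in self.ids if not self.neighbors[i]]

    def restrict(self, keep: Iterable) -> "Adjacency":
        """Subset to ``keep``; never creates edges, only drops them."""
        keep_set = set(keep)
        ids = [i for i in self.ids if i in keep_set]
        nbrs = {i: [j for j in self.neighbors[i] if j in keep_set] for i in ids}
        flags = {e: f for e, f in self.edge_flags.items() if e <= keep_set}
        return Adjacency(ids, nbrs, flags)

    def with_edge(self, i, j, flag: str = CONTIGUITY) -> "Adjacency":
        nbrs = {k: list(v) for k, v in self.neighbors.items()}
        if j not in nbrs[i]:
            nbrs[i].append(j)
            nbrs[j].append(i)
        flags = dict(self.edge_flags)
        flags[frozenset((i, j))] = flag
        return Adjacency(self.ids, nbrs, flags)


# ---------------------------------------------------------------------------
# Contiguity construction
# ---------------------------------------------------------------------------

def contiguity_adjacency(geography) -> Adjacency:
    """Queen contiguity (shared boundary or vertex) from unit footprints.

    A river gap built into the geography separates footprints physically, so
    cross-river pairs are simply not contiguous and need supplementary edges.
    """
    ids = list(geography.ids)
    polys = [geography.footprint(i) for i in ids]
    for i, p in zip(ids, polys):
        if p is None or p.is_empty or p.area <= 0:
            raise AdjacencyError(f"degenerate footprint for unit {i!r}")
    tree = STRtree(polys)
    nbrs: dict = {i: [] for i in ids}
    for a, poly in enumerate(polys):
        for b in tree.query(poly):
            b = int(b)
            if b <= a:
                continue
            # queen: any shared point (boundary segment or single vertex)
            if polys[a].intersects(polys[b]):
                nbrs[ids[a]].append(ids[b])
                nbrs[ids[b]].append(ids[a])
    return Adjacency(ids, nbrs)


def add_supplementary_edges(adjacency: Adjacency, geography,
                            max_distance: float) -> Adjacency:
    """Join unit pairs facing each other across the river when their
    footprints are less than ``max_distance`` apart.

    Mirrors the practice of supplementing a contiguity matrix across an
    estuary so the spatial prior does not treat the two banks as independent.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    river = getattr(geography, "river", None)
    if river is None or max_distance == 0:
        return adjacency
    out = adjacency
    ids = list(adjacency.ids)
    for a_idx, i in enumerate(ids):
        pi = geography.footprint(i)
        for j in ids[a_idx + 1:]:
            if j in out.neighbors[i]:
                continue
            pj = geography.footprint(j)
            # only pairs on opposite banks qualify
            if not _crosses_river(pi, pj, river):
                continue
            if pi.distance(pj) < max_distance:
                out = out.with_edge(i, j, SUPPLEMENTARY)
    return out


def _crosses_river(pi, pj, river) -> bool:
    from shapely.geometry import LineString

    seg = LineString([pi.centroid, pj.centroid])
    return seg.intersects(river)


# ---------------------------------------------------------------------------
# Study-area filtering
# ---------------------------------------------------------------------------

OUTSIDE_AREA = "outside-area"
ZERO_BIRTHS = "zero-births-in-a-period"
MISSING_SES = "missing-ses"
RETAINED = "retained"
_REASON_ORDER = (OUTSIDE_AREA, ZERO_BIRTHS, MISSING_SES)


@dataclass
class ExclusionLog:
    """Per-unit exclusion reason plus counts; reasons partition the input."""

    reasons: pd.Series  # index: unit id, values: reason strings
    counts: dict

    def __post_init__(self) -> None:
        if int(sum(self.counts.values())) != len(self.reasons):
            raise ValueError("exclusion counts must sum to the input size")

    def retained_ids(self) -> list:
        return list(self.reasons.index[self.reasons == RETAINED])

    def to_frame(self) -> pd.DataFrame:
        return self.reasons.rename("reason").rename_axis("suburb_id").reset_index()


class EmptyStudyAreaError(RuntimeError):
    pass


def apply_study_area_filters(suburbs_by_period: Mapping[str, pd.DataFrame],
                             area_flags: pd.DataFrame,
                             adjacency: Adjacency | None = None):
    """Apply the three study-area exclusion rules, in fixed precedence.

    Rules, applied in order (a unit is logged under the first that fires):
      1. more than 50% of the unit's area outside the urban area;
      2. zero births in at least one study period;
      3. socioeconomic index unavailable.

    Parameters
    ----------
    suburbs_by_period
        period label -> DataFrame with columns ``suburb_id`` and ``births``.
    area_flags
        DataFrame with ``suburb_id``, ``frac_outside_urban`` (in [0, 1]) and
        boolean ``ses_available``.
    adjacency
        If given, returned restricted to the retained units.

    Returns
    -------
    (filtered_tables, log[, restricted_adjacency])
    """
    flags = area_flags.set_index("suburb_id")
    all_ids = list(flags.index)
    births = {}
    for period, tab in suburbs_by_period.items():
        b = tab.set_index("suburb_id")["births"]
        births[period] = b.reindex(all_ids).fillna(0)

    reasons = {}
    for i in all_ids:
        if flags.loc[i, "frac_outside_urban"] > 0.5:
            reasons[i] = OUTSIDE_AREA
        elif any(births[p].loc[i] == 0 for p in births):
            reasons[i] = ZERO_BIRTHS
        elif not bool(flags.loc[i, "ses_available"]):
            reasons[i] = MISSING_SES
        else:
            reasons[i] = RETAINED
    reasons = pd.Series(reasons).reindex(all_ids)
    counts = {r: int((reasons == r).sum()) for r in (*_REASON_ORDER, RETAINED)}
    log = ExclusionLog(reasons, counts)
    keep = log.retained_ids()
    if not keep:
        raise EmptyStudyAreaError("no units retained after study-area filters")
    filtered = {
        p: tab[tab["suburb_id"].isin(keep)].reset_index(drop=True)
        for p, tab in suburbs_by_period.items()
    }
    if adjacency is not None:
        return filtered, log, adjacency.restrict(keep)
    return filtered, log


# ---------------------------------------------------------------------------
# GAL I/O
# ---------------------------------------------------------------------------

def write_gal(adjacency: Adjacency, path) -> None:
    """Plain-text GAL: count header, then per unit an ``id n`` line followed
    by the line of neighbour ids."""
    lines = [str(adjacency.n)]
    for i in adjacency.ids:
        ns = adjacency.neighbors[i]
        lines.append(f"{i} {len(ns)}")
        lines.append(" ".join(str(j) for j in ns))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gal(path) -> Adjacency:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    tokens = [t for t in (s.strip() for s in tokens)]
    n = int(tokens[0].split()[0])
    ids, nbrs = [], {}
    pos = 1
    for _ in range(n):
        head = tokens[pos].split()
        pos += 1
        uid, k = head[0], int(head[1])
        neigh = tokens[pos].split() if k > 0 else []
        pos += 1
        if len(neigh) != k:
            raise AdjacencyError(
                f"unit {uid}: declared {k} neighbours, found {len(neigh)}")
        ids.append(uid)
        nbrs[uid] = neigh
    return Adjacency(ids, nbrs)  # __post_init__ validates symmetry


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def read_geojson_polygons(path):
    """Read a FeatureCollection of unit polygons; returns (ids, shapely polys)."""
    with open(path) as fh:
        gj = json.load(fh)
    ids, polys = [], []
    for feat in gj["features"]:
        ids.append(feat["properties"]["suburb_id"])
        polys.append(shapely_shape(feat["geometry"]))
    return ids, polys


def write_geojson_polygons(ids: Sequence, polys: Sequence, path,
                           properties: pd.DataFrame | None = None) -> None:
    props = {}
    if properties is not None:
        props = properties.set_index("suburb_id").to_dict("index")
    feats = []
    for i, p in zip(ids, polys):
        extra = {k: (v.item() if hasattr(v, "item") else v)
                 for k, v in props.get(i, {}).items()}
        feats.append({
            "type": "Feature",
            "properties": {"suburb_id": i, **extra},
            "geometry": shapely_mapping(p),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
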
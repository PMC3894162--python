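"""Signed food-disease network assembly, temporal trends, and export.

An edge of the network is a (food, disease, sign) triple supported by a
count of distinct publications (abstracts).  Filtering applies the support
threshold first and per-disease top-k truncation second; opposite-sign edges
between the same pair coexist and are never netted out here — only the
temporal trend subtracts negative from positive publication counts per year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .relation_classifier import SignedEdge

__all__ = [
    "NetworkEdge",
    "FoodDiseaseNetwork",
    "TrendSeries",
    "build_network",
    "temporal_trend",
    "export_network",
    "read_network",
]

FORMATS = ("sif", "graphml", "tsv")
_SIF_SIGN = {"positive": "pos", "negative": "neg"}
_SIGN_SIF = {v: k for k, v in _SIF_SIGN.items()}


@dataclass(frozen=True)
class NetworkEdge:
    food_id: str
    disease_id: str
    sign: str
    support: int


@dataclass
class FoodDiseaseNetwork:
    edges: list[NetworkEdge]
    min_support: int = 1
    top_k: int | None = None

    def foods(self) -> set[str]:
        return {e.food_id for e in self.edges}

    def diseases(self) -> set[str]:
        return {e.disease_id for e in self.edges}

    def __eq__(self, other) -> bool:
        if not isinstance(other, FoodDiseaseNetwork):
            return NotImplemented
        return sorted(self.edges, key=_edge_key) == \
            sorted(other.edges, key=_edge_key)


def _edge_key(e: NetworkEdge):
    return (e.disease_id, e.food_id, e.sign)


@dataclass(frozen=True)
class TrendSeries:
    entity_id: str
    #: year -> (#positive publications - #negative publications)
    values: tuple[tuple[int, int], ...]

    def as_dict(self) -> dict[int, int]:
        return dict(self.values)


def build_network(signed_edges: Iterable[SignedEdge], min_support: int = 5,
                  top_k: int = 5, edible: set[str] | None = None,
                  species_of: dict[str, str] | None = None,
                  ) -> FoodDiseaseNetwork:
    """Aggregate abstract-level signed edges into the food-disease network.

    Support counts distinct abstracts per (food, disease, sign).  Foods are
    restricted to the ``edible`` set when given; ``species_of`` optionally
    collapses variety-level plant ids to their species before counting.
    Filtering order: support threshold first, then per-disease truncation to
    the ``top_k`` strongest edges (ties broken by food id).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    support: dict[tuple[str, str, str], set[str]] = {}
    for e in signed_edges:
        food = e.plant_id
        if species_of is not None:
            food = species_of.get(food, food)
        if edible is not None and food not in edible:
            continue
        support.setdefault((food, e.disease_id, e.sign), set()) \
            .add(e.abstract_id)

    qualified = [NetworkEdge(f, d, s, len(a))
                 for (f, d, s), a in sorted(support.items())
                 if len(a) >= min_support]
    by_disease: dict[str, list[NetworkEdge]] = {}
    for e in qualified:
        by_disease.setdefault(e.disease_id, []).append(e)
    kept: list[NetworkEdge] = []
    for d in sorted(by_disease):
        ranked = sorted(by_disease[d],
                        key=lambda e: (-e.support, e.food_id, e.sign))
        kept.extend(ranked[:top_k])
    kept.sort(key=_edge_key)
    return FoodDiseaseNetwork(kept, min_support=min_support, top_k=top_k)


def temporal_trend(signed_edges: Iterable[SignedEdge],
                   entity_id: str) -> TrendSeries:
    """Positive-minus-negative distinct publication counts per year for one
    food or disease; years without publications are omitted."""
    pos: dict[int, set[str]] = {}
    neg: dict[int, set[str]] = {}
    seen = False
    for e in signed_edges:
        if entity_id not in (e.plant_id, e.disease_id):
            continue
        seen = True
        bucket = pos if e.sign == "positive" else neg
        bucket.setdefault(e.year, set()).add(e.abstract_id)
    if not seen:
        raise KeyError(f"entity {entity_id!r} has no signed edges")
    years = sorted(set(pos) | set(neg))
    values = tuple((y, len(pos.get(y, set())) - len(neg.get(y, set())))
                   for y in years)
    return TrendSeries(entity_id, values)


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def export_network(net: FoodDiseaseNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as Cytoscape-readable SIF, GraphML, or an edge TSV.

    SIF encodes topology and sign only (``food pos|neg disease``); GraphML
    and TSV also carry the support attribute, so their round trip through
    :func:`read_network` reconstructs the network exactly.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        lines = [f"{e.food_id} {_SIF_SIGN[e.sign]} {e.disease_id}"
                 for e in sorted(net.edges, key=_edge_key)]
        path.write_text("".join(line + "\n" for line in lines))
    elif fmt == "graphml":
        g = nx.MultiDiGraph()
        for e in net.edges:
            g.add_node(e.food_id, kind="food")
            g.add_node(e.disease_id, kind="disease")
            g.add_edge(e.food_id, e.disease_id, key=e.sign,
                       sign=e.sign, support=e.support)
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        lines = ["food_id\tdisease_id\tsign\tsupport"]
        lines += [f"{e.food_id}\t{e.disease_id}\t{e.sign}\t{e.support}"
                  for e in sorted(net.edges, key=_edge_key)]
        path.write_text("".join(line + "\n" for line in lines))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_network(fmt: str, path: str | Path) -> FoodDiseaseNetwork:
    """Read a network previously written by :func:`export_network`.

    SIF carries no support attribute; edges read from SIF get support 0.
    """
    fmt = fmt.lower()
    path = Path(path)
    edges: list[NetworkEdge] = []
    if fmt == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            food, rel, disease = line.split()
            edges.append(NetworkEdge(food, disease, _SIGN_SIF[rel], 0))
    elif fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        for u, v, k, data in g.edges(keys=True, data=True):
            edges.append(NetworkEdge(u, v, data["sign"],
                                     int(data["support"])))
    elif fmt == "tsv":
        lines = path.read_text().splitlines()
        for line in lines[1:]:
            food, disease, sign, support = line.split("\t")
            edges.append(NetworkEdge(food, disease, sign, int(support)))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    edges.sort(key=_edge_key)
    return FoodDiseaseNetwork(edges)
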
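"""Fisher-exact association of compounds with diseases, FDR control, and
taxonomy overrepresentation.

The association unit is the plant: for a compound c and a disease d (one
direction at a time), the 2x2 table counts plants of the common universe by
containment of c and by linkage to d, and the one-sided (greater)
hypergeometric tail asks whether the proportion of plants with the compound
is higher among plants linked to the disease.  P-values are computed from
exact integer binomial coefficients, converted from a rational to a float at
the very end, so no approximation error enters the tail sum.

The positive (preventive) and negative (promoting) directions form separate
Benjamini-Hochberg families; tables with zero overlap (a = 0) can never be
significant and are excluded from the tested family, which reduces m.

Taxonomy overrepresentation works on genus-level units after projecting each
node's compound content upward through the tree (each node's set becomes the
union of its own and its descendants').
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

from .corpus_synthesis import Taxonomy
from .relation_classifier import ContentEdge, SignedEdge

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "EnrichmentResult",
    "build_contingency",
    "fisher_exact_greater",
    "benjamini_hochberg",
    "associate_compounds_to_diseases",
    "project_taxonomy_content",
    "taxonomy_enrichment_all",
    "taxonomy_enrichment",
    "conserved_compounds",
]

DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts over a plant universe: a = with compound AND disease,
    b = compound only, c = disease only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    compound_id: str
    disease_id: str
    direction: str
    table: ContingencyTable2x2
    p: float
    rank: int
    significant: bool


@dataclass(frozen=True)
class EnrichmentResult:
    compound_id: str
    node_id: str
    table: ContingencyTable2x2
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def build_contingency(compound_plants: set, disease_plants: set,
                      universe: set) -> ContingencyTable2x2:
    if not compound_plants <= universe or not disease_plants <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(compound_plants & disease_plants)
    b = len(compound_plants - disease_plants)
    c = len(disease_plants - compound_plants)
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_greater(t: ContingencyTable2x2) -> float:
    """One-sided ("greater") Fisher exact p-value.

    Exact hypergeometric tail over the feasible overlap values k >= a with
    the table's margins fixed, evaluated in integer arithmetic and converted
    to float once.
    """
    row1, row2, col1 = t.a + t.b, t.c + t.d, t.a + t.c
    hi = min(row1, col1)
    num = sum(comb(row1, k) * comb(row2, col1 - k)
              for k in range(t.a, hi + 1))
    denom = comb(t.n, col1)
    if denom == 0:  # empty universe: degenerate, whole tail
        return 1.0
    return float(Fraction(num, denom))


def benjamini_hochberg(pvals: Sequence[float], q: float = 0.05) -> list[bool]:
    """Step-up BH rejection flags, returned in input order."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValueError("p-values must be in (0, 1]")
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            k_max = rank
    flags = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_max:
            flags[i] = True
    return flags


# ---------------------------------------------------------------------------
# compound-disease association
# ---------------------------------------------------------------------------

def associate_compounds_to_diseases(
        content_edges: Iterable[ContentEdge | tuple],
        signed_edges: Iterable[SignedEdge | tuple],
        q: float = 0.05) -> list[AssociationResult]:
    """Fisher association of every (compound, disease, direction) with
    overlap, BH-corrected per direction.

    The plant universe is the set of plants appearing in *both* edge lists
    (plants with both phytochemical and disease annotation).  Edge inputs may
    be dataclasses or bare tuples ``(plant_id, compound_id, ...)`` /
    ``(plant_id, disease_id, direction/sign, ...)``.
    """
    compound_plants: dict[str, set[str]] = {}
    content_universe: set[str] = set()
    for e in content_edges:
        plant, compound = (e.plant_id, e.compound_id) \
            if isinstance(e, ContentEdge) else (e[0], e[1])
        content_universe.add(plant)
        compound_plants.setdefault(compound, set()).add(plant)

    disease_plants: dict[tuple[str, str], set[str]] = {}
    disease_universe: set[str] = set()
    for e in signed_edges:
        plant, disease, sign = (e.plant_id, e.disease_id, e.sign) \
            if isinstance(e, SignedEdge) else (e[0], e[1], e[2])
        if sign not in DIRECTIONS:
            raise ValueError(f"unknown direction {sign!r}")
        disease_universe.add(plant)
        disease_plants.setdefault((disease, sign), set()).add(plant)

    universe = content_universe & disease_universe
    if not universe:
        raise ValueError("empty plant universe (no plant has both "
                         "compound and disease annotation)")

    results: list[AssociationResult] = []
    for direction in DIRECTIONS:
        family: list[tuple[str, str, ContingencyTable2x2, float]] = []
        for (disease, sign), dplants in sorted(disease_plants.items()):
            if sign != direction:
                continue
            dset = dplants & universe
            if not dset:
                continue
            for compound, cplants in sorted(compound_plants.items()):
                table = build_contingency(cplants & universe, dset, universe)
                if table.a == 0:
                    continue  # can never be significant; keep family small
                family.append((compound, disease, table,
                               fisher_exact_greater(table)))
        flags = benjamini_hochberg([p for (_, _, _, p) in family], q) \
            if family else []
        ranks = sorted(range(len(family)), key=lambda i: family[i][3])
        rank_of = {i: r + 1 for r, i in enumerate(ranks)}
        for i, (compound, disease, table, p) in enumerate(family):
            results.append(AssociationResult(
                compound_id=compound, disease_id=disease,
                direction=direction, table=table, p=p,
                rank=rank_of[i], significant=flags[i]))
    return results


# ---------------------------------------------------------------------------
# taxonomy overrepresentation
# ---------------------------------------------------------------------------

def project_taxonomy_content(tax: Taxonomy) -> Taxonomy:
    """Return a taxonomy whose node content is the union of each node's own
    and all its descendants' content; idempotent, leaves unchanged."""
    projected = {nid: set(tax.content.get(nid, set())) for nid
                 in (n.node_id for n in tax.nodes)}

    def visit(nid: str) -> set[str]:
        acc = projected[nid]
        for child in tax.children(nid):
            acc |= visit(child)
        return acc

    for root in tax.roots():
        visit(root)
    return Taxonomy(list(tax.nodes), projected,
                    localized_compounds=tax.localized_compounds)


def _genus_units(tax_projected: Taxonomy) -> dict[str, set[str]]:
    """genus_id -> projected compound content; genera are the sampling
    units of the overrepresentation test."""
    return {g: set(tax_projected.content[g])
            for g in tax_projected.nodes_at_rank("genus")}


def taxonomy_enrichment_all(tax_projected: Taxonomy, q: float = 0.05,
                            ) -> list[EnrichmentResult]:
    """Overrepresentation of every compound on every internal node.

    For node v and compound c the table counts genera: inside v's subtree
    with c, outside with c, inside without, outside without; a one-sided
    greater test asks whether c concentrates in the subtree.  BH is applied
    across the whole (compound, node) family; zero-overlap pairs are skipped.
    """
    units = _genus_units(tax_projected)
    all_genera = set(units)
    compounds = sorted(set().union(*units.values()) if units else set())
    genera_with: dict[str, set[str]] = {
        c: {g for g, content in units.items() if c in content}
        for c in compounds
    }
    tests: list[tuple[str, str, ContingencyTable2x2, float]] = []
    for node in tax_projected.nodes:
        if node.rank == "species":
            continue
        subtree_genera = {g for g in tax_projected.subtree(node.node_id)
                          if g in all_genera}
        if not subtree_genera:
            continue
        for c in compounds:
            # orientation: a = genera in subtree with compound
            table = ContingencyTable2x2(
                a=len(genera_with[c] & subtree_genera),
                b=len(genera_with[c] - subtree_genera),
                c=len(subtree_genera - genera_with[c]),
                d=len(all_genera - subtree_genera - genera_with[c]),
            )
            if table.a == 0:
                continue
            tests.append((c, node.node_id, table,
                          fisher_exact_greater(table)))
    flags = benjamini_hochberg([p for (_, _, _, p) in tests], q) \
        if tests else []
    return [EnrichmentResult(c, nid, table, p, flag)
            for (c, nid, table, p), flag in zip(tests, flags)]


def taxonomy_enrichment(tax_projected: Taxonomy, compound_id: str,
                        node_id: str, q: float = 0.05) -> EnrichmentResult:
    """Result for one (compound, node) pair, with BH computed over the full
    family of tests on this taxonomy."""
    tax_projected.node(node_id)  # raises KeyError on unknown node
    units = _genus_units(tax_projected)
    known = set().union(*units.values()) if units else set()
    if compound_id not in known:
        raise KeyError(f"unknown compound {compound_id!r}")
    for r in taxonomy_enrichment_all(tax_projected, q):
        if r.compound_id == compound_id and r.node_id == node_id:
            return r
    # zero overlap: the pair was excluded from the family
    subtree_genera = {g for g in tax_projected.subtree(node_id) if g in units}
    table = ContingencyTable2x2(0, len({g for g in units
                                        if compound_id in units[g]}),
                                len(subtree_genera),
                                len(units) - len(subtree_genera)
                                - len({g for g in units
                                       if compound_id in units[g]}))
    return EnrichmentResult(compound_id, node_id, table, 1.0, False)


def conserved_compounds(tax_projected: Taxonomy,
                        enrichment: Iterable[EnrichmentResult],
                        parent_id: str, child_id: str) -> set[str]:
    """Compounds significantly overrepresented on both parent and child."""
    child = tax_projected.node(child_id)
    if child.parent_id != parent_id:
        raise ValueError(f"{child_id!r} is not a child of {parent_id!r}")
    sig: dict[str, set[str]] = {}
    for r in enrichment:
        if r.significant:
            sig.setdefault(r.node_id, set()).add(r.compound_id)
    return sig.get(parent_id, set()) & sig.get(child_id, set())
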
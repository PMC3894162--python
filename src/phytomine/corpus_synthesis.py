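"""Synthetic corpora and chemogenomic fixtures with planted ground truth.

Real runs of the pipeline would consume millions of MEDLINE abstracts together
with curated plant/compound/disease dictionaries, a species taxonomy, and
compound-protein / protein-disease reference tables.  None of those resources
can ship with a test suite, so this module fabricates miniature stand-ins that
preserve exactly the statistical structure the downstream analysis assumes:

* entity dictionaries whose surface forms are drawn from disjoint alphabets,
  so no string is ambiguous between classes;
* a ranked taxonomy (class > order > family > genus > species) in which a
  configurable fraction of compounds is *localized* (confined to one genus)
  while the rest is dispersed over the whole tree;
* templated abstracts in which relation cue words ("contains", "prevents",
  "promotes") surround co-mentioned entity pairs, with a tunable rate of
  off-lexicon noise words replacing cues;
* a plant universe in which selected compound-disease pairs are planted at a
  configured enrichment odds ratio, so Fisher-test power is controllable;
* an activity table wired so configured fractions of compounds are directly
  tested, similar (Tanimoto) to a tested reference, or unexplored.

Everything is deterministic given (config, seed); serialization of the same
bundle twice is byte-identical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, prod

__all__ = [
    "RANKS",
    "CUE_LEXICONS",
    "FILLER_LEXICON",
    "DictEntry",
    "EntityDictionary",
    "TaxonNode",
    "Taxonomy",
    "SyntheticAbstract",
    "ActivityRecord",
    "CorpusConfig",
    "FixtureBundle",
    "generate_dictionaries",
    "generate_taxonomy",
    "generate_abstract",
    "generate_corpus",
    "generate_eval_corpus",
    "generate_survey_corpus",
]

RANKS = ("class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

RELATIONS = ("contains", "prevents", "promotes", "none")

#: Cue lexicons for the three informative relations.  Pairwise disjoint; the
#: classifier's separability ceiling at noise_rate=0 rests on that.
CUE_LEXICONS = {
    "contains": (
        "contains", "isolated", "extract", "purified", "constituent",
        "compound", "concentrated",
    ),
    "prevents": (
        "prevents", "protective", "ameliorates", "inhibits", "suppresses",
        "chemopreventive", "beneficial",
    ),
    "promotes": (
        "promotes", "aggravates", "exacerbates", "induces", "worsens",
        "carcinogenic", "hypersensitivity",
    ),
}

#: Neutral words used for unrelated context and for injected noise.  Disjoint
#: from every cue lexicon.
FILLER_LEXICON = (
    "study", "observed", "samples", "methods", "cohort", "overall",
)

_RESERVED_WORDS = frozenset(
    w for lex in CUE_LEXICONS.values() for w in lex
) | frozenset(FILLER_LEXICON)

# Disjoint consonant alphabets guarantee that no generated surface string can
# belong to two entity classes.
_CLASS_CONSONANTS = {"plant": "bdfg", "compound": "klmn", "disease": "prst"}
_VOWELS = "aeiou"
_CLASS_PREFIX = {"plant": "PL", "compound": "CP", "disease": "DS"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DictEntry:
    entity_id: str
    canonical_name: str
    synonyms: tuple[str, ...]
    entity_class: str

    def names(self) -> tuple[str, ...]:
        return (self.canonical_name, *self.synonyms)


@dataclass(frozen=True)
class EntityDictionary:
    """A controlled vocabulary for one entity class."""

    entity_class: str
    entries: tuple[DictEntry, ...]

    def __post_init__(self):
        ids = [e.entity_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate entity_id in dictionary")
        for e in self.entries:
            names = [n.lower() for n in e.names()]
            if any(not n for n in names):
                raise ValueError(f"empty name in entry {e.entity_id}")
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate names within entry {e.entity_id}")
            if e.entity_class != self.entity_class:
                raise ValueError("entry class does not match dictionary class")

    def __len__(self) -> int:
        return len(self.entries)

    def by_id(self, entity_id: str) -> DictEntry:
        for e in self.entries:
            if e.entity_id == entity_id:
                return e
        raise KeyError(entity_id)


@dataclass(frozen=True)
class TaxonNode:
    node_id: str
    rank: str
    parent_id: str | None


@dataclass
class Taxonomy:
    """A ranked forest with per-node compound content.

    ``content`` maps node_id to the set of compound ids recorded *at* that
    node; projection of descendant content upward is a separate analysis step.
    """

    nodes: list[TaxonNode]
    content: dict[str, set[str]] = field(default_factory=dict)
    #: bookkeeping: which compounds were planted as taxonomically localized
    localized_compounds: frozenset[str] = frozenset()

    def __post_init__(self):
        self._by_id = {n.node_id: n for n in self.nodes}
        if len(self._by_id) != len(self.nodes):
            raise ValueError("duplicate node_id")
        self._children: dict[str, list[str]] = {n.node_id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                parent = self._by_id.get(n.parent_id)
                if parent is None:
                    raise ValueError(f"missing parent {n.parent_id}")
                if _RANK_INDEX[parent.rank] >= _RANK_INDEX[n.rank]:
                    raise ValueError(
                        f"rank of {n.node_id} not below its parent's"
                    )
                self._children[n.parent_id].append(n.node_id)
        # cycle check doubles as reachability check
        seen: set[str] = set()
        stack = [n.node_id for n in self.nodes if n.parent_id is None]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError("cycle in taxonomy")
            seen.add(nid)
            stack.extend(self._children[nid])
        if seen != set(self._by_id):
            raise ValueError("cycle in taxonomy (unreachable nodes)")

    def node(self, node_id: str) -> TaxonNode:
        return self._by_id[node_id]

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def roots(self) -> list[str]:
        return [n.node_id for n in self.nodes if n.parent_id is None]

    def subtree(self, node_id: str) -> list[str]:
        """Node ids of the subtree rooted at ``node_id`` (inclusive)."""
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self._children[nid])
        return out

    def nodes_at_rank(self, rank: str) -> list[str]:
        return [n.node_id for n in self.nodes if n.rank == rank]

    def leaves(self) -> list[str]:
        return [n.node_id for n in self.nodes if not self._children[n.node_id]]


@dataclass(frozen=True)
class SyntheticAbstract:
    abstract_id: str
    year: int
    text: str
    #: (entity_id_a, entity_id_b, relation) triples; relation "none" marks a
    #: co-mention with no informative context.
    truth: tuple[tuple[str, str, str], ...]


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental compound-protein activity assertion.

    ``structure`` is a canonical structure string used as the join key against
    the mined phytochemical list.
    """

    structure: str
    protein_id: str
    note: str = ""


# ---------------------------------------------------------------------------
# dictionaries
# ---------------------------------------------------------------------------

def _make_word(rng: random.Random, consonants: str, n_syllables: int) -> str:
    return "".join(
        rng.choice(consonants) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _make_name(rng: random.Random, consonants: str, used: set[str],
               multi_token: bool) -> str:
    for _ in range(10000):
        n_words = 2 if multi_token else 1
        name = " ".join(
            _make_word(rng, consonants, rng.randint(2, 4)) for _ in range(n_words)
        )
        if name not in used and name not in _RESERVED_WORDS:
            used.add(name)
            return name
    raise RuntimeError("name space exhausted")  # pragma: no cover


def generate_dictionaries(n_plants: int, n_compounds: int, n_diseases: int,
                          synonyms_per_entity: int = 1, seed: int = 0,
                          ) -> dict[str, EntityDictionary]:
    """Deterministically generate the three entity dictionaries.

    Surface forms for the three classes come from disjoint consonant
    alphabets, so no string is shared between classes.  Every third canonical
    name is two tokens long, which forces longest-match logic in tagging.
    """
    counts = {"plant": n_plants, "compound": n_compounds, "disease": n_diseases}
    if min(counts.values()) < 1:
        raise ValueError("entity counts must be >= 1")
    if synonyms_per_entity < 0:
        raise ValueError("synonyms_per_entity must be >= 0")
    rng = random.Random(seed)
    used: set[str] = set()
    out: dict[str, EntityDictionary] = {}
    for cls in ("plant", "compound", "disease"):
        consonants = _CLASS_CONSONANTS[cls]
        entries = []
        for i in range(counts[cls]):
            canonical = _make_name(rng, consonants, used, multi_token=i % 3 == 0)
            synonyms = tuple(
                _make_name(rng, consonants, used,
                           multi_token=(i + j) % 5 == 0)
                for j in range(synonyms_per_entity)
            )
            entries.append(DictEntry(
                entity_id=f"{_CLASS_PREFIX[cls]}{i + 1:04d}",
                canonical_name=canonical,
                synonyms=synonyms,
                entity_class=cls,
            ))
        out[cls] = EntityDictionary(cls, tuple(entries))
    return out


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def generate_taxonomy(shape: tuple[int, ...],
                      compound_ids: tuple[str, ...] = (),
                      localized_fraction: float = 0.0,
                      seed: int = 0,
                      species_ids: tuple[str, ...] | None = None) -> Taxonomy:
    """Build a ranked forest and assign compound content to species leaves.

    ``shape`` gives the branching factor at each of the five ranks, root level
    first: ``shape[0]`` class-rank roots, each with ``shape[1]`` orders, and
    so on down to species.  A ``localized_fraction`` of the compounds is
    confined to the species of a single genus; the remainder is dispersed over
    leaves sampled across the whole forest (never within a single genus when
    the forest allows it).
    """
    if len(shape) != len(RANKS):
        raise ValueError(f"shape must have {len(RANKS)} entries")
    if any(b < 1 for b in shape):
        raise ValueError("branching factors must be >= 1")
    if not 0.0 <= localized_fraction <= 1.0:
        raise ValueError("localized_fraction must be in [0, 1]")

    n_species = prod(shape)
    if species_ids is not None and len(species_ids) != n_species:
        raise ValueError("species_ids length must equal the species count")

    rng = random.Random(seed)
    nodes: list[TaxonNode] = []
    level: list[str] = []
    counter = 0
    species_counter = 0
    for depth, (rank, width) in enumerate(zip(RANKS, shape)):
        parents = level if depth else [None]
        level = []
        for parent in parents:
            for _ in range(width):
                if rank == "species" and species_ids is not None:
                    nid = species_ids[species_counter]
                    species_counter += 1
                else:
                    counter += 1
                    nid = f"{rank[:2].upper()}{counter:04d}"
                nodes.append(TaxonNode(nid, rank, parent))
                level.append(nid)

    tax = Taxonomy(nodes, {n.node_id: set() for n in nodes})

    genera = tax.nodes_at_rank("genus")
    leaves = tax.leaves()
    compounds = list(compound_ids)
    n_localized = round(localized_fraction * len(compounds))
    order = list(range(len(compounds)))
    rng.shuffle(order)
    localized_idx = set(order[:n_localized])
    localized: set[str] = set()
    for i, cid in enumerate(compounds):
        if i in localized_idx:
            genus = rng.choice(genera)
            members = [n for n in tax.subtree(genus)
                       if tax.node(n).rank == "species"]
            chosen = [s for s in members if rng.random() < 0.9]
            if not chosen:
                chosen = [rng.choice(members)]
            localized.add(cid)
        else:
            chosen = _sample_dispersed(rng, tax, leaves, genera)
        for s in chosen:
            tax.content[s].add(cid)
    tax.localized_compounds = frozenset(localized)
    return tax


def _sample_dispersed(rng: random.Random, tax: Taxonomy, leaves: list[str],
                      genera: list[str], prevalence: float = 0.3) -> list[str]:
    """Sample a leaf set that spans more than one genus whenever possible."""
    genus_of = {}
    for g in genera:
        for n in tax.subtree(g):
            if tax.node(n).rank == "species":
                genus_of[n] = g
    for _ in range(100):
        chosen = [s for s in leaves if rng.random() < prevalence]
        if len(chosen) < 2:
            continue
        if len(genera) > 1 and len({genus_of[s] for s in chosen}) < 2:
            continue
        return chosen
    # degenerate forest (single genus or very small); fall back to two leaves
    return list(rng.sample(leaves, min(2, len(leaves))))


# ---------------------------------------------------------------------------
# abstracts
# ---------------------------------------------------------------------------

def _check_lexicons(cue_lexicons: dict[str, tuple[str, ...]]) -> None:
    seen: set[str] = set()
    for rel, lex in cue_lexicons.items():
        lexset = set(lex)
        if lexset & seen:
            raise ValueError("cue lexicons must be pairwise disjoint")
        seen |= lexset


def generate_abstract(pair: tuple[str, str], relation: str,
                      dictionaries: dict[str, EntityDictionary],
                      cue_lexicons: dict[str, tuple[str, ...]] | None = None,
                      noise_rate: float = 0.0, year: int = 2000,
                      seed: int = 0, abstract_id: str = "A00001",
                      ) -> SyntheticAbstract:
    """Emit one templated abstract co-mentioning ``pair``.

    For an informative relation the non-entity tokens are cue words from that
    relation's lexicon; each cue slot is independently replaced by an
    off-lexicon filler word with probability ``noise_rate``.  For relation
    ``"none"`` every non-entity token is filler, so no informative cue occurs
    anywhere near the mentions.

    The first token between the two mentions is the relation's *canonical*
    cue (the first word of its lexicon; the first filler word for "none"),
    mirroring how a handful of high-frequency words ("compound", "isolated",
    "extract", ...) dominate real abstracts of each relation type.  Like any
    other slot it can be displaced by noise.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    cue_lexicons = dict(CUE_LEXICONS if cue_lexicons is None else cue_lexicons)
    _check_lexicons(cue_lexicons)

    entries: dict[str, DictEntry] = {}
    for eid in pair:
        for d in dictionaries.values():
            try:
                entries[eid] = d.by_id(eid)
                break
            except KeyError:
                continue
        if eid not in entries:
            raise KeyError(f"unknown entity id {eid!r}")

    rng = random.Random(seed)

    def surface(entry: DictEntry) -> str:
        s = rng.choice(entry.names())
        return s.capitalize() if rng.random() < 0.3 else s

    lexicon = (FILLER_LEXICON if relation == "none"
               else cue_lexicons[relation])

    def cue(canonical: bool = False) -> str:
        if relation != "none" and rng.random() < noise_rate:
            return rng.choice(FILLER_LEXICON)
        return lexicon[0] if canonical else rng.choice(lexicon)

    first, second = pair if rng.random() < 0.5 else (pair[1], pair[0])
    tokens = [cue() for _ in range(rng.randint(1, 2))]
    tokens.append(surface(entries[first]))
    tokens.append(cue(canonical=True))
    tokens.extend(cue() for _ in range(rng.randint(0, 2)))
    tokens.append(surface(entries[second]))
    tokens.extend(cue() for _ in range(rng.randint(1, 2)))
    text = " ".join(tokens) + "."
    return SyntheticAbstract(
        abstract_id=abstract_id, year=year, text=text,
        truth=((pair[0], pair[1], relation),),
    )


# ---------------------------------------------------------------------------
# chemistry fixture pools
# ---------------------------------------------------------------------------

def _tested_structures(n: int) -> list[str]:
    """Aromatic scaffolds (phenolic acids, flavonoid-like) for the directly
    tested pool; far from the aliphatic pools in path-fingerprint space."""
    bases = [
        "Oc1ccc(C(=O)O)cc1",
        "Oc1ccc(CC(=O)O)cc1",
        "COc1cc(C=O)ccc1O",
        "Oc1ccc(cc1)C1CC(=O)c2c(O)cc(O)cc2O1",
        "O=c1cc(-c2ccccc2)oc2ccccc12",
        "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",
        "COc1ccc(C=CC(=O)O)cc1O",
        "Oc1ccc(C=CC(=O)O)cc1",
    ]
    out = list(bases)
    k = 2
    while len(out) < n:
        out.append(f"Oc1ccc(C{'C' * k}(=O)O)cc1")
        out.append(f"COc1ccc({'C' * k}C=O)cc1")
        k += 1
    return out[:n]


def _similar_structures(n: int) -> list[tuple[str, str]]:
    """(compound, reference) pairs of adjacent linear alkanols.

    Even-length chains are compounds, odd-length their tested references; the
    hashed-path fingerprints of adjacent homologues are near identical, so
    each pair sits far above any sensible Tanimoto cutoff, while no compound
    structure coincides with a reference structure.
    """
    return [("C" * (10 + 2 * i) + "O", "C" * (11 + 2 * i) + "O")
            for i in range(n)]


_UNEXPLORED_POOL = (
    "CC1CNCCN1C", "CN(C)CCN(C)C", "FC(F)(F)CC(F)(F)F", "CC(C)OC(C)C",
    "OC1OC(CO)C(O)C(O)C1O", "CC1CCOC1C", "C1CNCCN1", "CC1CNC(C)CN1",
    "CN(C)CN(C)C", "COCCOC", "FC(F)(F)C(F)(F)F", "CC(C)N(C(C)C)C",
    "CC1COC(C)O1", "CN1CCNCC1",
)


def _unexplored_structures(n: int) -> list[str]:
    """Amine/ether/fluoro scaffolds dissimilar to both activity pools."""
    if n > len(_UNEXPLORED_POOL):
        raise ValueError(
            f"unexplored pool holds {len(_UNEXPLORED_POOL)} structures; "
            f"{n} requested"
        )
    return list(_UNEXPLORED_POOL[:n])


def _decorate(rng: random.Random, smiles: str) -> str:
    """Occasionally emit a salt-adduct form to exercise canonicalization."""
    r = rng.random()
    if r < 0.15:
        return smiles + ".[Na+]"
    if r < 0.25:
        return smiles + ".O"
    return smiles


# ---------------------------------------------------------------------------
# corpus configuration and bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for one synthetic corpus.

    Defaults describe a small but fully wired world: 60 plant species on a
    five-rank taxonomy, two dozen compounds, a handful of diseases, and four
    compound-disease pairs planted at a strong enrichment odds ratio.
    """

    taxonomy_shape: tuple[int, ...] = (2, 2, 3, 5, 1)
    n_compounds: int = 24
    n_diseases: int = 6
    synonyms_per_entity: int = 1
    localized_fraction: float = 0.25
    dispersed_prevalence: float = 0.3
    disease_prevalence: float = 0.35
    promoting_prevalence: float = 0.15
    n_planted_associations: int = 4
    planted_odds_ratio: float = 40.0
    planted_target_p: float = 1e-3
    n_abstracts_per_relation: int = 40
    noise_rate: float = 0.0
    year_range: tuple[int, int] = (1980, 2012)
    frac_tested: float = 0.4
    frac_similar: float = 0.3
    confirmed_fraction: float = 0.5
    edible_fraction: float = 0.7

    def __post_init__(self):
        if any(b < 1 for b in self.taxonomy_shape):
            raise ValueError("branching factors must be >= 1")
        for name in ("localized_fraction", "dispersed_prevalence",
                     "disease_prevalence", "promoting_prevalence",
                     "noise_rate", "frac_tested", "frac_similar",
                     "confirmed_fraction", "edible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_tested + self.frac_similar > 1.0 + 1e-9:
            raise ValueError("activity fractions must sum to <= 1")
        if self.n_compounds < 1 or self.n_diseases < 1:
            raise ValueError("entity counts must be >= 1")
        if self.planted_odds_ratio <= 0:
            raise ValueError("planted_odds_ratio must be > 0")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year range")

    @property
    def n_plants(self) -> int:
        return prod(self.taxonomy_shape)


@dataclass
class FixtureBundle:
    """Everything one pipeline run needs, with its planted ground truth."""

    config: CorpusConfig
    seed: int
    dictionaries: dict[str, EntityDictionary]
    taxonomy: Taxonomy
    corpus: list[SyntheticAbstract]
    #: compound_id -> set of plant ids containing it (species level)
    plant_content: dict[str, set[str]]
    #: (disease_id, direction) -> set of plant ids; direction in {positive, negative}
    disease_plants: dict[tuple[str, str], set[str]]
    #: raw (possibly salt-decorated) structure string per compound
    structures: dict[str, str]
    activity: list[ActivityRecord]
    target_disease: list[tuple[str, str]]
    #: disease_id -> protein set (disease-pathway stand-in)
    pathway: dict[str, set[str]]
    edible: set[str]
    #: planted (compound_id, disease_id, direction) associations
    truth_associations: list[tuple[str, str, str]]
    #: intended activity classes: compound_id -> {tested, similar, unexplored}
    activity_class: dict[str, str]
    #: compounds whose tested target resolves to their planted disease
    confirmed_compounds: set[str]

    # -- derived views -----------------------------------------------------
    def truth_content_edges(self) -> list[tuple[str, str]]:
        """(plant_id, compound_id) pairs of the full planted content map."""
        out = []
        for cid in sorted(self.plant_content):
            out.extend((p, cid) for p in sorted(self.plant_content[cid]))
        return out

    def truth_signed_edges(self) -> list[tuple[str, str, str]]:
        """(plant_id, disease_id, direction) triples of the planted map."""
        out = []
        for (did, direction) in sorted(self.disease_plants):
            out.extend((p, did, direction)
                       for p in sorted(self.disease_plants[(did, direction)]))
        return out

    def truth_relations(self) -> set[tuple[str, str, str, str]]:
        """(abstract_id, id_a, id_b, relation) for informative abstracts."""
        out = set()
        for a in self.corpus:
            for (x, y, rel) in a.truth:
                if rel != "none":
                    out.add((a.abstract_id, x, y, rel))
        return out


def _p_one(p0: float, odds_ratio: float) -> float:
    odds = odds_ratio * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def _hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) tail; local copy to validate planted tables."""
    row1, col1, n = a + b, a + c, a + b + c + d
    num = sum(comb(row1, k) * comb(c + d, col1 - k)
              for k in range(a, min(row1, col1) + 1))
    return float(Fraction(num, comb(n, col1)))


def generate_corpus(config: CorpusConfig, seed: int = 0) -> FixtureBundle:
    """Generate a fully cross-referenced fixture bundle.

    The corpus holds ``config.n_abstracts_per_relation`` abstracts for each of
    the four relations (contains / prevents / promotes / none); "none"
    abstracts alternate between compound and disease partners so both
    classification tasks see unrelated examples.
    """
    rng = random.Random(seed)
    dict_seed = rng.randrange(2 ** 31)
    tax_seed = rng.randrange(2 ** 31)

    dictionaries = generate_dictionaries(
        config.n_plants, config.n_compounds, config.n_diseases,
        config.synonyms_per_entity, seed=dict_seed,
    )
    plant_ids = [e.entity_id for e in dictionaries["plant"].entries]
    compound_ids = [e.entity_id for e in dictionaries["compound"].entries]
    disease_ids = [e.entity_id for e in dictionaries["disease"].entries]

    taxonomy = generate_taxonomy(
        config.taxonomy_shape, tuple(compound_ids),
        config.localized_fraction, seed=tax_seed,
        species_ids=tuple(plant_ids),
    )

    plant_content: dict[str, set[str]] = {c: set() for c in compound_ids}
    for pid in plant_ids:
        for cid in taxonomy.content[pid]:
            plant_content[cid].add(pid)

    # disease plant sets, both directions
    disease_plants: dict[tuple[str, str], set[str]] = {}
    for did in disease_ids:
        disease_plants[(did, "positive")] = {
            p for p in plant_ids if rng.random() < config.disease_prevalence
        }
        disease_plants[(did, "negative")] = {
            p for p in plant_ids if rng.random() < config.promoting_prevalence
        }

    # plant compound-disease associations at the configured odds ratio
    dispersed = [c for c in compound_ids
                 if c not in taxonomy.localized_compounds]
    if config.n_planted_associations > len(dispersed):
        raise ValueError(
            "not enough dispersed compounds to plant associations; lower "
            "localized_fraction or n_planted_associations"
        )
    planted_compounds = dispersed[:config.n_planted_associations]
    truth_associations: list[tuple[str, str, str]] = []
    p0 = config.dispersed_prevalence
    p1 = _p_one(p0, config.planted_odds_ratio)
    strong = config.planted_odds_ratio >= 10.0
    for i, cid in enumerate(planted_compounds):
        did = disease_ids[i % len(disease_ids)]
        dset = disease_plants[(did, "positive")]
        for _ in range(50):
            members = {
                p for p in plant_ids
                if rng.random() < (p1 if p in dset else p0)
            }
            if not strong:
                break
            a = len(members & dset)
            b = len(members - dset)
            c = len(dset - members)
            d = config.n_plants - a - b - c
            if _hypergeom_tail(a, b, c, d) <= config.planted_target_p:
                break
        else:  # pragma: no cover - only under absurd configurations
            raise RuntimeError("could not realize planted association")
        # rewire content maps consistently
        for p in plant_ids:
            if p in members:
                taxonomy.content[p].add(cid)
            else:
                taxonomy.content[p].discard(cid)
        plant_content[cid] = set(members)
        truth_associations.append((cid, did, "positive"))

    # activity classes and structures
    n = len(compound_ids)
    n_tested = round(config.frac_tested * n)
    n_similar = round(config.frac_similar * n)
    n_tested = min(n_tested, n)
    n_similar = min(n_similar, n - n_tested)
    class_order = list(compound_ids)
    rng.shuffle(class_order)
    tested_ids = class_order[:n_tested]
    similar_ids = class_order[n_tested:n_tested + n_similar]
    unexplored_ids = class_order[n_tested + n_similar:]
    activity_class = {c: "tested" for c in tested_ids}
    activity_class.update({c: "similar" for c in similar_ids})
    activity_class.update({c: "unexplored" for c in unexplored_ids})

    tested_smiles = _tested_structures(len(tested_ids))
    similar_pairs = _similar_structures(len(similar_ids))
    unexplored_smiles = _unexplored_structures(len(unexplored_ids))

    structures: dict[str, str] = {}
    activity: list[ActivityRecord] = []
    protein_of: dict[str, list[str]] = {}
    protein_counter = 0

    def new_protein() -> str:
        nonlocal protein_counter
        protein_counter += 1
        return f"PR{protein_counter:03d}"

    from .chemo_inference import canonicalize_structure  # local to avoid cycle

    for cid, smi in zip(tested_ids, tested_smiles):
        structures[cid] = _decorate(rng, smi)
        key = canonicalize_structure(smi)
        prots = [new_protein() for _ in range(rng.randint(1, 2))]
        protein_of[cid] = prots
        activity.extend(ActivityRecord(key, p, note="direct") for p in prots)
    for cid, (smi, ref) in zip(similar_ids, similar_pairs):
        structures[cid] = _decorate(rng, smi)
        key = canonicalize_structure(ref)
        prots = [new_protein()]
        protein_of[cid] = prots  # reachable only through similarity
        activity.extend(
            ActivityRecord(key, p, note="reference") for p in prots
        )
    for cid, smi in zip(unexplored_ids, unexplored_smiles):
        structures[cid] = smi

    # protein-disease links (TTD stand-in); planted associations are confirmed
    # with the configured probability, the rest of the proteins point at a
    # rotating "other" disease.
    target_disease: list[tuple[str, str]] = []
    confirmed: set[str] = set()
    planted_by_compound = {c: d for (c, d, _) in truth_associations}
    for cid in sorted(protein_of):
        prots = protein_of[cid]
        did = planted_by_compound.get(cid)
        if did is not None and rng.random() < config.confirmed_fraction:
            target_disease.append((prots[0], did))
            confirmed.add(cid)
            others = prots[1:]
        else:
            others = prots
        for p in others:
            alt = disease_ids[rng.randrange(len(disease_ids))]
            if did is not None and alt == did:
                alt = disease_ids[(disease_ids.index(alt) + 1)
                                  % len(disease_ids)]
            target_disease.append((p, alt))

    # pathway stand-in for the first planted disease
    pathway: dict[str, set[str]] = {}
    if truth_associations:
        focus = truth_associations[0][1]
        linked = {p for (p, d) in target_disease if d == focus}
        extra = {new_protein() for _ in range(2)}
        pathway[focus] = linked | extra

    edible = {p for p in plant_ids if rng.random() < config.edible_fraction}

    corpus = _sample_relation_corpus(
        dictionaries, plant_content, disease_plants, config,
        config.n_abstracts_per_relation, config.noise_rate, rng, prefix="A")

    return FixtureBundle(
        config=config, seed=seed, dictionaries=dictionaries,
        taxonomy=taxonomy, corpus=corpus, plant_content=plant_content,
        disease_plants=disease_plants, structures=structures,
        activity=activity, target_disease=target_disease, pathway=pathway,
        edible=edible, truth_associations=truth_associations,
        activity_class=activity_class, confirmed_compounds=confirmed,
    )


def _sample_relation_corpus(dictionaries, plant_content, disease_plants,
                            config: CorpusConfig, n_per_relation: int,
                            noise_rate: float, rng: random.Random,
                            prefix: str = "A") -> list[SyntheticAbstract]:
    """``n_per_relation`` abstracts for each of the four relations, sampled
    from the world's truth maps ("none" alternates partner classes)."""
    plant_ids = [e.entity_id for e in dictionaries["plant"].entries]
    compound_ids = [e.entity_id for e in dictionaries["compound"].entries]
    disease_ids = [e.entity_id for e in dictionaries["disease"].entries]
    corpus: list[SyntheticAbstract] = []
    counter = 0

    def add_abstract(pair: tuple[str, str], relation: str) -> None:
        nonlocal counter
        counter += 1
        corpus.append(generate_abstract(
            pair, relation, dictionaries, noise_rate=noise_rate,
            year=rng.randint(*config.year_range),
            seed=rng.randrange(2 ** 31),
            abstract_id=f"{prefix}{counter:05d}",
        ))

    contained_pairs = [
        (p, c) for c in compound_ids for p in sorted(plant_content[c])
    ]
    pos_pairs = [
        (p, did) for (did, s) in sorted(disease_plants) if s == "positive"
        for p in sorted(disease_plants[(did, s)])
    ]
    neg_pairs = [
        (p, did) for (did, s) in sorted(disease_plants) if s == "negative"
        for p in sorted(disease_plants[(did, s)])
    ]
    for _ in range(n_per_relation):
        add_abstract(rng.choice(contained_pairs), "contains")
    for _ in range(n_per_relation):
        add_abstract(rng.choice(pos_pairs), "prevents")
    for _ in range(n_per_relation):
        add_abstract(rng.choice(neg_pairs), "promotes")
    for k in range(n_per_relation):
        if k % 2 == 0:
            pair = _none_pair(rng, plant_ids, compound_ids,
                              lambda p, c: p not in plant_content[c])
        else:
            pair = _none_pair(
                rng, plant_ids, disease_ids,
                lambda p, d: p not in disease_plants[(d, "positive")]
                and p not in disease_plants[(d, "negative")])
        add_abstract(pair, "none")
    return corpus


def generate_eval_corpus(bundle: FixtureBundle, n_per_relation: int,
                         seed: int = 0, noise_rate: float | None = None,
                         ) -> list[SyntheticAbstract]:
    """A fresh held-out corpus over the *same* world as ``bundle``."""
    rng = random.Random(seed)
    rate = bundle.config.noise_rate if noise_rate is None else noise_rate
    return _sample_relation_corpus(
        bundle.dictionaries, bundle.plant_content, bundle.disease_plants,
        bundle.config, n_per_relation, rate, rng, prefix="E")


def generate_survey_corpus(bundle: FixtureBundle, seed: int = 0,
                           n_none: int = 20,
                           noise_rate: float | None = None,
                           well_studied_fraction: float = 0.15,
                           well_studied_repeats: tuple[int, int] = (5, 9),
                           ) -> list[SyntheticAbstract]:
    """Emit abstracts covering every planted truth edge, plus unrelated ones.

    Whereas :func:`generate_corpus` samples a fixed number of abstracts per
    relation, this survey corpus covers the *entire* planted content and
    disease maps, so relation extraction over it can reconstruct the full
    plant universe and the association stage downstream sees the planted
    enrichment structure at full strength.  A ``well_studied_fraction`` of
    the plant-disease edges receives several publications (uniform in
    ``well_studied_repeats``) instead of one, emulating the skewed
    publication counts behind support-filtered food-disease networks.
    """
    cfg = bundle.config
    rng = random.Random(seed)
    rate = cfg.noise_rate if noise_rate is None else noise_rate
    out: list[SyntheticAbstract] = []
    counter = 0

    def add(pair, relation):
        nonlocal counter
        counter += 1
        out.append(generate_abstract(
            pair, relation, bundle.dictionaries, noise_rate=rate,
            year=rng.randint(*cfg.year_range), seed=rng.randrange(2 ** 31),
            abstract_id=f"S{counter:05d}",
        ))

    for (p, c) in bundle.truth_content_edges():
        add((p, c), "contains")
    for (p, d, direction) in bundle.truth_signed_edges():
        relation = "prevents" if direction == "positive" else "promotes"
        repeats = (rng.randint(*well_studied_repeats)
                   if rng.random() < well_studied_fraction else 1)
        for _ in range(repeats):
            add((p, d), relation)
    plant_ids = [e.entity_id for e in bundle.dictionaries["plant"].entries]
    compound_ids = [e.entity_id for e in bundle.dictionaries["compound"].entries]
    disease_ids = [e.entity_id for e in bundle.dictionaries["disease"].entries]
    for k in range(n_none):
        if k % 2 == 0:
            pair = _none_pair(rng, plant_ids, compound_ids,
                              lambda p, c: p not in bundle.plant_content[c])
        else:
            pair = _none_pair(
                rng, plant_ids, disease_ids,
                lambda p, d: p not in bundle.disease_plants[(d, "positive")]
                and p not in bundle.disease_plants[(d, "negative")])
        add(pair, "none")
    return out


def _none_pair(rng, plants, partners, unrelated) -> tuple[str, str]:
    for _ in range(1000):
        p, q = rng.choice(plants), rng.choice(partners)
        if unrelated(p, q):
            return (p, q)
    raise RuntimeError("could not sample an unrelated pair")  # pragma: no cover
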
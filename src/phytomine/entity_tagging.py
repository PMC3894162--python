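"""Dictionary-based named-entity recognition and relation-candidate mining.

Tagging follows deliberately simple rules: case-insensitive exact matching of
dictionary names on token boundaries, with the longest match winning at each
position.  Remaining ties are broken by entity-class priority
(plant > compound > disease) and then by lexicographic entity id, so the
result is independent of dictionary entry order.  Matched spans are consumed,
so mentions never overlap.  No stemming, fuzzy matching or abbreviation
expansion is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus_synthesis import EntityDictionary, SyntheticAbstract

__all__ = [
    "Mention",
    "TaggedAbstract",
    "RelationCandidate",
    "tokenize",
    "tag_entities",
    "extract_candidates",
]

# Word characters are letters and digits; internal hyphens are part of the
# token, so hyphenated chemical names ("5-fluorouracil") stay whole.
_TOKEN_RE = re.compile(r"[0-9A-Za-z]+(?:-[0-9A-Za-z]+)*")

_CLASS_PRIORITY = {"plant": 0, "compound": 1, "disease": 2}


@dataclass(frozen=True)
class Mention:
    entity_id: str
    entity_class: str
    start: int
    end: int
    surface: str


@dataclass
class TaggedAbstract:
    abstract: SyntheticAbstract | Mapping
    mentions: list[Mention]

    def __post_init__(self):
        prev_end = -1
        for m in self.mentions:
            if m.start < prev_end:
                raise ValueError("mentions overlap or are unsorted")
            prev_end = m.end

    @property
    def abstract_id(self) -> str:
        a = self.abstract
        return a["abstract_id"] if isinstance(a, Mapping) else a.abstract_id

    @property
    def text(self) -> str:
        a = self.abstract
        return a["text"] if isinstance(a, Mapping) else a.text

    @property
    def year(self) -> int:
        a = self.abstract
        return a["year"] if isinstance(a, Mapping) else a.year


@dataclass
class RelationCandidate:
    abstract_id: str
    plant: Mention
    partner: Mention
    context: list[str] = field(default_factory=list)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lowercased word tokens with character offsets into ``text``."""
    return [(m.group(0).lower(), m.start(), m.end())
            for m in _TOKEN_RE.finditer(text)]


def _name_index(dictionaries: Iterable[EntityDictionary]):
    """token-tuple -> best (priority, entity_id, class) under the tie rules."""
    seen_ids: set[str] = set()
    index: dict[tuple[str, ...], tuple[int, str, str]] = {}
    max_len = 1
    for d in dictionaries:
        for entry in d.entries:
            if entry.entity_id in seen_ids:
                raise ValueError(
                    f"entity id {entry.entity_id!r} in more than one dictionary"
                )
            seen_ids.add(entry.entity_id)
            for name in entry.names():
                key = tuple(t for t, _, _ in tokenize(name))
                if not key:
                    continue
                max_len = max(max_len, len(key))
                cand = (_CLASS_PRIORITY[entry.entity_class],
                        entry.entity_id, entry.entity_class)
                if key not in index or cand < index[key]:
                    index[key] = cand
    return index, max_len


def tag_entities(text: str,
                 dictionaries: Iterable[EntityDictionary]) -> list[Mention]:
    """Locate dictionary names in ``text``; longest match wins per position."""
    tokens = tokenize(text)
    index, max_len = _name_index(dictionaries)
    mentions: list[Mention] = []
    i = 0
    while i < len(tokens):
        hit = None
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(t for t, _, _ in tokens[i:i + length])
            if key in index:
                hit = (length, index[key])
                break
        if hit is None:
            i += 1
            continue
        length, (_, entity_id, entity_class) = hit
        start = tokens[i][1]
        end = tokens[i + length - 1][2]
        mentions.append(Mention(entity_id, entity_class, start, end,
                                text[start:end]))
        i += length
    return mentions


def tag_abstract(abstract,
                 dictionaries: Iterable[EntityDictionary]) -> TaggedAbstract:
    text = abstract["text"] if isinstance(abstract, Mapping) else abstract.text
    return TaggedAbstract(abstract, tag_entities(text, dictionaries))


def extract_candidates(tagged: TaggedAbstract, partner_class: str,
                       window: int = 10) -> list[RelationCandidate]:
    """One candidate per unique co-mentioned (plant, partner) id pair.

    The context is the tokens lying within ``window`` tokens on either side
    of any mention of either entity (union of window positions, so a token
    position contributes once), minus the tokens of the entities' own
    mentions.
    """
    if partner_class not in ("compound", "disease"):
        raise ValueError(f"invalid partner class {partner_class!r}")
    if window < 1:
        raise ValueError("window must be >= 1")

    tokens = tokenize(tagged.text)
    # token index span of each mention
    spans: list[tuple[Mention, int, int]] = []
    for m in tagged.mentions:
        idx = [k for k, (_, s, e) in enumerate(tokens)
               if s >= m.start and e <= m.end]
        if idx:
            spans.append((m, idx[0], idx[-1]))

    plants: dict[str, list[tuple[int, int]]] = {}
    partners: dict[str, list[tuple[int, int]]] = {}
    first_mention: dict[str, Mention] = {}
    for m, lo, hi in spans:
        if m.entity_class == "plant":
            plants.setdefault(m.entity_id, []).append((lo, hi))
        elif m.entity_class == partner_class:
            partners.setdefault(m.entity_id, []).append((lo, hi))
        first_mention.setdefault(m.entity_id, m)

    out: list[RelationCandidate] = []
    for pid in sorted(plants):
        for qid in sorted(partners):
            own = plants[pid] + partners[qid]
            positions: set[int] = set()
            for lo, hi in own:
                positions.update(range(max(0, lo - window),
                                       min(len(tokens), hi + window + 1)))
            for lo, hi in own:
                positions.difference_update(range(lo, hi + 1))
            context = [tokens[k][0] for k in sorted(positions)]
            out.append(RelationCandidate(
                abstract_id=tagged.abstract_id,
                plant=first_mention[pid],
                partner=first_mention[qid],
                context=context,
            ))
    return out
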
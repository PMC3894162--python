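"""Plain-text interchange formats for every pipeline stage.

Dictionaries, taxonomy, activity and link tables are TSV; corpora and tagged
corpora are JSON-lines; structures are a SMILES file (structure, compound_id
per line).  Writers sort rows, so serialization is reproducible byte for
byte for a fixed bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .corpus_synthesis import (ActivityRecord, DictEntry, EntityDictionary,
                               FixtureBundle, SyntheticAbstract, TaxonNode,
                               Taxonomy)
from .entity_tagging import Mention, TaggedAbstract
from .relation_classifier import ContentEdge, SignedEdge

__all__ = [
    "write_bundle",
    "read_dictionaries",
    "read_taxonomy",
    "read_corpus",
    "read_structures",
    "read_activity",
    "read_pairs_tsv",
    "write_tagged_corpus",
    "read_tagged_corpus",
    "write_edges",
    "read_content_edges",
    "read_signed_edges",
    "write_associations",
    "write_enrichment",
]


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> Path:
    """Write every bundle component under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for cls in ("plant", "compound", "disease"):
        for e in bundle.dictionaries[cls].entries:
            rows.append({"entity_id": e.entity_id, "class": cls,
                         "canonical_name": e.canonical_name,
                         "synonyms": "|".join(e.synonyms)})
    _tsv(pd.DataFrame(rows), outdir / "dictionaries.tsv")

    _tsv(pd.DataFrame(
        [{"node_id": n.node_id, "rank": n.rank,
          "parent_id": n.parent_id or ""} for n in bundle.taxonomy.nodes]),
        outdir / "taxonomy.tsv")

    with open(outdir / "corpus.jsonl", "w") as fh:
        for a in bundle.corpus:
            fh.write(json.dumps({
                "abstract_id": a.abstract_id, "year": a.year, "text": a.text,
                "truth": [list(t) for t in a.truth]}) + "\n")

    with open(outdir / "structures.smi", "w") as fh:
        for cid in sorted(bundle.structures):
            fh.write(f"{bundle.structures[cid]}\t{cid}\n")

    _tsv(pd.DataFrame(
        [{"structure": r.structure, "protein_id": r.protein_id,
          "note": r.note} for r in bundle.activity]),
        outdir / "activity.tsv")

    _tsv(pd.DataFrame(sorted(bundle.target_disease),
                      columns=["protein_id", "disease_id"]),
         outdir / "target_disease.tsv")

    _tsv(pd.DataFrame(
        [{"disease_id": d, "protein_id": p}
         for d in sorted(bundle.pathway) for p in sorted(bundle.pathway[d])]),
        outdir / "pathway.tsv")

    _tsv(pd.DataFrame({"plant_id": sorted(bundle.edible)}),
         outdir / "edible.tsv")

    _tsv(pd.DataFrame(bundle.truth_content_edges(),
                      columns=["plant_id", "compound_id"]),
         outdir / "plant_content.tsv")

    _tsv(pd.DataFrame(bundle.truth_signed_edges(),
                      columns=["plant_id", "disease_id", "direction"]),
         outdir / "disease_plants.tsv")

    _tsv(pd.DataFrame(bundle.truth_associations,
                      columns=["compound_id", "disease_id", "direction"]),
         outdir / "truth_associations.tsv")

    with open(outdir / "config.json", "w") as fh:
        cfg = asdict(bundle.config)
        cfg["seed"] = bundle.seed
        json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir


def read_dictionaries(path: str | Path) -> dict[str, EntityDictionary]:
    df = _read_tsv(Path(path))
    out = {}
    for cls, grp in df.groupby("class", sort=True):
        entries = tuple(
            DictEntry(r.entity_id, r.canonical_name,
                      tuple(s for s in r.synonyms.split("|") if s), cls)
            for r in grp.itertuples()
        )
        out[cls] = EntityDictionary(cls, entries)
    return out


def read_taxonomy(path: str | Path,
                  content: dict[str, set[str]] | None = None) -> Taxonomy:
    df = _read_tsv(Path(path))
    nodes = [TaxonNode(r.node_id, r.rank, r.parent_id or None)
             for r in df.itertuples()]
    full_content = {n.node_id: set() for n in nodes}
    if content:
        for nid, compounds in content.items():
            full_content[nid] |= set(compounds)
    return Taxonomy(nodes, full_content)


def read_corpus(path: str | Path) -> list[SyntheticAbstract]:
    out = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        out.append(SyntheticAbstract(
            d["abstract_id"], d["year"], d["text"],
            tuple(tuple(t) for t in d.get("truth", []))))
    return out


def read_structures(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        smiles, cid = line.split("\t")
        out[cid] = smiles
    return out


def read_activity(path: str | Path) -> list[ActivityRecord]:
    df = _read_tsv(Path(path))
    return [ActivityRecord(r.structure, r.protein_id, r.note)
            for r in df.itertuples()]


def read_pairs_tsv(path: str | Path) -> list[tuple]:
    """Generic two-or-more-column TSV as a list of row tuples (no header
    interpretation beyond skipping it)."""
    df = _read_tsv(Path(path))
    return [tuple(r) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# tagged corpora and edges
# ---------------------------------------------------------------------------

def write_tagged_corpus(tagged: Iterable[TaggedAbstract],
                        path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for t in tagged:
            a = t.abstract
            record = a if isinstance(a, dict) else {
                "abstract_id": a.abstract_id, "year": a.year, "text": a.text,
                "truth": [list(x) for x in a.truth]}
            fh.write(json.dumps({
                "abstract": record,
                "mentions": [asdict(m) for m in t.mentions]}) + "\n")
    return path


def read_tagged_corpus(path: str | Path) -> list[TaggedAbstract]:
    out = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        a = d["abstract"]
        abstract = SyntheticAbstract(
            a["abstract_id"], a["year"], a["text"],
            tuple(tuple(t) for t in a.get("truth", [])))
        out.append(TaggedAbstract(
            abstract, [Mention(**m) for m in d["mentions"]]))
    return out


def write_edges(content_edges: Iterable[ContentEdge],
                signed_edges: Iterable[SignedEdge],
                content_path: str | Path, signed_path: str | Path) -> None:
    _tsv(pd.DataFrame(
        [{"plant_id": e.plant_id, "partner_id": e.compound_id, "sign": "NA",
          "abstract_id": e.abstract_id, "year": "",
          "posterior": f"{e.posterior:.6f}"} for e in content_edges]),
        Path(content_path))
    _tsv(pd.DataFrame(
        [{"plant_id": e.plant_id, "partner_id": e.disease_id, "sign": e.sign,
          "abstract_id": e.abstract_id, "year": e.year,
          "posterior": f"{e.posterior:.6f}"} for e in signed_edges]),
        Path(signed_path))


def read_content_edges(path: str | Path) -> list[ContentEdge]:
    df = _read_tsv(Path(path))
    return [ContentEdge(r.plant_id, r.partner_id, r.abstract_id,
                        float(r.posterior)) for r in df.itertuples()]


def read_signed_edges(path: str | Path) -> list[SignedEdge]:
    df = _read_tsv(Path(path))
    return [SignedEdge(r.plant_id, r.partner_id, r.sign, r.abstract_id,
                       int(r.year), float(r.posterior))
            for r in df.itertuples()]


def write_associations(results, path: str | Path) -> Path:
    path = Path(path)
    _tsv(pd.DataFrame(
        [{"compound_id": r.compound_id, "disease_id": r.disease_id,
          "direction": r.direction, "a": r.table.a, "b": r.table.b,
          "c": r.table.c, "d": r.table.d, "p": f"{r.p:.6g}",
          "rank": r.rank, "significant": int(r.significant)}
         for r in results]), path)
    return path


def write_enrichment(results, path: str | Path) -> Path:
    path = Path(path)
    _tsv(pd.DataFrame(
        [{"compound_id": r.compound_id, "node_id": r.node_id,
          "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
          "p": f"{r.p:.6g}", "significant": int(r.significant)}
         for r in results]), path)
    return path
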
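"""Structure canonicalization, fingerprints, Tanimoto target inference, the
tested/similar/unexplored tripartition, and disease-pathway overlay.

Canonical structure strings serve as the join key between the mined
phytochemical list and the compound-protein activity table: the largest
covalent fragment is kept (salt stripping), stereo descriptors and isotope
labels are erased, and the toolkit-canonical SMILES is emitted, so two inputs
denoting the same salt-stripped skeleton always collapse to one key.

Similarity inference uses hashed linear-path fingerprints (2048 bits, paths
up to length 7 by default) and a strict Tanimoto cutoff: a compound without
its own activity record inherits the protein targets of every reference
structure whose similarity exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger

from .corpus_synthesis import ActivityRecord

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Fingerprint",
    "Molecule",
    "SimilarityHit",
    "canonicalize_structure",
    "fingerprint",
    "make_molecule",
    "tanimoto",
    "infer_targets_by_similarity",
    "partition_phytochemicals",
    "validate_predictions",
    "pathway_overlay",
]

DEFAULT_THRESHOLD = 0.85
FP_BITS = 2048
FP_MAX_PATH = 7


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint as a set of on-bits."""

    bits: frozenset[int]
    nbits: int = FP_BITS

    def __post_init__(self):
        if any(not 0 <= b < self.nbits for b in self.bits):
            raise ValueError("bit index out of range")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class Molecule:
    compound_id: str
    canonical: str
    fingerprint: Fingerprint


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    reference: str  # canonical structure key of the active reference
    tanimoto: float
    inherited_targets: frozenset[str]


class StructureParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# canonicalization and fingerprints
# ---------------------------------------------------------------------------

def canonicalize_structure(raw: str) -> str:
    """Salt-stripped, stereo- and isotope-free canonical SMILES.

    Keeps the largest covalently connected fragment (ties broken by the
    lexicographically smallest canonical form), erases chiral centres,
    double-bond stereo and isotope labels, and emits RDKit's canonical
    SMILES.  Idempotent.  Raises :class:`StructureParseError` naming the
    offending string on unparsable input.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StructureParseError(f"unparsable structure string: {raw!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(),
                                        Chem.MolToSmiles(f)))
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


def fingerprint(canonical: str, nbits: int = FP_BITS,
                max_path: int = FP_MAX_PATH) -> Fingerprint:
    """Hashed linear-path fingerprint of a canonical structure string."""
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        raise StructureParseError(f"unparsable structure string: {canonical!r}")
    fp = Chem.RDKFingerprint(mol, maxPath=max_path, fpSize=nbits)
    return Fingerprint(frozenset(fp.GetOnBits()), nbits)


def make_molecule(compound_id: str, raw: str) -> Molecule:
    canonical = canonicalize_structure(raw)
    return Molecule(compound_id, canonical, fingerprint(canonical))


def tanimoto(fp1: Fingerprint, fp2: Fingerprint) -> float:
    """|intersection| / |union| of on-bits.

    Two all-zero fingerprints have an empty union; that degenerate case
    returns 0.0 with a warning rather than claiming identity.
    """
    if fp1.nbits != fp2.nbits:
        raise ValueError("fingerprint length mismatch")
    union = len(fp1.bits | fp2.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0.0",
                      stacklevel=2)
        return 0.0
    return len(fp1.bits & fp2.bits) / union


# ---------------------------------------------------------------------------
# target inference
# ---------------------------------------------------------------------------

def _targets_by_structure(activity: Iterable[ActivityRecord],
                          ) -> dict[str, frozenset[str]]:
    acc: dict[str, set[str]] = {}
    for rec in activity:
        acc.setdefault(rec.structure, set()).add(rec.protein_id)
    return {k: frozenset(v) for k, v in acc.items()}


def _hits_from_fps(query_id: str, query_fp: Fingerprint,
                   ref_fps: Mapping[str, Fingerprint],
                   ref_targets: Mapping[str, frozenset[str]],
                   threshold: float) -> list[SimilarityHit]:
    hits = []
    for key in sorted(ref_fps):
        tc = tanimoto(query_fp, ref_fps[key])
        if tc > threshold:  # strictly greater
            hits.append(SimilarityHit(query_id, key, tc, ref_targets[key]))
    hits.sort(key=lambda h: (-h.tanimoto, h.reference))
    return hits


def infer_targets_by_similarity(query: Molecule,
                                activity: Sequence[ActivityRecord],
                                threshold: float = DEFAULT_THRESHOLD,
                                ) -> list[SimilarityHit]:
    """Similarity hits against every distinct reference structure in the
    activity table, strict Tanimoto > threshold, each carrying the
    reference's full target set; sorted by descending similarity then key."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ref_targets = _targets_by_structure(activity)
    ref_fps = {key: fingerprint(key) for key in ref_targets}
    return _hits_from_fps(query.compound_id, query.fingerprint,
                          ref_fps, ref_targets, threshold)


# ---------------------------------------------------------------------------
# tripartition, validation, pathway overlay
# ---------------------------------------------------------------------------

def partition_phytochemicals(molecules: Sequence[Molecule],
                             activity: Sequence[ActivityRecord],
                             threshold: float = DEFAULT_THRESHOLD,
                             ) -> tuple[set[str], set[str], set[str]]:
    """(tested, similar, unexplored) compound-id sets.

    tested: own canonical key has an activity record; similar: not tested but
    at least one reference above the Tanimoto cutoff; unexplored: the rest.
    The three sets always partition the input.
    """
    ref_targets = _targets_by_structure(activity)
    ref_fps = {key: fingerprint(key) for key in ref_targets}
    tested, similar, unexplored = set(), set(), set()
    for mol in molecules:
        if mol.canonical in ref_targets:
            tested.add(mol.compound_id)
        elif _hits_from_fps(mol.compound_id, mol.fingerprint, ref_fps,
                            ref_targets, threshold):
            similar.add(mol.compound_id)
        else:
            unexplored.add(mol.compound_id)
    assert len(tested) + len(similar) + len(unexplored) == \
        len({m.compound_id for m in molecules})
    return tested, similar, unexplored


def validate_predictions(associations, molecules: Sequence[Molecule],
                         activity: Sequence[ActivityRecord],
                         target_disease: Iterable[tuple[str, str]],
                         ) -> tuple[int, int, float]:
    """Check predicted compound-disease links against experimental targets.

    Among experimentally tested compounds that carry a significant positive
    association to some disease, a compound is *confirmed* when one of its
    measured protein targets maps (through the protein-disease table) to one
    of those same diseases.  Returns (confirmed, tested, fraction).
    """
    ref_targets = _targets_by_structure(activity)
    mol_by_id = {m.compound_id: m for m in molecules}
    disease_of_protein: dict[str, set[str]] = {}
    for prot, dis in target_disease:
        disease_of_protein.setdefault(prot, set()).add(dis)

    predicted: dict[str, set[str]] = {}
    for r in associations:
        if r.significant and r.direction == "positive":
            predicted.setdefault(r.compound_id, set()).add(r.disease_id)

    confirmed = tested = 0
    for cid in sorted(predicted):
        mol = mol_by_id.get(cid)
        if mol is None or mol.canonical not in ref_targets:
            continue
        tested += 1
        target_diseases: set[str] = set()
        for prot in ref_targets[mol.canonical]:
            target_diseases |= disease_of_protein.get(prot, set())
        if target_diseases & predicted[cid]:
            confirmed += 1
    fraction = confirmed / tested if tested else 0.0
    return confirmed, tested, fraction


def pathway_overlay(disease_id: str, pathway: set[str], associations,
                    molecules: Sequence[Molecule],
                    activity: Sequence[ActivityRecord],
                    threshold: float = DEFAULT_THRESHOLD,
                    ) -> dict:
    """Per-protein counts of disease-associated compounds with direct versus
    similarity-inferred activity, plus disease-level totals.

    Returns ``{"per_protein": {protein: {"experimental": n, "predicted": n}},
    "experimental": set, "predicted": set}`` where the two sets hold the
    disease-associated compounds with any direct (respectively only
    inferred) activity on a pathway protein.
    """
    if not pathway:
        raise ValueError("pathway protein set is empty")
    associated = sorted({
        r.compound_id for r in associations
        if r.significant and r.direction == "positive"
        and r.disease_id == disease_id
    })
    ref_targets = _targets_by_structure(activity)
    ref_fps = {key: fingerprint(key) for key in ref_targets}
    mol_by_id = {m.compound_id: m for m in molecules}

    per_protein = {p: {"experimental": 0, "predicted": 0}
                   for p in sorted(pathway)}
    experimental_set: set[str] = set()
    predicted_set: set[str] = set()
    for cid in associated:
        mol = mol_by_id.get(cid)
        if mol is None:
            continue
        if mol.canonical in ref_targets:
            hit_prots = ref_targets[mol.canonical] & pathway
            if hit_prots:
                experimental_set.add(cid)
                for p in hit_prots:
                    per_protein[p]["experimental"] += 1
        else:
            inferred: set[str] = set()
            for hit in _hits_from_fps(cid, mol.fingerprint, ref_fps,
                                      ref_targets, threshold):
                inferred |= hit.inherited_targets
            hit_prots = inferred & pathway
            if hit_prots:
                predicted_set.add(cid)
                for p in hit_prots:
                    per_protein[p]["predicted"] += 1
    return {"per_protein": per_protein,
            "experimental": experimental_set,
            "predicted": predicted_set}
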
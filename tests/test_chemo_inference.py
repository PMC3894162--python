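"""Canonicalization contracts, Tanimoto arithmetic, tripartition, overlay."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytomine.chemo_inference import (Fingerprint, Molecule,
                                       StructureParseError, _hits_from_fps,
                                       canonicalize_structure, fingerprint,
                                       infer_targets_by_similarity,
                                       make_molecule,
                                       partition_phytochemicals,
                                       pathway_overlay, tanimoto,
                                       validate_predictions)
from phytomine.corpus_synthesis import ActivityRecord


class TestCanonicalize:
    def test_same_molecule_same_canonical(self):
        assert canonicalize_structure("OCC") == canonicalize_structure("C(C)O")

    def test_salt_stripping_keeps_largest_fragment(self):
        assert canonicalize_structure("CCO.[Na+]") == \
            canonicalize_structure("CCO")

    @pytest.mark.parametrize("stereo,flat", [
        ("C[C@H](O)C(=O)O", "CC(O)C(=O)O"),
        ("C/C=C/C", "CC=CC"),
    ])
    def test_stereo_stripping(self, stereo, flat):
        assert canonicalize_structure(stereo) == canonicalize_structure(flat)

    def test_isotope_stripping(self):
        assert canonicalize_structure("[13CH3]CO") == \
            canonicalize_structure("CCO")

    def test_idempotent(self):
        for smi in ("OCC", "CCO.[Na+]", "C[C@H](O)C(=O)O",
                    "Oc1ccc(CC(=O)O)cc1"):
            once = canonicalize_structure(smi)
            assert canonicalize_structure(once) == once

    def test_parse_error_names_the_string(self):
        with pytest.raises(StructureParseError, match="not-a-structure"):
            canonicalize_structure("not-a-structure")


class TestFingerprint:
    def test_deterministic(self):
        assert fingerprint("CCO") == fingerprint("CCO")

    def test_unrelated_scaffolds_below_identity(self):
        a = fingerprint(canonicalize_structure("Oc1ccc(CC(=O)O)cc1"))
        b = fingerprint(canonicalize_structure("CCCCCCCCCCCCO"))
        assert tanimoto(a, b) < 1.0

    def test_nontrivial_molecule_sets_bits(self):
        assert len(fingerprint("CCO")) > 0


class TestTanimoto:
    def test_identical_nonempty(self):
        fp = Fingerprint(frozenset({1, 5, 9}))
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(Fingerprint(frozenset({1})),
                        Fingerprint(frozenset({2}))) == 0.0

    def test_direct_count(self):
        a = Fingerprint(frozenset({1, 2, 3}))
        b = Fingerprint(frozenset({2, 3, 4}))
        assert tanimoto(a, b) == 0.5

    def test_empty_fingerprints_warn_and_return_zero(self):
        empty = Fingerprint(frozenset())
        with pytest.warns(UserWarning):
            assert tanimoto(empty, empty) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(Fingerprint(frozenset(), 1024),
                     Fingerprint(frozenset(), 2048))

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 127), max_size=30),
           st.sets(st.integers(0, 127), max_size=30))
    def test_symmetry_and_bounds(self, b1, b2):
        import warnings
        f1, f2 = Fingerprint(frozenset(b1), 128), Fingerprint(frozenset(b2), 128)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t12, t21 = tanimoto(f1, f2), tanimoto(f2, f1)
        assert t12 == t21
        assert 0.0 <= t12 <= 1.0

    def test_agrees_with_rdkit_datastructs(self):
        from rdkit import Chem, DataStructs
        pairs = [("CCO", "CCCO"), ("Oc1ccc(CC(=O)O)cc1", "CCCCCCCCCCO")]
        for s1, s2 in pairs:
            ours = tanimoto(fingerprint(s1), fingerprint(s2))
            ref = DataStructs.TanimotoSimilarity(
                Chem.RDKFingerprint(Chem.MolFromSmiles(s1), maxPath=7,
                                    fpSize=2048),
                Chem.RDKFingerprint(Chem.MolFromSmiles(s2), maxPath=7,
                                    fpSize=2048))
            assert ours == pytest.approx(ref, abs=1e-12)


class TestSimilarityInference:
    activity = [ActivityRecord("CCCCCCCCCCCO", "PR1"),
                ActivityRecord("CCCCCCCCCCCO", "PR2"),
                ActivityRecord(canonicalize_structure("Oc1ccc(C=O)cc1"), "PR3")]

    def test_identical_reference_surfaces_first(self):
        query = make_molecule("q", "CCCCCCCCCCCO")
        hits = infer_targets_by_similarity(query, self.activity, 0.85)
        assert hits[0].tanimoto == 1.0
        assert hits[0].inherited_targets == {"PR1", "PR2"}

    def test_adjacent_homologue_inherits_targets(self):
        query = make_molecule("q", "CCCCCCCCCCCCO")
        hits = infer_targets_by_similarity(query, self.activity, 0.85)
        assert any(h.reference == "CCCCCCCCCCCO" for h in hits)

    def test_exact_threshold_excluded(self):
        """Tc exactly at the cutoff produces no hit (strict inequality)."""
        # intersection 17, union 20: Tc = 17/20 = 0.85 exactly
        q = Fingerprint(frozenset(range(19)), 128)
        ref = Fingerprint(frozenset(range(2, 20)), 128)
        assert tanimoto(q, ref) == pytest.approx(0.85)
        hits = _hits_from_fps("q", q, {"R": ref}, {"R": frozenset({"P"})},
                              0.85)
        assert hits == []
        above = Fingerprint(frozenset(range(1, 20)), 128)  # Tc = 18/20
        assert _hits_from_fps("q", q, {"R": above},
                              {"R": frozenset({"P"})}, 0.85)

    def test_empty_activity_table(self):
        query = make_molecule("q", "CCO")
        assert infer_targets_by_similarity(query, [], 0.85) == []

    def test_threshold_monotonicity(self):
        query = make_molecule("q", "CCCCCCCCCCCCO")
        lo = infer_targets_by_similarity(query, self.activity, 0.5)
        hi = infer_targets_by_similarity(query, self.activity, 0.95)
        assert {h.reference for h in hi} <= {h.reference for h in lo}


class TestPartition:
    def _fixture(self):
        mols = [make_molecule("tested1", "Oc1ccc(C=O)cc1"),
                make_molecule("tested2", "Oc1ccc(CC(=O)O)cc1"),
                make_molecule("sim1", "CCCCCCCCCCCCO"),
                make_molecule("un1", "CC1CNCCN1C"),
                make_molecule("un2", "CN(C)CCN(C)C")]
        activity = [
            ActivityRecord(canonicalize_structure("Oc1ccc(C=O)cc1"), "P1"),
            ActivityRecord(canonicalize_structure("Oc1ccc(CC(=O)O)cc1"), "P2"),
            ActivityRecord("CCCCCCCCCCCO", "P3"),
        ]
        return mols, activity

    def test_constructed_partition(self):
        mols, activity = self._fixture()
        tested, similar, unexplored = partition_phytochemicals(mols, activity)
        assert tested == {"tested1", "tested2"}
        assert similar == {"sim1"}
        assert unexplored == {"un1", "un2"}

    def test_partition_sums_to_input(self, default_bundle):
        """Additive check: |tested| + |similar| + |unexplored| = n."""
        mols = [make_molecule(cid, smi)
                for cid, smi in sorted(default_bundle.structures.items())]
        parts = partition_phytochemicals(mols, default_bundle.activity)
        assert sum(map(len, parts)) == len(mols)
        for i, s1 in enumerate(parts):
            for s2 in parts[i + 1:]:
                assert not s1 & s2

    def test_empty_activity_all_unexplored(self):
        mols, _ = self._fixture()
        tested, similar, unexplored = partition_phytochemicals(mols, [])
        assert (len(tested), len(similar)) == (0, 0)
        assert len(unexplored) == len(mols)

    def test_generator_classes_realized(self, default_bundle):
        """The bundle's intended tested/similar/unexplored classes are the
        ones the chemoinformatics actually reconstructs."""
        mols = [make_molecule(cid, smi)
                for cid, smi in sorted(default_bundle.structures.items())]
        tested, similar, unexplored = partition_phytochemicals(
            mols, default_bundle.activity)
        intended = default_bundle.activity_class
        assert tested == {c for c, k in intended.items() if k == "tested"}
        assert similar == {c for c, k in intended.items() if k == "similar"}
        assert unexplored == {c for c, k in intended.items()
                              if k == "unexplored"}


class _Assoc:
    def __init__(self, compound_id, disease_id, direction="positive",
                 significant=True):
        self.compound_id = compound_id
        self.disease_id = disease_id
        self.direction = direction
        self.significant = significant


class TestValidation:
    def test_confirmed_and_unconfirmed(self):
        mols = [make_molecule("c1", "Oc1ccc(C=O)cc1"),
                make_molecule("c2", "Oc1ccc(CC(=O)O)cc1")]
        activity = [ActivityRecord(m.canonical, p)
                    for m, p in zip(mols, ("P1", "P2"))]
        links = [("P1", "d1"), ("P2", "d9")]
        assoc = [_Assoc("c1", "d1"), _Assoc("c2", "d1")]
        confirmed, tested, fraction = validate_predictions(
            assoc, mols, activity, links)
        assert (confirmed, tested) == (1, 2)
        assert fraction == 0.5

    def test_untested_compounds_not_counted(self):
        mols = [make_molecule("c1", "CC1CNCCN1C")]
        confirmed, tested, fraction = validate_predictions(
            [_Assoc("c1", "d1")], mols, [], [])
        assert (confirmed, tested, fraction) == (0, 0, 0.0)


class TestPathwayOverlay:
    def test_counts_per_protein(self):
        # four compounds active on protein X, one on Y, one inferred on X
        scaffolds = ["Oc1ccc(C=O)cc1", "Oc1ccc(CC(=O)O)cc1",
                     "COc1cc(C=O)ccc1O", "O=c1cc(-c2ccccc2)oc2ccccc12"]
        mols = [make_molecule(f"t{i}", s) for i, s in enumerate(scaffolds)]
        activity = [ActivityRecord(m.canonical, "X") for m in mols]
        activity.append(ActivityRecord(mols[0].canonical, "Y"))
        activity.append(ActivityRecord("CCCCCCCCCCCO", "X"))
        mols.append(make_molecule("sim", "CCCCCCCCCCCCO"))
        assoc = [_Assoc(m.compound_id, "d1") for m in mols]
        overlay = pathway_overlay("d1", {"X", "Y", "Z"}, assoc, mols,
                                  activity)
        assert overlay["per_protein"]["X"] == {"experimental": 4,
                                               "predicted": 1}
        assert overlay["per_protein"]["Y"]["experimental"] == 1
        assert overlay["per_protein"]["Z"] == {"experimental": 0,
                                               "predicted": 0}
        assert overlay["experimental"] == {"t0", "t1", "t2", "t3"}
        assert overlay["predicted"] == {"sim"}

    def test_no_associated_compounds(self):
        overlay = pathway_overlay("d1", {"X"}, [], [], [])
        assert overlay["per_protein"]["X"] == {"experimental": 0,
                                               "predicted": 0}

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            pathway_overlay("d1", set(), [], [], [])
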
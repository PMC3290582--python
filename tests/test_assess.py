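"""Pose quality: superposition, DNA RMSD, contacts, f_nat, MCC, enrichment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ccpdock import assess, structures
from ccpdock.dockgen import Decoy, DecoySet

from conftest import (
    random_rigid_transform,
    transform_na_sites,
    transform_protein_sites,
)


def _pose(protein, na, pid="p"):
    return structures.ComplexPose(protein, na, pid)


class TestSuperpose:
    def test_identity_for_identical_proteins(self, toy_protein):
        tf = assess.superpose_protein(toy_protein, toy_protein)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)

    def test_recovers_known_rotation(self, toy_protein):
        rng = np.random.default_rng(8)
        R, t = random_rigid_transform(rng)
        moved = transform_protein_sites(toy_protein, R, t)
        tf = assess.superpose_protein(toy_protein, moved)
        np.testing.assert_allclose(tf.rotation, R.T, atol=1e-6)
        a = np.array([s.position for s in toy_protein])
        b = tf.apply(np.array([s.position for s in moved]))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_beats_random_candidate_transforms(self):
        """Kabsch result is optimal: no random rigid transform does better."""
        rng = np.random.default_rng(9)
        a = rng.uniform(-10, 10, (12, 3))
        b = a + 0.5 * rng.standard_normal((12, 3))
        sites_a = [structures.ProteinSite("ALA", "P", i, p, 0.5, 0)
                   for i, p in enumerate(a)]
        sites_b = [structures.ProteinSite("ALA", "P", i, p, 0.5, 0)
                   for i, p in enumerate(b)]
        tf = assess.superpose_protein(sites_a, sites_b)
        best = np.sqrt(np.mean(np.sum((a - tf.apply(b)) ** 2, axis=1)))
        for _ in range(1000):
            R, t = random_rigid_transform(rng)
            cand = np.sqrt(np.mean(np.sum((a - (b @ R.T + t)) ** 2, axis=1)))
            assert best <= cand + 1e-9

    def test_too_few_atoms_rejected(self):
        s = [structures.ProteinSite("ALA", "P", 1, (0, 0, 0), 0.5, 0)]
        with pytest.raises(ValueError):
            assess.superpose_protein(s, s)

    def test_mismatched_lengths_rejected(self, toy_protein):
        with pytest.raises(ValueError):
            assess.superpose_protein(toy_protein, toy_protein[:-1])


class TestDnaRmsd:
    def test_identical_complexes(self, native_pose):
        assert assess.dna_rmsd(native_pose, native_pose) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_is_pythagorean(self, native_pose):
        moved = _pose(
            native_pose.protein_sites,
            transform_na_sites(native_pose.na_sites, np.eye(3), np.array([3.0, 4.0, 0.0])),
        )
        assert assess.dna_rmsd(native_pose, moved) == pytest.approx(5.0, abs=1e-9)

    def test_matches_per_atom_oracle(self, native_pose):
        """After a random rigid DNA perturbation the reported RMSD equals a
        directly coded per-atom computation."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = _pose(native_pose.protein_sites,
                          transform_na_sites(native_pose.na_sites, R, t))
            got = assess.dna_rmsd(native_pose, moved)
            # oracle: proteins identical -> no superposition needed
            deltas = []
            for a, b in zip(native_pose.na_sites, moved.na_sites):
                for pa, pb in ((a.p_position, b.p_position),
                               (a.c2p_position, b.c2p_position),
                               (a.c4_position, b.c4_position)):
                    if pa is not None and pb is not None:
                        deltas.append(np.sum((pa - pb) ** 2))
            want = np.sqrt(np.mean(deltas))
            assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_under_common_rigid_motion(self, native_pose):
        rng = np.random.default_rng(12)
        Rm, tm = random_rigid_transform(rng)
        model = _pose(native_pose.protein_sites,
                      transform_na_sites(native_pose.na_sites, Rm, tm))
        base = assess.dna_rmsd(native_pose, model)
        Rc, tc = random_rigid_transform(rng)
        both_moved = (
            _pose(transform_protein_sites(native_pose.protein_sites, Rc, tc),
                  transform_na_sites(native_pose.na_sites, Rc, tc)),
            _pose(transform_protein_sites(model.protein_sites, Rc, tc),
                  transform_na_sites(model.na_sites, Rc, tc)),
        )
        assert assess.dna_rmsd(*both_moved) == pytest.approx(base, abs=1e-8)


class TestContacts:
    def _one_site_pose(self, distance):
        site = structures.ProteinSite("LYS", "P", 1, (distance, 0.0, 0.0), 5.5, +1)
        nuc = structures.NucleotideSites(
            "A", "A", 1, major_position=(0.0, 50.0, 0.0),
            minor_position=(0.0, -50.0, 0.0), p_position=(0.0, 0.0, 0.0))
        return _pose([site], [nuc])

    def test_below_cutoff_counts(self):
        cs = assess.contact_set(self._one_site_pose(6.9))
        assert len(cs.pairs) == 1
        ((res, moiety),) = cs.pairs
        assert moiety == ("A", 1, "P")

    def test_above_cutoff_excluded(self):
        assert len(assess.contact_set(self._one_site_pose(7.1)).pairs) == 0

    def test_matches_bruteforce_scan(self, native_pose):
        cs = assess.contact_set(native_pose)
        brute = set()
        for s in native_pose.protein_sites:
            for n in native_pose.na_sites:
                for moiety, c in (("P", n.p_position), ("M", n.major_position),
                                  ("m", n.minor_position)):
                    if c is not None and np.linalg.norm(s.position - c) < 7.0:
                        brute.add(((s.chain_id, s.residue_index),
                                   (n.chain_id, n.residue_index, moiety)))
        assert cs.pairs == brute


class TestFractionNativeContacts:
    def _cs(self, pairs):
        return assess.ContactSet(cutoff=7.0, pairs=frozenset(pairs))

    def test_perfect_model(self):
        cs = self._cs({("r1", "n1"), ("r2", "n2")})
        assert assess.fraction_native_contacts(cs, cs) == 1.0

    def test_disjoint_model(self):
        a = self._cs({("r1", "n1")})
        b = self._cs({("r2", "n2")})
        assert assess.fraction_native_contacts(a, b) == 0.0

    def test_half_recovered(self):
        nat = self._cs({("r1", "n1"), ("r2", "n2"), ("r3", "n3"), ("r4", "n4")})
        mdl = self._cs({("r1", "n1"), ("r2", "n2"), ("r9", "n9")})
        assert assess.fraction_native_contacts(nat, mdl) == 0.5

    def test_empty_native_rejected(self):
        with pytest.raises(ValueError):
            assess.fraction_native_contacts(self._cs(set()), self._cs({("a", "b")}))


class TestProteinMCC:
    def test_identical_sets(self):
        assert assess.protein_mcc({"r1", "r2"}, {"r1", "r2"}) == 1.0

    def test_precision_recall_geometric_mean(self):
        # native 4 residues, model recovers 2 with no false positives:
        # sqrt(1.0 * 0.5)
        got = assess.protein_mcc({"r1", "r2", "r3", "r4"}, {"r1", "r2"})
        assert got == pytest.approx(np.sqrt(0.5))

    def test_no_overlap(self):
        assert assess.protein_mcc({"r1", "r2"}, {"r3", "r4"}) == 0.0

    def test_empty_native_rejected(self):
        with pytest.raises(ValueError):
            assess.protein_mcc(set(), {"r1"})

    def test_equals_one_iff_sets_match(self):
        assert assess.protein_mcc({"r1"}, {"r1", "r2"}) < 1.0
        assert assess.protein_mcc({"r1", "r2"}, {"r1"}) < 1.0


def _decoy_set(selector_vals, truth_vals):
    return DecoySet(decoys=[
        Decoy(pose_id=f"d{i}", rotation_index=0, translation=np.zeros(3),
              scs=0.0, scs_rank=i + 1,
              annotations={"sel": s, "tru": t})
        for i, (s, t) in enumerate(zip(selector_vals, truth_vals))
    ])


class TestRankEnrichment:
    def test_perfect_selector(self):
        vals = list(range(100))
        ds = _decoy_set(vals, vals)
        assert assess.rank_enrichment(ds, "sel", "tru", subset_size=30) == 1.0

    def test_reversed_selector(self):
        vals = list(range(100))
        ds = _decoy_set(vals[::-1], vals)
        assert assess.rank_enrichment(ds, "sel", "tru", subset_size=20) == 0.0

    def test_random_selector_matches_expectation(self):
        """Random pre-ranking retains top decoys at rate subset_size/N."""
        rng = np.random.default_rng(42)
        n, subset = 10_000, 1_000
        fracs = []
        for _ in range(20):
            ds = _decoy_set(rng.permutation(n).tolist(), list(range(n)))
            fracs.append(assess.rank_enrichment(ds, "sel", "tru", subset_size=subset))
        assert np.mean(fracs) == pytest.approx(subset / n, abs=0.03)

    def test_oversized_subset_rejected(self):
        ds = _decoy_set([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            assess.rank_enrichment(ds, "sel", "tru", subset_size=10, top_n=2)


def test_quality_report_self_comparison(native_pose):
    r = assess.quality_report(native_pose, native_pose)
    assert r.dna_rmsd == pytest.approx(0.0, abs=1e-9)
    assert r.f_nat == 1.0
    assert r.protein_mcc == 1.0
    assert r.ccd == pytest.approx(0.0, abs=1e-4)
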
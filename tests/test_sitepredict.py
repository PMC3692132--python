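"""Contact criterion, ligand clustering, pocket selection and residue voting,
each checked against brute-force oracles."""

import math

import numpy as np
import pytest

from pocketvote.sitepredict import (ContactParams, LigandCluster,
                                    atoms_in_contact, cluster_ligands,
                                    ligands_in_contact, predict_site,
                                    select_pocket, vote_residues,
                                    vote_threshold)
from pocketvote.structio import StructureModel
from tests.conftest import point_ligand, point_residue

ZN_ZN_THRESHOLD = 1.39 + 1.39 + 0.5  # 3.28 A


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_partition(ligands, p):
    """Transitive closure of the pairwise contact matrix."""
    n = len(ligands)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = ligands_in_contact(ligands[i], ligands[j], p)
    reach = adj.copy()
    for _ in range(n):
        reach = reach | (reach @ reach)
    groups = set()
    for i in range(n):
        groups.add(frozenset(ligands[j].ligand_id for j in range(n)
                             if reach[i, j]))
    return groups


def brute_force_votes(model, pocket, p):
    """Direct enumeration of the voting rule over the contact matrix."""
    n = pocket.size
    need = 1 if n <= 1 else max(2, math.ceil(0.25 * n))
    accepted = []
    for res in model.residues:
        votes = 0
        for lig in pocket.members:
            heavy = res.heavy_atoms()
            if any(atoms_in_contact(a, b, p)
                   for a in heavy for b in lig.atoms):
                votes += 1
        if votes >= need:
            accepted.append(res.seq)
    return sorted(accepted)


def random_instance(rng, n_res=30, n_lig=10, box=18.0):
    model = StructureModel(
        id="rand",
        residues=[point_residue(i + 1, rng.uniform(0, box, 3))
                  for i in range(n_res)])
    ligands = [point_ligand(f"t:ZN:{i}:Z", rng.uniform(0, box, 3),
                            source=f"t{i % 3}") for i in range(n_lig)]
    return model, ligands


# ---------------------------------------------------------------------------


class TestAtomContacts:
    @pytest.mark.parametrize("d,expected", [
        (3.80, True),   # C-C threshold is 1.70+1.70+0.5 = 3.90
        (3.95, False),
    ])
    def test_carbon_pair(self, d, expected, params):
        a = point_residue(1, (0, 0, 0), element="C").atoms[0]
        b = point_residue(2, (d, 0, 0), element="C").atoms[0]
        assert atoms_in_contact(a, b, params) is expected

    def test_carbon_zinc(self, params):
        # threshold 1.70 + 1.39 + 0.5 = 3.59
        a = point_residue(1, (0, 0, 0), element="C").atoms[0]
        b = point_ligand("t:ZN:1:Z", (3.55, 0, 0)).atoms[0]
        assert atoms_in_contact(a, b, params)

    def test_single_radius_mode(self):
        p = ContactParams(sum_radii=False)  # threshold r(a) + 0.5
        a = point_residue(1, (0, 0, 0), element="C").atoms[0]
        b = point_residue(2, (2.1, 0, 0), element="C").atoms[0]
        assert atoms_in_contact(a, b, p)
        b.coords = np.array([2.3, 0.0, 0.0])
        assert not atoms_in_contact(a, b, p)


class TestLigandContacts:
    @pytest.mark.parametrize("d,expected", [(3.0, True), (3.5, False)])
    def test_zinc_pair(self, d, expected, params):
        l1 = point_ligand("a", (0, 0, 0))
        l2 = point_ligand("b", (d, 0, 0))
        assert ligands_in_contact(l1, l2, params) is expected
        assert abs(ZN_ZN_THRESHOLD - 3.28) < 1e-9

    def test_self_contact(self, params):
        l = point_ligand("a", (1, 2, 3))
        assert ligands_in_contact(l, l, params)


class TestClustering:
    def test_transitive_chain(self, params):
        a = point_ligand("a", (0, 0, 0))
        b = point_ligand("b", (3.0, 0, 0))
        c = point_ligand("c", (6.0, 0, 0))  # touches b, not a
        clusters = cluster_ligands([a, b, c], params)
        assert len(clusters) == 1
        assert clusters[0].size == 3

    def test_distant_singletons(self, params):
        a = point_ligand("a", (0, 0, 0))
        b = point_ligand("b", (50, 0, 0))
        clusters = cluster_ligands([a, b], params)
        assert [c.size for c in clusters] == [1, 1]

    def test_empty(self, params):
        assert cluster_ligands([], params) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_transitive_closure_oracle(self, seed, params):
        rng = np.random.default_rng(seed)
        _, ligands = random_instance(rng, n_lig=int(rng.integers(5, 31)))
        clusters = cluster_ligands(ligands, params)
        ours = {frozenset(l.ligand_id for l in c.members) for c in clusters}
        assert ours == brute_force_partition(ligands, params)
        # partition: disjoint and covering
        ids = [l.ligand_id for c in clusters for l in c.members]
        assert sorted(ids) == sorted(l.ligand_id for l in ligands)

    def test_sorted_by_size_descending(self, params):
        ligs = ([point_ligand(f"a{i}", (i * 3.0, 0, 0)) for i in range(3)]
                + [point_ligand("b", (80, 0, 0))])
        sizes = [c.size for c in cluster_ligands(ligs, params)]
        assert sizes == sorted(sizes, reverse=True)


class TestVoteThreshold:
    @pytest.mark.parametrize("n,need", [
        (1, 1), (2, 2), (8, 2), (9, 3), (12, 3), (13, 4), (40, 10)])
    def test_rule_arithmetic(self, n, need):
        assert vote_threshold(n) == need


class TestVoting:
    def _cluster_at(self, positions):
        return LigandCluster(members=[
            point_ligand(f"l{i}", p) for i, p in enumerate(positions)])

    def test_two_of_eight_accepted(self, params):
        # residue touches exactly 2 of 8 ligands: 2 >= max(2, ceil(2)) = 2
        near = [(3.0, 0, 0), (0, 3.0, 0)]
        far = [(30 + i * 5, 0, 0) for i in range(6)]
        pocket = self._cluster_at(near + far)
        model = StructureModel(id="m", residues=[point_residue(1, (0, 0, 0))])
        assert [r.seq for r in vote_residues(model, pocket, params)] == [1]

    def test_one_of_eight_rejected(self, params):
        pocket = self._cluster_at([(3.0, 0, 0)] +
                                  [(30 + i * 5, 0, 0) for i in range(7)])
        model = StructureModel(id="m", residues=[point_residue(1, (0, 0, 0))])
        assert vote_residues(model, pocket, params) == []

    def test_quarter_rule_at_twelve(self, params):
        # N=12 needs ceil(3) = 3 votes
        def build(n_near):
            near = [(3.0, 0, 0), (0, 3.0, 0), (0, 0, 3.0)][:n_near]
            far = [(40 + i * 5, 0, 0) for i in range(12 - n_near)]
            return self._cluster_at(near + far)
        model = StructureModel(id="m", residues=[point_residue(1, (0, 0, 0))])
        assert vote_residues(model, build(2), params) == []
        assert [r.seq for r in vote_residues(model, build(3), params)] == [1]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed, params):
        rng = np.random.default_rng(100 + seed)
        model, ligands = random_instance(rng)
        clusters = cluster_ligands(ligands, params)
        for pocket in clusters:
            ours = [r.seq for r in vote_residues(model, pocket, params)]
            assert ours == brute_force_votes(model, pocket, params)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_contacting_ligands(self, seed, params):
        # adding a ligand in contact with residue r keeps r accepted as long
        # as the vote threshold does not rise
        rng = np.random.default_rng(200 + seed)
        model, ligands = random_instance(rng)
        for pocket in cluster_ligands(ligands, params):
            accepted = vote_residues(model, pocket, params)
            if not accepted:
                continue
            n = pocket.size
            if vote_threshold(n + 1) != vote_threshold(n):
                continue
            res = accepted[0]
            extra = point_ligand("extra", res.atoms[0].coords + [2.0, 0, 0])
            bigger = LigandCluster(members=pocket.members + [extra])
            assert res.seq in [r.seq for r in
                               vote_residues(model, bigger, params)]


class TestSelectPocket:
    def test_largest_wins(self, params):
        big = LigandCluster([point_ligand(f"b{i}", (i * 3.0, 0, 0))
                             for i in range(8)])
        small = LigandCluster([point_ligand("s", (100, 0, 0))])
        model = StructureModel(id="m", residues=[point_residue(1, (0, 0, 0))])
        assert select_pocket([big, small], model, params) is big
        assert select_pocket([small], model, params) is small
        assert select_pocket([], model, params) is None

    def test_tie_broken_by_voting_residues(self, params):
        # two clusters of 4; cluster A yields 2 voting residues, B yields 1
        a = LigandCluster([point_ligand(f"a{i}", (i * 3.0, 0, 0))
                           for i in range(4)])
        b = LigandCluster([point_ligand(f"b{i}", (100 + i * 3.0, 0, 0))
                           for i in range(4)])
        residues = [point_residue(1, (1.5, 2.0, 0)),
                    point_residue(2, (4.5, 2.0, 0)),
                    point_residue(3, (101.5, 2.0, 0))]
        model = StructureModel(id="m", residues=residues)
        assert select_pocket([b, a], model, params) is a


class TestPredictSite:
    def test_no_templates(self):
        model = StructureModel(id="m", residues=[point_residue(1, (0, 0, 0))])
        pred = predict_site(model, [])
        assert pred.status == "no-template"
        assert pred.is_empty

    def test_two_masses_largest_selected(self, params):
        from pocketvote.superpose import Correspondence, SuperposedTemplate
        near_site = [point_ligand(f"i{k}", (2.8 + 0.01 * k, 0, 0),
                                  source="tA") for k in range(8)]
        far_site = [point_ligand(f"o{k}", (60 + 0.01 * k, 0, 0), resname="HEM",
                                 element="C", ltype="O", source="tB")
                    for k in range(3)]
        tmpl = SuperposedTemplate(
            template_id="tA", rotation=np.eye(3), translation=np.zeros(3),
            tm_score=1.0, rmsd=0.0,
            correspondence=Correspondence([(1, 1), (2, 2), (3, 3)]),
            ligands=near_site + far_site)
        model = StructureModel(id="m", residues=[
            point_residue(1, (0, 0, 0)), point_residue(2, (2.85, 3.0, 0))])
        pred = predict_site(model, [tmpl], params)
        assert pred.pocket.size == 8
        assert pred.pocket.type_counts["I"] == 8
        assert set(pred.residue_seqs) == {1, 2}
        assert len(pred.all_clusters) == 2

    def test_deterministic(self, params):
        from pocketvote.synthetic import SyntheticScenario, make_model, make_templates
        from pocketvote.superpose import iterative_superpose
        sc = SyntheticScenario(seed=9, coord_noise_sigma=0.7)
        model = make_model(sc)
        sup = [iterative_superpose(model, t, None, l)
               for t, l in make_templates(sc, model)]
        p1 = predict_site(model, sup, params)
        p2 = predict_site(model, sup, params)
        assert p1.residue_seqs == p2.residue_seqs
        assert p1.pocket.size == p2.pocket.size
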
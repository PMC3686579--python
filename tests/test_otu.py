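"""OTU clustering, taxonomy, tables, diet summaries and rarefaction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from minicoi import (assign_taxonomy, build_otu_table, cluster_otus,
                     diet_summaries, rarefaction_curve, remove_self_otus)
from minicoi.align import pairwise_identity
from minicoi.io import RANKS
from minicoi.otu import OTU, TaxonAssignment, abundance_class


def _lineage(**overrides):
    base = {"kingdom": "Animalia", "phylum": "Arthropoda", "class": "Malacostraca",
            "order": "Decapoda", "family": "Alpheidae", "genus": "Alpheus",
            "species": "Alpheus_obesomanus"}
    base.update(overrides)
    return base


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice(sorted(set("ACGT") - {out[p]}))
    return "".join(out)


class TestClustering:
    def test_identical_sequences_one_otu(self):
        reads = [(f"r{i}", "S01", "ACGT" * 40) for i in range(20)]
        otus = cluster_otus(reads, radius=0.07)
        assert len(otus) == 1 and otus[0].abundance == 20

    def test_radius_zero_splits_unique_sequences(self):
        reads = [("r1", "S01", "AAAA" * 30), ("r2", "S01", "AAAA" * 30),
                 ("r3", "S01", "CAAA" * 30)]
        otus = cluster_otus(reads, radius=0.0)
        assert len(otus) == 2

    def test_two_centroids_with_satellites_against_brute_force(self):
        rng = np.random.default_rng(21)
        L = 200
        c1 = "".join(rng.choice(list("ACGT"), size=L))
        c2 = _mutate(c1, rng.choice(L, size=30, replace=False), rng)  # 15% apart
        reads = []
        for tag, centroid in (("a", c1), ("b", c2)):
            for i in range(4):  # satellites within 2%
                sat = _mutate(centroid, rng.choice(L, size=i, replace=False), rng)
                for j in range(5 - i):
                    reads.append((f"{tag}{i}_{j}", "S01", sat))
        otus = cluster_otus(reads, radius=0.07)
        assert len(otus) == 2
        # oracle: every member within the radius of its centroid, across > radius
        members = {o.otu_id: frozenset(o.members) for o in otus}
        seqs = {rid: seq for rid, _, seq in reads}
        for o in otus:
            for rid in o.members:
                assert 1 - pairwise_identity(seqs[rid], o.representative) <= 0.07
        reps = [o.representative for o in otus]
        assert 1 - pairwise_identity(reps[0], reps[1]) > 0.07
        by_parent = {frozenset(rid for rid, _, _ in reads if rid.startswith(tag))
                     for tag in "ab"}
        assert set(members.values()) == by_parent

    def test_abundance_conserved_and_membership_radius(self, small_panel):
        rng = np.random.default_rng(8)
        reads = []
        for rid, seq in small_panel.inserts:
            for k in range(int(rng.integers(2, 6))):
                reads.append((f"{rid}.{k}", f"S{1 + k % 2:02d}", seq))
        otus = cluster_otus(reads, radius=0.07)
        assert sum(o.abundance for o in otus) == len(reads)
        assert len(otus) == small_panel.spec.n_species
        for o in otus:
            assert sum(o.sample_counts.values()) == o.abundance


class TestTaxonomy:
    def _db(self, rng, n=6):
        L = 300
        seqs = ["".join(rng.choice(list("ACGT"), size=L))]
        for _ in range(n - 1):
            seqs.append(_mutate(seqs[0], rng.choice(L, size=45, replace=False), rng))
        return seqs

    def test_species_match_inclusive_at_98(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        db = [("ref1", ref, _lineage())]
        exactly_98 = _mutate(ref, rng.choice(300, size=6, replace=False), rng)
        assert assign_taxonomy(exactly_98, db).method == "species_match"
        below = _mutate(ref, rng.choice(300, size=7, replace=False), rng)
        assert assign_taxonomy(below, db).method != "species_match"

    def test_rank_consensus_at_family(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=300))
        # two congeners-in-family references ~8% from the query, same family,
        # different genera -> consensus stops at family
        r1 = _mutate(base, rng.choice(300, size=24, replace=False), rng)
        r2 = _mutate(base, rng.choice(300, size=24, replace=False), rng)
        db = [("r1", r1, _lineage(genus="Alpheus", species="Alpheus_obesomanus")),
              ("r2", r2, _lineage(genus="Synalpheus", species="Synalpheus_sp"))]
        a = assign_taxonomy(base, db)
        assert a.method == "rank_consensus"
        assert a.assigned_rank == "family"
        assert a.taxon_path["family"] == "Alpheidae"

    def test_below_floor_unidentified(self):
        rng = np.random.default_rng(5)
        db = [("r1", "".join(rng.choice(list("ACGT"), size=300)), _lineage())]
        query = "".join(rng.choice(list("ACGT"), size=300))
        assert assign_taxonomy(query, db).method == "unidentified"

    def test_monotone_rank_depth_in_identity(self):
        rng = np.random.default_rng(6)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        db = [("r1", ref, _lineage())]
        depth = {None: -1}
        depth.update({r: i for i, r in enumerate(RANKS)})
        last = -1
        for n_mut in (80, 50, 40, 32, 20, 10, 3, 0):
            q = _mutate(ref, rng.choice(300, size=n_mut, replace=False), rng) \
                if n_mut else ref
            a = assign_taxonomy(q, db)
            d = depth[a.assigned_rank]
            assert d >= last or a.best_identity < 0.70
            last = max(last, d)

    def test_panel_references_assign_to_their_own_species(self, small_panel):
        db = small_panel.reference_db()
        for rid, seq in small_panel.inserts[:6]:
            a = assign_taxonomy(seq, db)
            assert a.method == "species_match"
            assert a.taxon_path["species"] == small_panel.species_of[rid]


class TestOtuTable:
    def _toy_otus(self):
        o1 = OTU("OTU_0001", "A" * 50, ["r1", "r2", "r3"],
                 sample_counts=pd.Series({"S01": 2, "S02": 1}).to_dict())
        o1.sample_counts = {"S01": 2, "S02": 1}
        o2 = OTU("OTU_0002", "C" * 50, ["r4"], sample_counts={"S02": 1})
        o3 = OTU("OTU_0003", "G" * 50, ["r5", "r6"], sample_counts={"S01": 2})
        from collections import Counter
        for o in (o1, o2, o3):
            o.sample_counts = Counter(o.sample_counts)
        return [o1, o2, o3]

    def test_matrix_conservation(self):
        otus = self._toy_otus()
        table = build_otu_table(otus, samples=["S01", "S02", "S03"])
        assert table.values.sum() == 6
        assert table.loc["OTU_0001"].tolist() == [2, 1, 0]
        assert table["S03"].sum() == 0  # empty sample keeps its zero column

    @pytest.mark.parametrize("n,label", [
        (1, "1"), (2, "2-9"), (9, "2-9"), (10, "10-99"), (99, "10-99"),
        (100, "100-999"), (999, "100-999"), (1000, ">=1000"), (5000, ">=1000"),
    ])
    def test_abundance_classes(self, n, label):
        assert abundance_class(n) == label

    def test_unknown_sample_is_hard_error(self):
        otus = self._toy_otus()
        with pytest.raises(ValueError):
            build_otu_table(otus, samples=["S01"])


class TestSelfRemovalAndDiet:
    def _make_otu(self, oid, counts, species=None, phylum="Arthropoda"):
        from collections import Counter
        o = OTU(oid, "A" * 40, members=[f"{oid}_{i}" for i in range(sum(counts.values()))],
                sample_counts=Counter(counts))
        if species:
            o.assignment = TaxonAssignment(
                "species_match", 0.99,
                _lineage(species=species, phylum=phylum), "species")
        return o

    def test_predator_otu_removed_congener_kept(self):
        otus = [
            self._make_otu("OTU_0001", {"S01": 5}, species="Predator_sp"),
            self._make_otu("OTU_0002", {"S01": 3}, species="Predator_cousin"),
            self._make_otu("OTU_0003", {"S01": 2}),  # unassigned
        ]
        kept, report = remove_self_otus(otus, {"S01": "Predator_sp"})
        assert [o.otu_id for o in kept] == ["OTU_0002", "OTU_0003"]
        assert report[0]["otu_id"] == "OTU_0001" and report[0]["abundance"] == 5

    def test_diet_sharing_matches_hand_enumeration(self):
        # species X: individuals S01,S02,S03; species Y: S04
        predators = {"S01": "X", "S02": "X", "S03": "X", "S04": "Y"}
        otus = [
            self._make_otu("o1", {"S01": 1}),                     # X: 1 indiv
            self._make_otu("o2", {"S01": 2, "S02": 1}),           # X: 2 indiv
            self._make_otu("o3", {"S01": 1, "S02": 1, "S03": 2}),  # X: >2
            self._make_otu("o4", {"S03": 1, "S04": 4}),           # shared X-Y
            self._make_otu("o5", {"S04": 1}),                     # Y only
        ]
        s = diet_summaries(otus, predators)
        x = s.intraspecific["X"]
        assert (x["n_otus"], x["in_1"], x["in_2"], x["in_more"]) == (4, 2, 1, 1)
        assert x["prop_1"] == pytest.approx(0.5)
        assert s.interspecific["X"]["prop_shared"] == pytest.approx(1 / 4)
        assert s.interspecific["Y"]["prop_shared"] == pytest.approx(1 / 2)

    def test_single_individual_all_in_one(self):
        s = diet_summaries([self._make_otu("o1", {"S01": 3}),
                            self._make_otu("o2", {"S01": 1})], {"S01": "X"})
        assert s.intraspecific["X"]["prop_1"] == 1.0

    def test_disjoint_species_share_nothing(self):
        s = diet_summaries([self._make_otu("o1", {"S01": 1}),
                            self._make_otu("o2", {"S02": 1})],
                           {"S01": "X", "S02": "Y"})
        assert s.interspecific["X"]["prop_shared"] == 0.0
        assert s.interspecific["Y"]["prop_shared"] == 0.0


class TestRarefaction:
    def test_exhaustive_enumeration_oracle(self):
        # all C(10,4) subsamples of the vector (5,3,2)
        pool = [0] * 5 + [1] * 3 + [2] * 2
        exact = np.mean([len(set(c)) for c in itertools.combinations(pool, 4)])
        got = rarefaction_curve([5, 3, 2], [4]).expected_otus[0]
        assert got == pytest.approx(exact, abs=1e-9)

    def test_boundary_depths(self):
        curve = rarefaction_curve([5, 3, 2], [1, 10])
        assert curve.expected_otus[0] == pytest.approx(1.0)
        assert curve.expected_otus[1] == pytest.approx(3.0)

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(7)
        vec = rng.integers(1, 40, size=12)
        curve = rarefaction_curve(vec, range(1, int(vec.sum()) + 1))
        assert (np.diff(curve.expected_otus) >= -1e-9).all()

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(17)
        vec = [40, 20, 10, 5, 2, 1, 1]
        N = sum(vec)
        pool = np.repeat(np.arange(len(vec)), vec)
        for depth in (5, 20, 50):
            reps = 1000
            sims = np.array([len(np.unique(rng.choice(pool, size=depth, replace=False)))
                             for _ in range(reps)])
            se = sims.std(ddof=1) / np.sqrt(reps)
            expected = rarefaction_curve(vec, [depth]).expected_otus[0]
            assert abs(expected - sims.mean()) <= 3 * max(se, 1e-9)

    def test_depth_past_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([3, 2], [6])
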
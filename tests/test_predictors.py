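"""Kernels, promiscuity, clustering, performance, compatibility, toxicity."""

import itertools
import math

import numpy as np
import pytest

from retrosig.config import RunConfig
from retrosig.fixtures import FixtureSpec, generate_predictor_data, generate_toy_network
from retrosig.network import MetabolicNetwork
from retrosig.predictors import (
    CompatibilityModel,
    EnzymeSequence,
    KineticRecord,
    PromiscuityClassifier,
    Taxonomy,
    candidate_enzymes,
    cluster_reactions,
    compatibility_descriptors,
    gc_content,
    gene_rank_pvalue,
    kmer_spectrum,
    promiscuity_score,
    similarity_matrix,
    string_kernel,
    tensor_kernel,
    train_compatibility,
    train_performance_model,
    train_toxicity,
)


@pytest.fixture(scope="module")
def spec():
    return FixtureSpec(seed=3)


@pytest.fixture(scope="module")
def net(spec):
    return generate_toy_network(spec)


@pytest.fixture(scope="module")
def data(spec, net):
    return generate_predictor_data(spec, net)


class TestKmerSpectrum:
    @pytest.mark.parametrize(
        "seq,k,expect",
        [("AAAA", 2, {"AA": 3}), ("AAB", 2, {"AA": 1, "AB": 1}), ("ABC", 1, {"A": 1, "B": 1, "C": 1})],
    )
    def test_examples(self, seq, k, expect):
        assert kmer_spectrum(seq, k).counts == expect

    def test_total_count_property(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEF"), size=50))
        assert sum(kmer_spectrum(seq, 3).counts.values()) == 48

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kmer_spectrum("AB", 3)


class TestStringKernel:
    def test_identical_is_one(self):
        assert string_kernel("MKLV", "MKLV", 2) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert string_kernel("AAAA", "CCCC", 2) == 0.0

    def test_hand_computed_half(self):
        # spectra {AA:1, AB:1} and {AB:1, BA:1}: dot 1, norms sqrt(2) each
        assert string_kernel("AAB", "ABA", 2) == pytest.approx(0.5)

    def test_symmetry(self):
        assert string_kernel("MKLVWA", "MKAVWL", 2) == string_kernel("MKAVWL", "MKLVWA", 2)

    def test_gram_matrix_psd_unit_diagonal(self, data):
        from retrosig.predictors import _gram

        seqs = data["promiscuity_sequences"][:12]
        G = _gram(seqs, 3)
        assert np.allclose(np.diag(G), 1.0)
        assert np.all(np.linalg.eigvalsh(G) > -1e-8)


class TestPromiscuity:
    def test_single_reaction_scores_zero(self, net):
        enz = EnzymeSequence("e", "MKLV" * 20, reaction_ids=["R01"])
        assert promiscuity_score(enz, net) == 0.0

    def test_identical_reactions_score_zero(self, net):
        enz = EnzymeSequence("e", "MKLV" * 20, reaction_ids=["R01", "R01"])
        assert promiscuity_score(enz, net) == 0.0

    def test_complement_of_min_similarity(self, net, config):
        rids = sorted(net.reactions)[:3]
        enz = EnzymeSequence("e", "MKLV" * 20, reaction_ids=rids)
        M = similarity_matrix(net, rids, config.height, config)
        pairs = [M[i, j] for i, j in itertools.combinations(range(3), 2)]
        assert promiscuity_score(enz, net) == pytest.approx(1.0 - min(pairs))

    def test_order_invariance(self, net):
        rids = sorted(net.reactions)[:3]
        a = EnzymeSequence("a", "MKLV" * 20, reaction_ids=rids)
        b = EnzymeSequence("b", "MKLV" * 20, reaction_ids=rids[::-1])
        assert promiscuity_score(a, net) == promiscuity_score(b, net)

    def test_classifier_recovers_planted_motif(self, data):
        seqs = data["promiscuity_sequences"]
        labels = data["promiscuity_labels"]
        n_train = 120
        clf = PromiscuityClassifier(k=3, seed=0).fit(seqs[:n_train], labels[:n_train])
        from sklearn.metrics import roc_auc_score

        p = clf.predict(seqs[n_train:])
        assert roc_auc_score(labels[n_train:], p) > 0.9

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            PromiscuityClassifier().fit(["MKLV" * 10, "MKAV" * 10], [1, 1])

    def test_untrained_predict_rejected(self):
        with pytest.raises(ValueError):
            PromiscuityClassifier().predict(["MKLV" * 10])


class TestClustering:
    def test_two_well_separated_groups(self, net):
        # two copies of each of two chemically unrelated reactions
        rids = ["R01", "R05"]
        # build a 4-reaction set by duplicating ids in the distance space
        cl = cluster_reactions(net, sorted(net.reactions), h=2, n_range=range(2, 6))
        assert cl.n in cl.silhouettes
        assert all(-1.0 <= s <= 1.0 for s in cl.silhouettes.values())
        assert cl.n == max(cl.silhouettes, key=lambda n: (cl.silhouettes[n], -n))

    def test_matches_reference_linkage(self, net, config):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rids = sorted(net.reactions)
        cl = cluster_reactions(net, rids, h=2)
        D = 1.0 - similarity_matrix(net, rids, 2, config)
        np.fill_diagonal(D, 0.0)
        ref = fcluster(linkage(squareform(D, checks=False), "average"), cl.n, "maxclust")
        # same partition up to label renaming
        mapping = {}
        for a, b in zip(cl.labels.tolist(), ref.tolist()):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_fewer_than_two_rejected(self, net):
        with pytest.raises(ValueError):
            cluster_reactions(net, ["R01"], h=2)

    def test_identical_reactions_single_cluster(self):
        spec = FixtureSpec(seed=5, n_pairs=1)
        net = generate_toy_network(spec)
        from retrosig.network import enumerate_emrs

        emrs = enumerate_emrs(net, 1)
        # a putative reaction and its parent share the signature: at the
        # generation height all pairwise distances within the family are 0
        fam = ["R20", "R20~emrs0"]
        cl = cluster_reactions(emrs, fam, h=1)
        assert cl.n == 1


class TestTensorKernel:
    def test_identical_pairs_one(self, net):
        s = "MKLVWA" * 10
        assert tensor_kernel(s, "R01", s, "R01", net) == pytest.approx(1.0)

    def test_orthogonal_sequences_zero(self, net):
        assert tensor_kernel("AAAAAA" * 5, "R01", "CCCCCC" * 5, "R01", net) == 0.0

    def test_factorisation(self, net, config):
        from retrosig.predictors import reaction_pair_similarity

        s1, s2 = "MKLVWA" * 10, "MKAVWL" * 10
        expect = string_kernel(s1, s2, config.kmer) * reaction_pair_similarity(
            net, "R01", "R05", config.height, config
        )
        assert tensor_kernel(s1, "R01", s2, "R05", net) == pytest.approx(expect)


class TestCandidateEnzymes:
    def test_known_reaction_ranks_its_enzyme_first(self, net, data, config):
        enzymes = data["enzymes"]
        cl = cluster_reactions(net, sorted(net.reactions), h=config.height, config=config)
        rstar = enzymes[0].reaction_ids[0]
        ranked = candidate_enzymes(
            net, rstar, enzymes, cl, config, trained_min_positives=10**9
        )
        assert ranked
        top_ids = [e.id for e, _ in ranked if _ == ranked[0][1]]
        holders = {e.id for e in enzymes if rstar in e.reaction_ids}
        assert holders & set(e.id for e, s in ranked if s == ranked[0][1])

    def test_empty_database_rejected(self, net, config):
        cl = cluster_reactions(net, sorted(net.reactions), h=2, config=config)
        with pytest.raises(ValueError):
            candidate_enzymes(net, "R01", [], cl, config)

    def test_deterministic(self, net, data, config):
        cl = cluster_reactions(net, sorted(net.reactions), h=config.height, config=config)
        a = candidate_enzymes(net, "R01", data["enzymes"], cl, config)
        b = candidate_enzymes(net, "R01", data["enzymes"], cl, config)
        assert [(e.id, s) for e, s in a] == [(e.id, s) for e, s in b]


class TestPerformance:
    def test_recovers_planted_split(self, net, data, config):
        enzymes = {e.id: e for e in data["enzymes"]}
        cl = cluster_reactions(net, sorted(net.reactions), h=config.height, config=config)
        spec = FixtureSpec(seed=3)
        model = train_performance_model(
            data["kinetics"], enzymes, net, cl, min_records=5
        )
        # the tree should explain the planted split: raw prediction error
        # below the planted noise level for records in fitted clusters
        errs = []
        for r in data["kinetics"]:
            yhat = model.predict_efficiency(r.reaction_id, enzymes[r.enzyme_id], config)
            if yhat is not None:
                errs.append(yhat - r.efficiency())
        assert errs, "no cluster had enough records to fit"
        assert float(np.sqrt(np.mean(np.square(errs)))) < spec.kinetic_noise

    def test_training_max_normalises_to_one(self, net, data, config):
        enzymes = {e.id: e for e in data["enzymes"]}
        cl = cluster_reactions(net, sorted(net.reactions), h=config.height, config=config)
        model = train_performance_model(data["kinetics"], enzymes, net, cl, min_records=3)
        best = max(data["kinetics"], key=lambda r: r.efficiency())
        p = model.perf(best.reaction_id, enzymes[best.enzyme_id], config)
        assert 0.0 <= p <= 1.0

    def test_missing_cluster_falls_back(self, net, config):
        cl = cluster_reactions(net, sorted(net.reactions), h=2, config=config)
        model = train_performance_model([], {}, net, cl)
        enz = EnzymeSequence("e", "MKLV" * 20)
        assert model.perf("R01", enz, config) == 0.5

    def test_nonpositive_kinetics_rejected(self):
        with pytest.raises(ValueError):
            KineticRecord("e", "r", -1.0, 1e-4)


class TestCompatibility:
    def test_gc_content(self):
        assert gc_content("GGCC") == 1.0
        assert gc_content("ATAT") == 0.0

    def test_self_distance_zero(self, data):
        taxo = Taxonomy(data["taxonomy_edges"])
        assert taxo.distance("ECO", "ECO") == 0.0
        assert taxo.distance("ECO", "ORG1") == 2.0

    def test_planted_separation_recovered(self, data):
        taxo = Taxonomy(data["taxonomy_edges"])
        model = train_compatibility(data["enzymes"], "ECO", taxo, seed=0)
        pos = [model.het(e) for e in data["enzymes"] if e.organism == "ECO"]
        neg = [model.het(e) for e in data["enzymes"] if e.organism != "ECO"]
        assert np.mean(pos) > np.mean(neg)
        assert all(0.0 <= h <= 1.0 for h in pos + neg)

    def test_untrained_rejected(self):
        with pytest.raises(ValueError):
            CompatibilityModel("ECO").het(EnzymeSequence("e", "MKLV" * 10))

    def test_descriptors_without_nucleotide_sequence(self):
        d = compatibility_descriptors(EnzymeSequence("e", "MKLV" * 10), "ECO", None)
        assert d["gc_content"] is None and d["phylo_distance"] is None
        assert d["length"] == 40


class TestGeneRankPvalue:
    @pytest.mark.parametrize("rank,total,expect", [(1, 20, 0.05), (20, 20, 1.0), (5, 100, 0.05)])
    def test_examples(self, rank, total, expect):
        assert gene_rank_pvalue(rank, total) == pytest.approx(expect)

    def test_invalid_rank(self):
        with pytest.raises(ValueError):
            gene_rank_pvalue(0, 10)
        with pytest.raises(ValueError):
            gene_rank_pvalue(11, 10)


class TestToxicity:
    def test_inverse_ic50_definition(self, data):
        model = train_toxicity(data["toxicity"])
        c, _ = data["toxicity"][0]
        assert model.tox(c) == pytest.approx(1.0 / model.predict_ic50(c))

    def test_noiseless_linear_data_high_q2(self, data):
        model = train_toxicity(data["toxicity"], components=3)
        assert model.q2 is not None and model.q2 > 0.95

    def test_too_few_records_rejected(self, data):
        with pytest.raises(ValueError):
            train_toxicity(data["toxicity"][:5])

    def test_nonpositive_ic50_rejected(self, data):
        bad = [(c, -1.0) for c, _ in data["toxicity"]]
        with pytest.raises(ValueError):
            train_toxicity(bad)
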
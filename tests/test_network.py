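"""Extended reaction space generation and thermodynamic filtering."""

import itertools

import pytest

from retrosig.config import RunConfig
from retrosig.fixtures import FixtureSpec, generate_toy_network
from retrosig.network import (
    Compound,
    GroupContributionTable,
    MetabolicNetwork,
    NetworkReaction,
    UnsupportedHeightError,
    compound_gibbs,
    emrs_statistics,
    enumerate_emrs,
    feasibility_filter,
    reaction_gibbs,
    signature_classes,
)
from retrosig.signatures import MolecularGraph


def mk_compound(cid, smiles, endo=False):
    return Compound(cid, MolecularGraph.from_smiles(smiles, name=cid), endo)


class TestSignatureClasses:
    def test_planted_pair_merges_at_h1_separates_at_h3(self, toy_network):
        cls1 = signature_classes(toy_network, 1)
        together = [c for c in cls1.values() if {"ETH_A0", "ETH_B0"} <= set(c)]
        assert len(together) == 1
        cls3 = signature_classes(toy_network, 3)
        assert not any({"ETH_A0", "ETH_B0"} <= set(c) for c in cls3.values())

    def test_partition_is_disjoint_and_exhaustive(self, toy_network):
        for h in (1, 2, 3):
            classes = signature_classes(toy_network, h)
            members = sorted(itertools.chain.from_iterable(classes.values()))
            assert members == sorted(toy_network.compounds)

    def test_all_singletons_beyond_diameter(self, toy_network):
        h = max(c.structure.diameter() for c in toy_network.compounds.values())
        classes = signature_classes(toy_network, h)
        assert all(len(v) == 1 for v in classes.values())

    def test_empty_network(self):
        assert signature_classes(MetabolicNetwork(), 1) == {}


def brute_force_substitutions(net, h):
    """Independent oracle: try every compound in every role of every
    nominal reaction, keep exact molecular-signature matches, dedup."""
    keys = {cid: net.compounds[cid].signature_key(h) for cid in net.compounds}
    seen = {r.participant_key() for r in net.reactions.values()}
    out = set()
    for rxn in net.nominal_reactions():
        roles = [cid for _, cid in rxn.substrates + rxn.products]
        options = [
            sorted(c for c in net.compounds if keys[c] == keys[cid]) for cid in roles
        ]
        n_subs = len(rxn.substrates)
        for combo in itertools.product(*options):
            if list(combo) == roles:
                continue
            subs = tuple(sorted((k, combo[i]) for i, (k, _) in enumerate(rxn.substrates)))
            prods = tuple(
                sorted((k, combo[n_subs + i]) for i, (k, _) in enumerate(rxn.products))
            )
            if subs == prods:
                continue
            key = (subs, prods, rxn.direction)
            if key not in seen:
                seen.add(key)
                out.add(key)
    return out


class TestEnumerateEmrs:
    def test_height_zero_unsupported(self, toy_network):
        with pytest.raises(UnsupportedHeightError):
            enumerate_emrs(toy_network, 0)

    def test_putative_signatures_match_parent(self, toy_network):
        for h in (1, 2):
            emrs = enumerate_emrs(toy_network, h)
            for r in emrs.putative_reactions():
                assert (
                    emrs.reaction_signature_of(r.id, h).entries
                    == emrs.reaction_signature_of(r.parent_id, h).entries
                )

    def test_nominal_reactions_retained_unchanged(self, toy_network):
        emrs = enumerate_emrs(toy_network, 1)
        for rid, r in toy_network.reactions.items():
            assert emrs.reactions[rid].participant_key() == r.participant_key()

    def test_matches_brute_force_oracle(self, toy_network, toy_network_two_pairs):
        for net in (toy_network, toy_network_two_pairs):
            for h in (1, 2, 3):
                emrs = enumerate_emrs(net, h)
                got = {r.participant_key() for r in emrs.putative_reactions()}
                assert got == brute_force_substitutions(net, h)

    def test_no_duplicates_by_participants(self, toy_network_two_pairs):
        emrs = enumerate_emrs(toy_network_two_pairs, 1)
        keys = [r.participant_key() for r in emrs.reactions.values()]
        assert len(keys) == len(set(keys))

    def test_no_putative_beyond_diameter(self, toy_network):
        h = max(c.structure.diameter() for c in toy_network.compounds.values())
        assert enumerate_emrs(toy_network, h).putative_reactions() == []

    def test_elemental_balance_matches_parent(self, toy_network):
        emrs = enumerate_emrs(toy_network, 1)
        for r in emrs.putative_reactions():
            assert (
                emrs.reaction_signature_of(r.id, 0).entries
                == emrs.reaction_signature_of(r.parent_id, 0).entries
            )

    def test_deterministic_output_order(self, toy_network):
        a = list(enumerate_emrs(toy_network, 1).reactions)
        b = list(enumerate_emrs(toy_network, 1).reactions)
        assert a == b


class TestGibbs:
    def table_for(self, *compounds, value=-10.0):
        sigs = {
            s
            for c in compounds
            for s in c.signature(1).entries
        }
        return GroupContributionTable({s: value for s in sigs}, 1)

    def test_identity_reaction_zero(self):
        a = mk_compound("A", "CCO")
        net = MetabolicNetwork([a, mk_compound("B", "CCN")], [
            NetworkReaction("r", "", [(1, "A")], [(1, "B")])
        ])
        table = self.table_for(*net.compounds.values())
        g = reaction_gibbs(net.reactions["r"], net, table)
        ga = compound_gibbs(net.compounds["A"], table)
        gb = compound_gibbs(net.compounds["B"], table)
        assert g == pytest.approx(gb - ga)

    def test_toy_arithmetic(self):
        a = mk_compound("A", "C")   # one subgroup
        b = mk_compound("B", "O")
        net = MetabolicNetwork([a, b], [NetworkReaction("r", "", [(1, "A")], [(1, "B")])])
        table = GroupContributionTable(
            {next(iter(a.signature(1).entries)): -10.0,
             next(iter(b.signature(1).entries)): -30.0}, 1)
        assert reaction_gibbs(net.reactions["r"], net, table) == pytest.approx(-20.0)

    def test_stoichiometric_weighting(self):
        a = mk_compound("A", "C")
        b = mk_compound("B", "O")
        net = MetabolicNetwork([a, b], [NetworkReaction("r", "", [(2, "A")], [(1, "B")])])
        table = GroupContributionTable(
            {next(iter(a.signature(1).entries)): -5.0,
             next(iter(b.signature(1).entries)): -30.0}, 1)
        assert reaction_gibbs(net.reactions["r"], net, table) == pytest.approx(-20.0)

    def test_missing_subgroup_gives_unset(self):
        a = mk_compound("A", "CCO")
        b = mk_compound("B", "CCN")
        net = MetabolicNetwork([a, b], [NetworkReaction("r", "", [(1, "A")], [(1, "B")])])
        assert reaction_gibbs(net.reactions["r"], net, GroupContributionTable({}, 1)) is None


class TestFeasibilityFilter:
    def test_infinite_threshold_is_identity(self, toy_network, toy_group_table):
        emrs = enumerate_emrs(toy_network, 1)
        kept = feasibility_filter(emrs, toy_group_table, threshold=float("inf"))
        assert sorted(kept.reactions) == sorted(emrs.reactions)

    def test_nominal_never_removed(self, toy_network, toy_group_table):
        emrs = enumerate_emrs(toy_network, 1)
        kept = feasibility_filter(emrs, toy_group_table, threshold=-1e9)
        assert {r.id for r in kept.nominal_reactions()} == {
            r.id for r in emrs.nominal_reactions()
        }

    def test_unscored_reactions_retained_and_flagged(self, toy_network):
        emrs = enumerate_emrs(toy_network, 1)
        kept = feasibility_filter(emrs, GroupContributionTable({}, 1), threshold=0.0)
        assert sorted(kept.reactions) == sorted(emrs.reactions)
        assert all("unscored" in r.flags for r in kept.reactions.values())

    def test_matches_independent_recomputation(self, toy_network, toy_group_table, config):
        emrs = enumerate_emrs(toy_network, 1)
        kept = feasibility_filter(emrs, toy_group_table, threshold=0.0, config=config)
        cut = 0.0 + config.gibbs_tolerance
        for r in emrs.putative_reactions():
            dg = reaction_gibbs(r, emrs, toy_group_table)
            expected_kept = dg is None or dg <= cut or (
                r.direction == "reversible" and -dg <= cut
            )
            assert (r.id in kept.reactions) == expected_kept


class TestEmrsStatistics:
    def test_nominal_only_network_zero_increase(self):
        net = MetabolicNetwork(
            [mk_compound("A", "CCO", True), mk_compound("B", "CCN")],
            [NetworkReaction("r", "", [(1, "A")], [(1, "B")])],
            chassis=["A"],
        )
        stats = emrs_statistics(net, [1, 2, 3])
        assert (stats["pct_increase"] == 0.0).all()

    def test_counts_non_increasing_with_height(self, toy_network_two_pairs):
        stats = emrs_statistics(toy_network_two_pairs, [1, 2, 3, 4])
        counts = stats["reactions"].tolist()
        assert counts == sorted(counts, reverse=True)
        assert stats["pct_increase"].iloc[0] > 0.0

    def test_empty_height_list(self, toy_network):
        assert len(emrs_statistics(toy_network, [])) == 0
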
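"""Fisher exact test, hit grouping, Dollo dating and conservation tallies."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopept import evostats as es
from isopept import synthetic_data as sd
from isopept.evostats import (
    ContingencyTable,
    HitRecord,
    SpeciesPresence,
    assign_hits_to_genes,
    conservation_fraction,
    dollo_origin,
    fisher_exact,
    load_tree,
    node_label,
)


def brute_force_fisher_two_sided(a, b, c, d):
    """Oracle: enumerate every table with the observed margins and sum the
    probabilities of those no more likely than the observed table."""
    n, row1, col1 = a + b + c + d, a + b, a + c

    def prob(k):
        return comb(row1, k) * comb(n - row1, col1 - k) / comb(n, col1)

    p_obs = prob(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_equal_proportions_give_p_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5))["p_value"] == pytest.approx(1.0)

    def test_matches_enumeration_for_worked_example(self):
        out = fisher_exact(ContingencyTable(3, 7, 6, 4))
        assert out["p_value"] == pytest.approx(brute_force_fisher_two_sided(3, 7, 6, 4))

    def test_exhaustive_sweep_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            assert fisher_exact(ContingencyTable(a, b, c, d))["p_value"] == pytest.approx(
                brute_force_fisher_two_sided(a, b, c, d)
            )

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    @settings(max_examples=300, derandomize=True)
    def test_random_tables_up_to_n60_match_oracle_and_scipy(self, cells):
        from scipy.stats import fisher_exact as scipy_fisher

        a, b, c, d = cells
        if 0 in (a + b, c + d, a + c, b + d) or a + b + c + d > 60:
            return
        ours = fisher_exact(ContingencyTable(a, b, c, d))["p_value"]
        assert ours == pytest.approx(brute_force_fisher_two_sided(a, b, c, d))
        assert ours == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(0, 0, 3, 4))

    def test_odds_ratio_with_zero_cells_uses_continuity(self):
        out = fisher_exact(ContingencyTable(5, 0, 1, 4))
        assert np.isfinite(out["odds_ratio"]) and out["odds_ratio"] > 1


class TestDollo:
    TREE = "(lamprey,(zebrafish,(fugu,human))jawed)root;"

    def test_single_species_origin_is_terminal_branch(self):
        tree = load_tree(self.TREE)
        node = dollo_origin(SpeciesPresence("f", {"human": True}), tree)
        assert node_label(node) == "human"

    def test_human_plus_zebrafish_dates_to_jawed_ancestor(self):
        tree = load_tree(self.TREE)
        node = dollo_origin(
            SpeciesPresence("f", {"human": True, "zebrafish": True, "lamprey": False}),
            tree,
        )
        assert node_label(node) == "jawed"

    def test_presence_in_any_distant_species_predates_their_split(self):
        tree = load_tree(sd.SPECIES_TREE)
        for other in ("lamprey", "spotted gar", "fugu", "zebrafish", "coelacanth"):
            node = dollo_origin(
                SpeciesPresence("f", {"human": True, other: True}), tree
            )
            # origin must be an ancestor of both leaves, hence internal
            assert node.is_internal()

    def test_no_present_species_raises(self):
        tree = load_tree(self.TREE)
        with pytest.raises(ValueError):
            dollo_origin(SpeciesPresence("f", {"human": False}), tree)

    def test_unknown_species_raises(self):
        tree = load_tree(self.TREE)
        with pytest.raises(KeyError):
            dollo_origin(SpeciesPresence("f", {"martian": True}), tree)

    def test_adding_presence_never_makes_origin_more_recent(self):
        tree = load_tree(sd.SPECIES_TREE)
        leaves = sorted(t.label for t in tree.taxon_namespace)
        rng = np.random.default_rng(6)

        def depth(node):
            d = 0
            while node.parent_node is not None:
                node, d = node.parent_node, d + 1
            return d

        for _ in range(40):
            base = {"human"} | set(
                rng.choice(leaves, size=rng.integers(0, 3), replace=False)
            )
            extra = str(rng.choice(leaves))
            d_base = depth(dollo_origin(SpeciesPresence("f", {s: True for s in base}), tree))
            d_more = depth(
                dollo_origin(
                    SpeciesPresence("f", {s: True for s in base | {extra}}), tree
                )
            )
            assert d_more <= d_base


class TestHitAssignment:
    def test_hit_within_window_assigned_to_gene(self):
        hits = [HitRecord("q", "sp", "c1", 10_500, 10_560)]
        genes = {"sp": [("g1", "c1", 2_000, 9_500)]}
        out = assign_hits_to_genes(hits, genes, {"sp": [1000, 2000, 50_000]})
        assert out[hits[0]] == "g1"

    def test_far_hits_become_separate_loci(self):
        hits = [
            HitRecord("q1", "sp", "c1", 1_000_000, 1_000_060),
            HitRecord("q2", "sp", "c1", 1_400_000, 1_400_060),
        ]
        out = assign_hits_to_genes(hits, {"sp": []}, {"sp": [1000, 2000, 50_000]})
        assert len(set(out.values())) == 2

    def test_matches_single_linkage_oracle(self):
        rng = np.random.default_rng(13)
        window = 10_000
        starts = np.sort(rng.integers(0, 2_000_000, size=100))
        hits = [HitRecord(f"q{i}", "sp", "c1", int(s), int(s) + 60)
                for i, s in enumerate(starts)]
        out = assign_hits_to_genes(
            hits, {"sp": []}, {"sp": [window] * 20}, window_quantile=0.95
        )
        # oracle: single-linkage clusters on the sorted intervals
        clusters, last_end = 0, None
        oracle = {}
        for h in sorted(hits, key=lambda h: h.start):
            if last_end is None or h.start - last_end > window:
                clusters += 1
            oracle[h] = clusters
            last_end = h.end
        ours_groups = {}
        for h, locus in out.items():
            ours_groups.setdefault(locus, set()).add(h.query_exon_id)
        oracle_groups = {}
        for h, c in oracle.items():
            oracle_groups.setdefault(c, set()).add(h.query_exon_id)
        assert sorted(ours_groups.values(), key=sorted) == sorted(
            oracle_groups.values(), key=sorted
        )

    def test_synthetic_hit_tables_assign_to_planted_genes(self):
        fix = sd.generate_species_fixtures(n_features=30, seed=4)
        hits = [
            HitRecord(r.query_exon_id, r.species, r.chrom, int(r.start), int(r.end))
            for r in fix.hits.itertuples(index=False)
        ]
        genes = {
            sp: [(r.gene_id, r.chrom, int(r.start), int(r.end))
                 for r in df.itertuples(index=False)]
            for sp, df in fix.species_genes.items()
        }
        lengths = {sp: df["length"].tolist() for sp, df in fix.species_genes.items()}
        out = assign_hits_to_genes(hits, genes, lengths)
        for hit, assigned in out.items():
            want = fix.hit_truth.get((hit.query_exon_id, hit.species, hit.start))
            if want == "novel":
                assert "novel_locus" in assigned
            elif want is not None:
                assert assigned == want


class TestConservationFraction:
    def test_zero_and_full(self):
        assert conservation_fraction({"e1": False, "e2": False}) == 0.0
        assert conservation_fraction({"e1": True, "e2": True}) == 1.0

    def test_planted_fraction(self):
        calls = {f"e{i}": i < 193 for i in range(1000)}
        assert conservation_fraction(calls) == pytest.approx(0.193)

    def test_order_invariant(self):
        calls = {f"e{i}": i % 3 == 0 for i in range(50)}
        shuffled = dict(sorted(calls.items(), reverse=True))
        assert conservation_fraction(calls) == conservation_fraction(shuffled)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            conservation_fraction({})
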
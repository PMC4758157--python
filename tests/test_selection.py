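"""Ancestral reconstruction, site counting, selection calls, group tests."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats

from interevol.selection import (
    benjamini_hochberg,
    classify_alignment_sites,
    classify_site,
    compare_selection_groups,
    count_site_substitutions,
    parsimony_ancestral_codons,
    region_selection_proportions,
    resolve_polytomies,
)
from interevol.simulate import ScenarioConfig, gen_codon_alignment


class TestFitchParsimony:
    def test_identical_leaves_propagate_to_all_ancestors(self):
        tree = "((a:1,b:1):1,(c:1,d:1):1);"
        recon = parsimony_ancestral_codons(
            tree, {t: "ATG" for t in "abcd"}
        )
        assert all(c == ["ATG"] for c in recon.codons.values())
        assert recon.substitution_count == 0

    def test_two_leaf_tie_breaks_lexicographically(self):
        recon = parsimony_ancestral_codons(
            "(a:1,b:1);", {"a": "TTT", "b": "TTC"}
        )
        root = recon.tree.seed_node
        assert recon.codons[id(root)][0] == "TTC"  # TTC < TTT

    def test_taxon_mismatch_lists_missing(self):
        with pytest.raises(ValueError, match="extra"):
            parsimony_ancestral_codons("(a:1,extra:1);", {"a": "TTT", "b": "TTT"})

    def test_counts_match_brute_force_on_small_trees(self):
        """Fitch parsimony equals exhaustive minimisation over labelings."""

        def brute_force_min(tree, leaf_states):
            t = dendropy.Tree.get(data=tree, schema="newick")
            internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
            observed = sorted(set(leaf_states.values()))
            best = None
            for labels in itertools.product(observed, repeat=len(internal)):
                assign = dict(zip(map(id, internal), labels))
                for leaf in t.leaf_node_iter():
                    assign[id(leaf)] = leaf_states[leaf.taxon.label]
                changes = sum(
                    assign[id(n)] != assign[id(n.parent_node)]
                    for n in t.preorder_node_iter()
                    if n.parent_node is not None
                )
                best = changes if best is None else min(best, changes)
            return best

        rng = np.random.default_rng(12)
        codons = ["TTT", "TTC", "TTA", "ATG", "GGG"]
        trees = [
            "((a:1,b:1):1,(c:1,d:1):1);",
            "(((a:1,b:1):1,c:1):1,(d:1,e:1):1);",
            "((a:1,(b:1,c:1):1):1,((d:1,e:1):1,f:1):1);",
        ]
        for tree in trees:
            taxa = sorted(
                leaf.taxon.label
                for leaf in dendropy.Tree.get(
                    data=tree, schema="newick"
                ).leaf_node_iter()
            )
            for _ in range(10):
                leaf_states = {t: str(rng.choice(codons)) for t in taxa}
                recon = parsimony_ancestral_codons(
                    tree, {t: s for t, s in leaf_states.items()}
                )
                assert recon.substitution_count == brute_force_min(
                    tree, leaf_states
                )

    def test_polytomy_resolution_is_deterministic_and_binary(self):
        tree1 = resolve_polytomies(
            dendropy.Tree.get(data="(a:1,b:1,c:1,d:1);", schema="newick")
        )
        tree2 = resolve_polytomies(
            dendropy.Tree.get(data="(a:1,b:1,c:1,d:1);", schema="newick")
        )
        for t in (tree1, tree2):
            assert all(
                len(n.child_nodes()) in (0, 2) for n in t.preorder_node_iter()
            )
        assert tree1.as_string(schema="newick") == tree2.as_string(schema="newick")


class TestSiteCounting:
    def test_single_branch_synonymous(self):
        recon = parsimony_ancestral_codons(
            "(a:1,b:1);", {"a": "TTT", "b": "TTC"}
        )
        n, s, en, es = count_site_substitutions(recon, 0)
        assert (n, s) == (0.0, 1.0)  # Phe -> Phe

    def test_single_branch_nonsynonymous(self):
        recon = parsimony_ancestral_codons(
            "(a:1,b:1);", {"a": "TTT", "b": "TTA"}
        )
        n, s, _, _ = count_site_substitutions(recon, 0)
        assert (n, s) == (1.0, 0.0)  # Phe -> Leu

    def test_expected_sites_scale_with_observed_total(self):
        recon = parsimony_ancestral_codons(
            "(a:1,b:1);", {"a": "TTT", "b": "TTC"}
        )
        n, s, en, es = count_site_substitutions(recon, 0)
        assert en + es == pytest.approx(n + s)
        # all codons at this column are TTT/TTC: site fractions 8/9 vs 1/9
        assert en / (en + es) == pytest.approx(8 / 9)

    def test_stop_codon_is_an_error_naming_site(self):
        with pytest.raises(ValueError, match="site 0"):
            recon = parsimony_ancestral_codons(
                "(a:1,b:1);", {"a": "TGA", "b": "TGA"}
            )
            count_site_substitutions(recon, 0)


class TestClassifySite:
    def test_pure_synonymous_run_is_negative(self):
        # N=0, S=5 with neutral nonsynonymous share 0.75:
        # lower tail = 0.25^5, doubled by the two-tailed convention
        site = classify_site(0, n_obs=0, s_obs=5, en=7.5, es=2.5)
        assert site.selection_class == "negative"
        assert site.p_value == pytest.approx(2 * 0.25**5)

    def test_proportional_counts_are_neutral(self):
        site = classify_site(0, n_obs=3, s_obs=1, en=7.5, es=2.5)
        assert site.selection_class == "neutral"

    def test_no_substitutions_is_neutral_by_definition(self):
        site = classify_site(0, n_obs=0, s_obs=0, en=0, es=0)
        assert site.selection_class == "neutral"
        assert site.p_value == 1.0

    def test_excess_nonsynonymous_is_positive(self):
        site = classify_site(0, n_obs=12, s_obs=0, en=6, es=6)
        assert site.selection_class == "positive"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify_site(0, n_obs=-1, s_obs=0, en=1, es=1)

    def test_binomial_oracle_over_grid(self):
        """p-values equal the doubled binomial tail computed directly."""
        for n_obs, s_obs, p_neutral in [
            (0, 5, 0.75),
            (2, 8, 0.5),
            (9, 1, 0.6),
            (4, 4, 0.75),
        ]:
            total = n_obs + s_obs
            site = classify_site(
                0, n_obs, s_obs, en=p_neutral * total, es=(1 - p_neutral) * total
            )
            lower = stats.binom.cdf(n_obs, total, p_neutral)
            upper = stats.binom.sf(n_obs - 1, total, p_neutral)
            assert site.p_value == pytest.approx(min(1.0, 2 * min(lower, upper)))


class TestCalibrationAndPower:
    def test_type_i_error_controlled_at_neutral_sites(self):
        cfg = ScenarioConfig(seed=71, site_classes=(("neutral", 1.0, 1000),))
        alignment, _ = gen_codon_alignment(cfg)
        sites = classify_alignment_sites(cfg.tree, alignment)
        non_neutral = sum(s.selection_class != "neutral" for s in sites)
        # <= alpha plus 3 sigma binomial slack
        bound = 0.05 + 3 * (0.05 * 0.95 / 1000) ** 0.5
        assert non_neutral / 1000 <= bound

    def test_power_monotone_in_purifying_strength(self):
        fracs = []
        for omega in (0.5, 0.1, 0.01):
            cfg = ScenarioConfig(seed=72, site_classes=(("w", omega, 400),))
            alignment, _ = gen_codon_alignment(cfg)
            sites = classify_alignment_sites(cfg.tree, alignment)
            fracs.append(
                sum(s.selection_class == "negative" for s in sites) / 400
            )
        assert fracs[0] < fracs[1] < fracs[2]


class TestGroupComparisons:
    def test_bh_closed_form(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_in_rank_order(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(size=25)
        adjusted = benjamini_hochberg(raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_identical_groups_not_significant(self):
        g = {"x": [0.5, 0.6, 0.7, 0.8], "y": [0.5, 0.6, 0.7, 0.8]}
        report = compare_selection_groups(g)
        assert report["pairwise"][0]["p_raw"] > 0.9

    def test_mann_whitney_matches_exhaustive_permutation(self):
        """Exact Mann-Whitney p equals full enumeration of group relabelings."""
        x = [1.2, 3.4, 5.1, 2.2]
        y = [4.5, 6.1, 7.0]
        u_obs, p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided")
        pooled = x + y
        n_x = len(x)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_x):
            gx = [pooled[i] for i in idx]
            gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u, _ = stats.mannwhitneyu(gx, gy, alternative="two-sided")
            half = len(gx) * len(gy) / 2
            if abs(u - half) >= abs(u_obs - half) - 1e-12:
                count += 1
            total += 1
        assert p_scipy == pytest.approx(count / total)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_selection_groups({"only": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fewer than two"):
            compare_selection_groups({"a": [1.0], "b": [1.0, 2.0]})


class TestRegionProportions:
    def _sites(self, classes):
        return [
            classify_site(i, 0, 5, 7.5, 2.5)
            if c == "negative"
            else classify_site(i, 0, 0, 0, 0)
            for i, c in enumerate(classes)
        ]

    def test_all_negative_interface_gives_proportion_one(self):
        sites = self._sites(["negative", "negative", "neutral"])
        props = region_selection_proportions(sites, [True, True, False])
        assert props["interface"]["negative"] == 1.0
        assert props["non_interface"]["neutral"] == 1.0

    def test_empty_interface_region_is_none(self):
        sites = self._sites(["neutral", "neutral"])
        props = region_selection_proportions(sites, [False, False])
        assert props["interface"] is None

    def test_planted_omega_contrast_separates_regions(self):
        cfg = ScenarioConfig(seed=73)
        per_site = [("interface", 0.05)] * 60 + [("non_interface", 1.0)] * 140
        alignment, _ = gen_codon_alignment(cfg, per_site_omegas=per_site)
        sites = classify_alignment_sites(cfg.tree, alignment)
        mask = [label == "interface" for label, _ in per_site]
        props = region_selection_proportions(sites, mask)
        assert props["interface"]["negative"] > props["non_interface"]["negative"]
        assert props["non_interface"]["neutral"] > 0.9
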
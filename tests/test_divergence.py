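"""Interface mapping, substitution counting, relative rates, Ka/Ks, matrix."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from interevol.codons import ng86_site_counts, pathway_counts
from interevol.constants import GENETIC_CODE, MATRIX_ALPHABET
from interevol.divergence import (
    DivergenceCall,
    DuplicatePair,
    RegionCounts,
    build_substitution_matrix,
    classify_pair_divergence,
    contingency_table,
    count_substitutions,
    map_interface_to_alignment,
    pairwise_divergence,
    relative_interface_rate,
)
from interevol.network import EvidenceRecord, PairExcluded, build_network
from interevol.simulate import ScenarioConfig, gen_duplicate_pair, gen_toy_complex


def _pair(seq_a, seq_b, iface_a=frozenset(), iface_b=frozenset(), **kw):
    return DuplicatePair(
        pair_id="t",
        gene_a="ga",
        gene_b="gb",
        aligned_seq_a=seq_a,
        aligned_seq_b=seq_b,
        interface_residues_a=frozenset(iface_a),
        interface_residues_b=frozenset(iface_b),
        **kw,
    )


class TestInterfaceMapping:
    def test_ungapped_residues_map_to_their_columns(self):
        pair = _pair("ACDEFGHIKL", "ACDEFGHIKL", iface_a={3, 5})
        cols = map_interface_to_alignment(pair)
        assert list(np.flatnonzero(cols)) == [2, 4]  # 0-based columns

    def test_gap_shifts_interface_columns(self):
        # member A has a gap at column 2, so A's residue 3 sits in column 3
        pair = _pair("AC-DEFGHIK", "ACMDEFGHIK", iface_a={3})
        cols = map_interface_to_alignment(pair)
        assert list(np.flatnonzero(cols)) == [3]

    def test_either_member_can_mark_a_column(self):
        pair = _pair("ACDEF", "ACDEF", iface_a={1}, iface_b={5})
        assert list(np.flatnonzero(map_interface_to_alignment(pair))) == [0, 4]

    def test_empty_interface_means_all_non_interface(self):
        pair = _pair("ACDEF", "ACDEF")
        assert not map_interface_to_alignment(pair).any()

    def test_residue_beyond_length_is_an_error(self):
        pair = _pair("ACDEF", "ACDEF", iface_a={6})
        with pytest.raises(ValueError, match="beyond"):
            map_interface_to_alignment(pair)


class TestSubstitutionCounting:
    def test_identical_sequences_count_zero(self):
        pair = _pair("ACDEF", "ACDEF", iface_a={1})
        iface, non = count_substitutions(pair, map_interface_to_alignment(pair))
        assert (iface.n_subs, non.n_subs) == (0, 0)
        assert iface.n_sites + non.n_sites == 5

    def test_gap_column_is_a_gap_not_a_substitution(self):
        pair = _pair("ACDEF", "-CDEF")
        _, non = count_substitutions(pair, np.zeros(5, bool))
        assert (non.n_subs, non.n_gaps) == (0, 1)

    def test_planted_generator_densities_recovered(self):
        cfg = ScenarioConfig(
            seed=61,
            n_pairs=1,
            chain_length=1000,
            interface_size=500,
            p_sub_interface=0.1,
            p_sub_noninterface=0.2,
        )
        st, planted = gen_toy_complex(cfg)
        pair, _, truth = gen_duplicate_pair(st, planted, cfg, "big")
        cols = map_interface_to_alignment(pair)
        iface, non = count_substitutions(pair, cols)
        assert iface.n_sites == 500 and non.n_sites == 500
        assert iface.n_subs == sum(t.substituted for t in truth if t.interface)
        # a single pair at 500 sites/region is sampling-noise dominated
        # (sd ~ 15%); exact truth equality is asserted above, so only a
        # coarse consistency band is meaningful here
        rel = relative_interface_rate(iface, non)
        assert rel.ratio == pytest.approx(0.5, rel=0.45)
        assert not rel.excluded

    def test_region_sites_partition_alignment(self):
        pair = _pair("ACDEFGHIKL", "ACDEFGHIKL", iface_a={2, 7, 9})
        iface, non = count_substitutions(pair, map_interface_to_alignment(pair))
        assert iface.n_sites + non.n_sites == pair.n_columns


class TestRelativeRate:
    def _counts(self, region, sites, subs, gaps=0):
        return RegionCounts(region=region, n_sites=sites, n_subs=subs, n_gaps=gaps)

    def test_conserved_interface_gives_zero_ratio(self):
        rel = relative_interface_rate(
            self._counts("interface", 10, 0),
            self._counts("non_interface", 90, 9),
        )
        assert rel.ratio == 0.0 and rel.defined and not rel.excluded

    def test_filter_excludes_above_cap(self):
        rel = relative_interface_rate(
            self._counts("interface", 10, 5),  # rate 0.5
            self._counts("non_interface", 100, 20),  # rate 0.2 -> ratio 2.5
        )
        assert rel.ratio == pytest.approx(2.5)
        assert rel.excluded

    def test_ratio_exactly_two_is_retained(self):
        rel = relative_interface_rate(
            self._counts("interface", 10, 4),
            self._counts("non_interface", 100, 20),
        )
        assert rel.ratio == pytest.approx(2.0)
        assert not rel.excluded

    def test_zero_noninterface_rate_is_undefined_not_excluded(self):
        rel = relative_interface_rate(
            self._counts("interface", 10, 1),
            self._counts("non_interface", 90, 0),
        )
        assert not rel.defined and np.isnan(rel.ratio)

    def test_zero_sites_in_a_region_excludes_pair(self):
        with pytest.raises(PairExcluded, match="interface"):
            relative_interface_rate(
                self._counts("interface", 0, 0),
                self._counts("non_interface", 90, 9),
            )


class TestPairwiseDivergence:
    def test_identical_sequences_are_zero_everywhere(self):
        pair = _pair("FF", "FF", codon_seq_a="TTTTTT", codon_seq_b="TTTTTT")
        d = pairwise_divergence(pair)
        assert d["protein_divergence"] == 0.0
        assert d["p_n"] == 0.0 and d["p_s"] == 0.0
        assert d["ka"] == 0.0 and d["ks"] == 0.0

    def test_single_synonymous_change_moves_only_ks(self):
        pair = _pair("FF", "FF", codon_seq_a="TTTTTT", codon_seq_b="TTCTTT")
        d = pairwise_divergence(pair)
        assert d["p_n"] == 0.0
        assert d["p_s"] > 0.0

    def test_codon_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            _pair("FF", "FF", codon_seq_a="TTTTT", codon_seq_b="TTTTTT")

    def test_pathway_counts_match_exhaustive_permutation_oracle(self):
        """Recursive pathway averaging equals explicit enumeration of all
        substitution orders (stop-free pathways only)."""

        def oracle(a, b):
            diff = [i for i in range(3) if a[i] != b[i]]
            totals = []
            for order in itertools.permutations(diff):
                cur, n, s, ok = a, 0.0, 0.0, True
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    if GENETIC_CODE[nxt] == "*":
                        ok = False
                        break
                    if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                if ok:
                    totals.append((n, s))
            assert totals, "oracle found no stop-free pathway"
            return (
                sum(t[0] for t in totals) / len(totals),
                sum(t[1] for t in totals) / len(totals),
            )

        rng = np.random.default_rng(8)
        sense = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
        checked = 0
        while checked < 100:
            a, b = rng.choice(sense, size=2)
            try:
                expected = oracle(a, b)
            except AssertionError:
                continue
            assert pathway_counts(a, b) == pytest.approx(expected)
            checked += 1

    def test_ng86_sites_match_biopython_style_counts(self):
        # spot-check canonical values
        assert ng86_site_counts("TTT") == pytest.approx((8 / 3, 1 / 3))
        n, s = ng86_site_counts("CTT")  # Leu: 3rd position fully synonymous
        assert s >= 1.0

    def test_kaks_against_independent_reference(self):
        """Cross-check Ka/Ks on a 100-codon toy against Bio.codonalign NG86."""
        Bio = pytest.importorskip("Bio")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import Bio.codonalign.codonseq as cs

        cfg = ScenarioConfig(
            seed=63, n_pairs=1, chain_length=100, interface_size=10,
            p_sub_interface=0.15, p_sub_noninterface=0.15,
        )
        st, planted = gen_toy_complex(cfg)
        pair, _, _ = gen_duplicate_pair(st, planted, cfg, "kaks")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cs.cal_dn_ds(
                cs.CodonSeq(pair.codon_seq_a),
                cs.CodonSeq(pair.codon_seq_b),
                method="NG86",
            )
        mine = pairwise_divergence(pair)
        assert mine["ka"] == pytest.approx(dn, abs=0.02)
        assert mine["ks"] == pytest.approx(ds, abs=0.05)


def _network_for(pair, partners_a, partners_b):
    records = []
    for gene, partners in ((pair.gene_a, partners_a), (pair.gene_b, partners_b)):
        for p in partners:
            records.append(EvidenceRecord(gene, p, f"s{gene}{p}1"))
            records.append(EvidenceRecord(gene, p, f"s{gene}{p}2"))
    return build_network(records, mode="MC")


class TestDivergenceCalls:
    def test_four_table_cells(self):
        conserved = _pair("ACDEF", "ACDEF", iface_a={1})
        diverged_iface = _pair("ACDEF", "MCDEF", iface_a={1})
        shared, split = {"p1", "p2"}, {"p1"}
        cases = [
            (conserved, shared, shared, ("conserved", "conserved")),
            (diverged_iface, shared, shared, ("diverged", "conserved")),
            (conserved, shared, split, ("conserved", "diverged")),
            (diverged_iface, shared, split, ("diverged", "diverged")),
        ]
        for pair, pa, pb, expected in cases:
            call = classify_pair_divergence(pair, _network_for(pair, pa, pb))
            assert (call.interface_status, call.interaction_status) == expected

    def test_gap_in_interface_is_divergence_by_default(self):
        pair = _pair("ACDEF", "-CDEF", iface_a={1})
        net = _network_for(pair, {"p"}, {"p"})
        assert classify_pair_divergence(pair, net).interface_status == "diverged"
        relaxed = classify_pair_divergence(
            pair, net, count_gaps_as_divergence=False
        )
        assert relaxed.interface_status == "conserved"

    def test_missing_member_is_excluded_loudly(self):
        pair = _pair("ACDEF", "ACDEF", iface_a={1})
        net = _network_for(pair, {"p"}, set())
        with pytest.raises(PairExcluded):
            classify_pair_divergence(pair, net)

    def test_cohort_cells_sum_to_cohort_size(self):
        cfg = ScenarioConfig(seed=64, n_pairs=40, chain_length=60, interface_size=6)
        calls = []
        for k in range(10):
            st, planted = gen_toy_complex(cfg, pair_index=k)
            pair, _, _ = gen_duplicate_pair(
                st, planted, cfg, f"pair{k:04d}", pair_index=k
            )
            net = _network_for(pair, {"p1", "p2"}, {"p1"} if k % 2 else {"p1", "p2"})
            calls.append(classify_pair_divergence(pair, net))
        table = contingency_table(calls)
        assert sum(table.values()) == 10


class TestSubstitutionMatrix:
    def test_single_conserved_substitution(self):
        pair = _pair("M", "A", iface_a={1})
        call = DivergenceCall("t", "diverged", "conserved")
        m = build_substitution_matrix([pair], [call])
        i, j = MATRIX_ALPHABET.index("M"), MATRIX_ALPHABET.index("A")
        assert m.counts["conserved"][i, j] == 1
        assert m.counts["conserved"][j, i] == 1  # undirected
        assert m.total() == 1

    def test_matrix_is_symmetric_and_conserves_totals(self):
        cfg = ScenarioConfig(
            seed=65, n_pairs=1, chain_length=200, interface_size=60,
            p_sub_interface=0.3, p_del=0.03,
        )
        st, planted = gen_toy_complex(cfg)
        pair, _, _ = gen_duplicate_pair(st, planted, cfg, "m")
        cols = map_interface_to_alignment(pair)
        iface, _ = count_substitutions(pair, cols)
        call = DivergenceCall("m", "diverged", "diverged")
        m = build_substitution_matrix([pair], [call], [cols])
        for status in ("conserved", "diverged"):
            assert np.array_equal(m.counts[status], m.counts[status].T)
        assert m.total() == iface.n_subs + iface.n_gaps

    def test_proportions_sum_to_one_per_cell(self):
        pairs = [_pair("M", "A", iface_a={1}), _pair("M", "A", iface_a={1})]
        calls = [
            DivergenceCall("1", "diverged", "conserved"),
            DivergenceCall("2", "diverged", "diverged"),
        ]
        m = build_substitution_matrix(pairs, calls)
        props = m.proportions()[("A", "M")]
        assert props["conserved"] + props["diverged"] == pytest.approx(1.0)

    def test_marginals_invariant_to_pair_order(self):
        pairs = [_pair("MC", "AC", iface_a={1, 2}), _pair("KW", "EW", iface_a={1})]
        calls = [
            DivergenceCall("1", "diverged", "conserved"),
            DivergenceCall("2", "diverged", "diverged"),
        ]
        m1 = build_substitution_matrix(pairs, calls)
        m2 = build_substitution_matrix(pairs[::-1], calls[::-1])
        for status in ("conserved", "diverged"):
            assert np.array_equal(m1.counts[status], m2.counts[status])

    def test_non_standard_residue_is_an_error(self):
        pair = _pair("X", "A", iface_a={1})
        call = DivergenceCall("t", "diverged", "conserved")
        with pytest.raises(ValueError, match="non-standard"):
            build_substitution_matrix([pair], [call])
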
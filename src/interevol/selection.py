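"""Per-site selection classification by SLAC-style ancestor counting.

Ancestral codons at the internal nodes of a given phylogeny are
reconstructed with Fitch parsimony (deterministic lexicographic
tie-breaking). For each alignment column, codon differences along every
branch are decomposed into single-nucleotide steps averaged over shortest
pathways and classified synonymous / nonsynonymous under the universal
code. The observed (N, S) counts are tested against the expected
nonsynonymous proportion EN/(EN+ES) from Nei–Gojobori site counting with a
two-tailed binomial test: a significant deficit of nonsynonymous change is
negative selection, a significant excess positive selection, anything else
neutral. Group comparisons use Kruskal–Wallis with pairwise Mann–Whitney
tests and Benjamini–Hochberg correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codons import is_stop, ng86_site_counts, pathway_counts
from .constants import GENETIC_CODE

__all__ = [
    "SiteSelection",
    "AncestralReconstruction",
    "resolve_polytomies",
    "parsimony_ancestral_codons",
    "count_site_substitutions",
    "classify_site",
    "region_selection_proportions",
    "compare_selection_groups",
    "ALPHA",
]

ALPHA = 0.05  # significance cutoff for calling selection


@dataclass(frozen=True)
class SiteSelection:
    column: int
    n_obs: float
    s_obs: float
    en: float
    es: float
    p_value: float
    selection_class: Literal["negative", "neutral", "positive"]


@dataclass
class AncestralReconstruction:
    """A (resolved) tree with codon states at every node, per site."""

    tree: dendropy.Tree
    # node id -> list of codons (one per alignment column)
    codons: dict[int, list[str]]
    taxa: list[str]
    n_sites: int
    substitution_count: int  # total parsimony changes over all sites

    def branch_states(self, site: int) -> list[tuple[str, str]]:
        """(parent codon, child codon) for every branch at one column."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out.append(
                (
                    self.codons[id(node.parent_node)][site],
                    self.codons[id(node)][site],
                )
            )
        return out


def _load_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick tree: {exc}") from exc


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies by pairing children in input order (zero-length
    branches), so the resolution is deterministic."""
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            a, b = children[0], children[1]
            node.remove_child(a)
            node.remove_child(b)
            joint = dendropy.Node(edge_length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.insert_child(0, joint)
    return tree


def parsimony_ancestral_codons(
    tree: dendropy.Tree | str,
    alignment: Mapping[str, str],
) -> AncestralReconstruction:
    """Fitch-parsimony ancestral codons at every internal node.

    ``alignment`` maps taxon label -> ungapped codon sequence; all
    sequences must share a length divisible by 3, and the tree's leaves
    must match the alignment taxa exactly. Ties in the Fitch top-down pass
    are broken by codon lexicographic order.
    """
    t = resolve_polytomies(_load_tree(tree))
    leaves = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    missing = sorted(set(leaves) ^ set(alignment))
    if missing:
        raise ValueError(
            f"tree/alignment taxon mismatch: {', '.join(missing)}"
        )
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1 or next(iter(lengths)) % 3:
        raise ValueError("alignment sequences must share a length divisible by 3")
    n_sites = next(iter(lengths)) // 3

    codons: dict[int, list[str]] = {
        id(node): [""] * n_sites for node in t.preorder_node_iter()
    }
    total_changes = 0
    postorder = list(t.postorder_node_iter())
    preorder = list(t.preorder_node_iter())
    for site in range(n_sites):
        state_sets: dict[int, frozenset[str]] = {}
        for node in postorder:
            if node.is_leaf():
                seq = alignment[node.taxon.label]
                state_sets[id(node)] = frozenset({seq[3 * site : 3 * site + 3]})
            else:
                kids = [state_sets[id(c)] for c in node.child_nodes()]
                inter = frozenset.intersection(*kids)
                if inter:
                    state_sets[id(node)] = inter
                else:
                    state_sets[id(node)] = frozenset.union(*kids)
                    total_changes += 1
        for node in preorder:
            options = state_sets[id(node)]
            if node.parent_node is None:
                codons[id(node)][site] = min(options)
            else:
                parent_codon = codons[id(node.parent_node)][site]
                codons[id(node)][site] = (
                    parent_codon if parent_codon in options else min(options)
                )
    return AncestralReconstruction(
        tree=t,
        codons=codons,
        taxa=sorted(leaves),
        n_sites=n_sites,
        substitution_count=total_changes,
    )


def count_site_substitutions(
    recon: AncestralReconstruction, site: int
) -> tuple[float, float, float, float]:
    """(N_obs, S_obs, EN, ES) at one alignment column.

    N_obs/S_obs sum pathway-averaged nonsynonymous/synonymous steps over
    all branches. EN/ES are the Nei–Gojobori site fractions averaged over
    the codons observed at the column (leaves and ancestors), scaled by the
    total observed substitutions so EN + ES = N_obs + S_obs.
    """
    if not 0 <= site < recon.n_sites:
        raise ValueError(f"site {site} out of range")
    n_obs = s_obs = 0.0
    observed: list[str] = []
    for node in recon.tree.preorder_node_iter():
        codon = recon.codons[id(node)][site]
        if is_stop(codon) or GENETIC_CODE.get(codon) is None:
            label = (
                node.taxon.label if node.is_leaf() else "internal node"
            )
            raise ValueError(f"stop/invalid codon at {label}, site {site}")
        observed.append(codon)
    for parent, child in recon.branch_states(site):
        if parent != child:
            dn, ds = pathway_counts(parent, child)
            n_obs += dn
            s_obs += ds
    site_counts = np.array([ng86_site_counts(c) for c in observed])
    mean_n, mean_s = site_counts.mean(axis=0)
    f_n = mean_n / (mean_n + mean_s)
    total = n_obs + s_obs
    return (n_obs, s_obs, total * f_n, total * (1.0 - f_n))


def classify_site(
    column: int,
    n_obs: float,
    s_obs: float,
    en: float,
    es: float,
    alpha: float = ALPHA,
) -> SiteSelection:
    """Binomial test of the nonsynonymous count against its neutral share.

    Two-tailed p = min(1, 2 * min(lower tail, upper tail)) of
    Binomial(N_obs + S_obs, EN/(EN+ES)) at N_obs. No substitutions at all
    is a neutral call by definition.
    """
    if min(n_obs, s_obs) < 0:
        raise ValueError("negative substitution counts")
    total = n_obs + s_obs
    if total == 0:
        return SiteSelection(column, n_obs, s_obs, en, es, 1.0, "neutral")
    if en + es <= 0:
        raise ValueError("EN + ES must be positive when substitutions exist")
    p_neutral = en / (en + es)
    # Counts are pathway averages, hence possibly fractional; round the
    # trials/successes to the nearest integers for the test.
    k = int(round(n_obs))
    n = int(round(total))
    k = min(k, n)
    lower = stats.binom.cdf(k, n, p_neutral)
    upper = stats.binom.sf(k - 1, n, p_neutral)
    p = min(1.0, 2.0 * min(lower, upper))
    if p < alpha:
        cls = "negative" if (n_obs / total) < p_neutral else "positive"
    else:
        cls = "neutral"
    return SiteSelection(column, n_obs, s_obs, en, es, float(p), cls)


def classify_alignment_sites(
    tree: dendropy.Tree | str,
    alignment: Mapping[str, str],
    alpha: float = ALPHA,
) -> list[SiteSelection]:
    """Convenience: reconstruct ancestors, then classify every column."""
    recon = parsimony_ancestral_codons(tree, alignment)
    out = []
    for site in range(recon.n_sites):
        n_obs, s_obs, en, es = count_site_substitutions(recon, site)
        out.append(classify_site(site, n_obs, s_obs, en, es, alpha=alpha))
    return out


def region_selection_proportions(
    sites: Sequence[SiteSelection],
    interface_columns: Sequence[bool],
    include_positive: bool = False,
) -> dict[str, dict[str, float] | None]:
    """Per-region class proportions for one duplicate pair.

    Returns ``{region: {class: proportion}}``; a region with zero sites is
    ``None`` (the pair drops out of comparisons on that region). Positive
    sites are tallied but, by default, reported only as a proportion and
    excluded from downstream group comparisons (too few to compare).
    """
    mask = np.asarray(interface_columns, dtype=bool)
    if mask.size != len(sites):
        raise ValueError("region labels do not match site count")
    out: dict[str, dict[str, float] | None] = {}
    classes = ["negative", "neutral"] + (["positive"] if include_positive else [])
    for region, m in (("interface", mask), ("non_interface", ~mask)):
        chosen = [s for s, flag in zip(sites, m) if flag]
        if not chosen:
            out[region] = None
            continue
        n = len(chosen)
        props = {
            cls: sum(s.selection_class == cls for s in chosen) / n
            for cls in ("negative", "neutral", "positive")
        }
        out[region] = {cls: props[cls] for cls in classes}
    return out


def compare_selection_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
) -> dict:
    """Kruskal–Wallis across groups + pairwise Mann–Whitney with BH correction.

    ``groups`` maps group label -> per-pair proportions. Requires at least
    two groups of at least two pairs each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} has fewer than two pairs")
    labels = sorted(groups)
    kw_stat, kw_p = stats.kruskal(*[np.asarray(groups[g]) for g in labels])
    comparisons = []
    raw_p = []
    for g1, g2 in itertools.combinations(labels, 2):
        u, p = stats.mannwhitneyu(
            groups[g1], groups[g2], alternative="two-sided"
        )
        comparisons.append({"group_1": g1, "group_2": g2, "u": float(u)})
        raw_p.append(float(p))
    reject, adj_p, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    for comp, p, q, rej in zip(comparisons, raw_p, adj_p, reject):
        comp.update(p_raw=p, p_adjusted=float(q), significant=bool(rej))
    return {
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": comparisons,
    }


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (delegates to statsmodels fdr_bh)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]
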
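"""Interaction networks, shared-interaction ratio, and loss-rate estimation.

Networks are undirected graphs over proteins with per-edge study evidence.
Two network modes are supported:

* ``MC`` (multiple confidence): an experimental edge is kept only when
  supported by at least two *distinct* studies;
* ``all``: every experimental edge is kept.

Structure-derived edges are added afterwards only where no experimental
evidence exists for the pair at all, so every protein with a detected
interface has at least one interaction without double-counting.

For a duplicate pair with partner sets of sizes n1 and n2 sharing s
partners, the shared interaction ratio is SIR = 2s / (n1 + n2). The
interaction-loss rate after duplication is rate = (l / a) (1 / d) with l
lost interactions, a ancestral gene–partner interactions and d the time
since duplication in Myr (100 for the whole-genome duplication).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "EvidenceRecord",
    "InteractionNetwork",
    "SIRRecord",
    "LossRateEstimate",
    "PairExcluded",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "build_network",
    "compute_sir",
    "infer_ancestral_interactions",
    "estimate_loss_rate",
    "find_hubs",
    "correlate_divergence_with_sir",
    "WGD_AGE_MYR",
    "HUB_DEGREE_THRESHOLD",
]

WGD_AGE_MYR = 100.0  # age of the yeast whole-genome duplication
HUB_DEGREE_THRESHOLD = 40  # strictly more interactions than this = hub


class PairExcluded(Exception):
    """A duplicate pair cannot enter an analysis (signalled, never silent)."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One line of interaction evidence (one study observing one pair)."""

    protein_a: str
    protein_b: str
    study_id: str
    source: Literal["experimental", "structural"] = "experimental"

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.source not in ("experimental", "structural"):
            raise ValueError(f"unknown evidence source {self.source!r}")


class InteractionNetwork:
    """Evidence-filtered undirected interaction network.

    Thin wrapper over a :class:`networkx.Graph`; edges carry the distinct
    study ids and evidence sources that support them. Self-interactions are
    permitted and a protein's partner set may include itself.
    """

    def __init__(self, graph: nx.Graph, mode: str):
        self.graph = graph
        self.mode = mode

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def partners(self, protein: str) -> frozenset[str]:
        """Distinct interaction partners (self included for self-loops)."""
        if protein not in self.graph:
            raise PairExcluded(f"{protein} absent from the network")
        return frozenset(self.graph.neighbors(protein))

    def degree(self, protein: str) -> int:
        return len(self.partners(protein))

    def to_edge_tsv(self, path: str | Path) -> None:
        lines = ["protein_a\tprotein_b\tn_studies\tsources"]
        for u, v, data in sorted(self.graph.edges(data=True)):
            lines.append(
                f"{u}\t{v}\t{len(data['studies'])}\t"
                f"{','.join(sorted(data['sources']))}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def summary(self) -> dict:
        n_structural = sum(
            1
            for _, _, d in self.graph.edges(data=True)
            if d["sources"] == {"structural"}
        )
        return {
            "mode": self.mode,
            "n_proteins": len(self.graph),
            "n_edges": self.n_edges,
            "n_structural_only": n_structural,
            "hubs": find_hubs(self),
        }


@dataclass(frozen=True)
class SIRRecord:
    pair_id: str
    s: int
    n1: int
    n2: int

    @property
    def sir(self) -> float:
        return 2.0 * self.s / (self.n1 + self.n2)


@dataclass(frozen=True)
class LossRateEstimate:
    l: int  # noqa: E741 - the field's standard name
    a: int
    d: float

    @property
    def rate(self) -> float:
        return (self.l / self.a) / self.d


# -- evidence I/O ----------------------------------------------------------


def read_evidence_tsv(path: str | Path) -> list[EvidenceRecord]:
    """Read evidence records from TSV (protein_a, protein_b, study_id[, source])."""
    records = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("protein_a"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected ≥3 tab-separated fields")
        source = fields[3] if len(fields) > 3 else "experimental"
        try:
            records.append(
                EvidenceRecord(fields[0], fields[1], fields[2], source)  # type: ignore[arg-type]
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_evidence_tsv(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    lines = ["protein_a\tprotein_b\tstudy_id\tsource"]
    for r in records:
        lines.append(f"{r.protein_a}\t{r.protein_b}\t{r.study_id}\t{r.source}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- network assembly ------------------------------------------------------


def build_network(
    records: Sequence[EvidenceRecord], mode: Literal["MC", "all"] = "MC"
) -> InteractionNetwork:
    """Assemble an evidence-filtered network.

    In ``MC`` mode an experimental edge needs at least two distinct study
    ids (duplicate study ids are deduplicated first). Structural edges are
    then added only for pairs with no experimental evidence at all.
    The result is independent of record order and idempotent.
    """
    if mode not in ("MC", "all"):
        raise ValueError(f"unknown network mode {mode!r}")
    exp_studies: dict[tuple[str, str], set[str]] = {}
    struct_studies: dict[tuple[str, str], set[str]] = {}
    for r in records:
        key = tuple(sorted((r.protein_a, r.protein_b)))
        bucket = exp_studies if r.source == "experimental" else struct_studies
        bucket.setdefault(key, set()).add(r.study_id)

    g = nx.Graph()
    min_studies = 2 if mode == "MC" else 1
    for (u, v), studies in exp_studies.items():
        if len(studies) >= min_studies:
            g.add_edge(u, v, studies=frozenset(studies), sources={"experimental"})
    for (u, v), studies in struct_studies.items():
        if (u, v) in exp_studies:
            # pair already has experimental evidence: never double-counted,
            # and never rescued into MC mode by structural support
            if g.has_edge(u, v):
                g[u][v]["sources"] = {"experimental", "structural"}
            continue
        g.add_edge(u, v, studies=frozenset(studies), sources={"structural"})
    return InteractionNetwork(g, mode)


# -- duplicate-pair statistics --------------------------------------------


def compute_sir(
    pair_id: str,
    gene_a: str,
    gene_b: str,
    network: InteractionNetwork,
) -> SIRRecord:
    """Shared interaction ratio of a duplicate pair on a given network.

    Partner matching is by identity: self-interactions and interaction with
    the sister paralogue count as ordinary partners. Raises
    :class:`PairExcluded` when either member has no interactions.
    """
    try:
        partners_a = network.partners(gene_a)
        partners_b = network.partners(gene_b)
    except PairExcluded as exc:
        raise PairExcluded(f"pair {pair_id}: {exc}") from exc
    if not partners_a or not partners_b:
        raise PairExcluded(f"pair {pair_id}: a member has zero interactions")
    return SIRRecord(
        pair_id=pair_id,
        s=len(partners_a & partners_b),
        n1=len(partners_a),
        n2=len(partners_b),
    )


def infer_ancestral_interactions(
    pair_id: str,
    gene_a: str,
    gene_b: str,
    network: InteractionNetwork,
    convention: Literal["per_gene", "union"] = "per_gene",
) -> tuple[int, int]:
    """Infer (a, l): ancestral interaction count and losses since duplication.

    Both members are assumed to have held the union U of their current
    partner sets immediately after duplication. Under the default
    ``per_gene`` convention each member-partner interaction counts, so
    a = 2|U| and l = (|U| - n_a) + (|U| - n_b); ``union`` counts partners
    once (a = |U|, l halved is not meaningful there, so l counts members'
    missing partners the same way but against a = |U|).

    Interactions lost by *both* members are invisible to this inference
    (they vanish from U), which biases the loss rate downward; the bias is
    measured by the test suite, not corrected.
    """
    partners_a = network.partners(gene_a)
    partners_b = network.partners(gene_b)
    union = partners_a | partners_b
    if not union:
        raise PairExcluded(f"pair {pair_id}: no current interactions")
    losses = (len(union) - len(partners_a)) + (len(union) - len(partners_b))
    if convention == "per_gene":
        return (2 * len(union), losses)
    if convention == "union":
        return (len(union), losses)
    raise ValueError(f"unknown ancestral-count convention {convention!r}")


def estimate_loss_rate(l: int, a: int, d: float) -> LossRateEstimate:  # noqa: E741
    """Interaction-loss rate (l/a)/d per PPI per Myr."""
    if a <= 0:
        raise ValueError("ancestral interaction count must be positive")
    if d <= 0:
        raise ValueError("divergence time must be positive")
    if not 0 <= l <= a:
        raise ValueError("losses must satisfy 0 <= l <= a")
    return LossRateEstimate(l=l, a=a, d=d)


def find_hubs(
    network: InteractionNetwork, threshold: int = HUB_DEGREE_THRESHOLD
) -> list[str]:
    """Proteins with strictly more than ``threshold`` interaction partners."""
    return sorted(
        p for p in network.proteins if network.degree(p) > threshold
    )


def correlate_divergence_with_sir(
    divergence: Sequence[float], sir: Sequence[float]
) -> dict[str, float]:
    """Rank (Spearman) and linear (Pearson) correlation of divergence vs SIR."""
    x = np.asarray(divergence, dtype=float)
    y = np.asarray(sir, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs to correlate")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    rho, p_rho = stats.spearmanr(x, y)
    r, p_r = stats.pearsonr(x, y)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "pearson_r": float(r),
        "pearson_p": float(p_r),
        "n": int(x.size),
    }


def network_summary_json(network: InteractionNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network.summary(), indent=2) + "\n")
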
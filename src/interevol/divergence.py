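"""Interface-aware sequence divergence between duplicate pairs.

Maps structure interfaces onto pairwise alignments, counts substitutions
inside and outside interfaces, computes the interface substitution rate
relative to the non-interface rate (pairs with ratio > 2 are flagged as
erroneous and excluded), classifies each pair into the interface x
interaction 2x2 contingency, and accumulates the undirected interface
substitution matrix (20 amino acids + gap) split by interaction status.

Columns are 0-based alignment indices throughout. Gap columns are excluded
from substitution counts and from site totals when computing rates, but
count as the 21st symbol in the substitution matrix and as interface
divergence in the 2x2 classification (an indel in an interface almost
always changes the interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .codons import ng86_site_counts, pathway_counts, translate
from .constants import GAP, MATRIX_ALPHABET
from .network import InteractionNetwork, PairExcluded, compute_sir

__all__ = [
    "DuplicatePair",
    "RegionCounts",
    "RelativeRate",
    "DivergenceCall",
    "SubstitutionMatrixCounts",
    "map_interface_to_alignment",
    "count_substitutions",
    "relative_interface_rate",
    "pairwise_divergence",
    "classify_pair_divergence",
    "build_substitution_matrix",
    "RATE_FILTER_CAP",
]

# Pairs whose interface substitution rate exceeds the non-interface rate by
# more than this factor are excluded as erroneous rate estimates.
RATE_FILTER_CAP = 2.0


@dataclass
class DuplicatePair:
    """Two paralogous genes with aligned sequences and interface metadata."""

    pair_id: str
    gene_a: str
    gene_b: str
    aligned_seq_a: str
    aligned_seq_b: str
    duplication_class: Literal["WGD", "SSD"] = "WGD"
    age_myr: float = 100.0
    codon_seq_a: str | None = None
    codon_seq_b: str | None = None
    interface_residues_a: frozenset[int] = field(default_factory=frozenset)
    interface_residues_b: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.aligned_seq_a) != len(self.aligned_seq_b):
            raise ValueError(
                f"pair {self.pair_id}: aligned sequences differ in length"
            )
        for codon_seq, aligned in (
            (self.codon_seq_a, self.aligned_seq_a),
            (self.codon_seq_b, self.aligned_seq_b),
        ):
            if codon_seq is not None:
                protein = translate(codon_seq)
                if protein != aligned.replace(GAP, ""):
                    raise ValueError(
                        f"pair {self.pair_id}: codon sequence does not "
                        "translate to the ungapped protein sequence"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.aligned_seq_a)


@dataclass(frozen=True)
class RegionCounts:
    region: Literal["interface", "non_interface"]
    n_sites: int
    n_subs: int
    n_gaps: int

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_subs, self.n_gaps) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_subs + self.n_gaps > self.n_sites:
            raise ValueError("substitutions + gaps exceed sites")

    @property
    def rate(self) -> float:
        """Substitutions per gap-free site (nan when no gap-free sites)."""
        sites = self.n_sites - self.n_gaps
        return self.n_subs / sites if sites else float("nan")


@dataclass(frozen=True)
class RelativeRate:
    """Interface substitution rate relative to the non-interface rate."""

    ratio: float  # nan when undefined (zero non-interface rate)
    defined: bool
    excluded: bool  # ratio > RATE_FILTER_CAP: erroneous estimate, drop pair


@dataclass(frozen=True)
class DivergenceCall:
    """One cell of the interface x interaction 2x2 contingency."""

    pair_id: str
    interface_status: Literal["conserved", "diverged"]
    interaction_status: Literal["conserved", "diverged"]


def map_interface_to_alignment(pair: DuplicatePair) -> np.ndarray:
    """Label every alignment column ``interface`` (True) or not (False).

    A column is an interface column when either member's residue occupying
    it (1-based ungapped position) is an interface residue of that member.
    Non-interface columns include both core and surface residues.
    """
    n = pair.n_columns
    labels = np.zeros(n, dtype=bool)
    for aligned, residues in (
        (pair.aligned_seq_a, pair.interface_residues_a),
        (pair.aligned_seq_b, pair.interface_residues_b),
    ):
        length = len(aligned.replace(GAP, ""))
        for r in residues:
            if not 1 <= r <= length:
                raise ValueError(
                    f"pair {pair.pair_id}: interface residue {r} beyond "
                    f"sequence length {length}"
                )
        pos = 0
        for col, aa in enumerate(aligned):
            if aa == GAP:
                continue
            pos += 1
            if pos in residues:
                labels[col] = True
    return labels


def count_substitutions(
    pair: DuplicatePair, interface_columns: np.ndarray
) -> tuple[RegionCounts, RegionCounts]:
    """Per-region site, substitution and gap-column counts.

    A column with an amino-acid mismatch (both members non-gap) is a
    substitution; a column where either member is a gap counts as a gap
    column, never as a substitution.
    """
    interface_columns = np.asarray(interface_columns, dtype=bool)
    if interface_columns.size != pair.n_columns:
        raise ValueError("column labels do not match alignment length")
    out = []
    for region, mask in (
        ("interface", interface_columns),
        ("non_interface", ~interface_columns),
    ):
        subs = gaps = 0
        for col in np.flatnonzero(mask):
            a, b = pair.aligned_seq_a[col], pair.aligned_seq_b[col]
            if GAP in (a, b):
                gaps += 1
            elif a != b:
                subs += 1
        out.append(
            RegionCounts(
                region=region,  # type: ignore[arg-type]
                n_sites=int(mask.sum()),
                n_subs=subs,
                n_gaps=gaps,
            )
        )
    return out[0], out[1]


def relative_interface_rate(
    interface: RegionCounts,
    non_interface: RegionCounts,
    cap: float = RATE_FILTER_CAP,
) -> RelativeRate:
    """Interface / non-interface substitution-rate ratio with the >cap filter.

    Raises :class:`PairExcluded` when either region has no gap-free sites;
    returns an undefined (nan) ratio when the non-interface rate is zero.
    """
    if interface.n_sites - interface.n_gaps <= 0:
        raise PairExcluded("no gap-free interface sites")
    if non_interface.n_sites - non_interface.n_gaps <= 0:
        raise PairExcluded("no gap-free non-interface sites")
    denom = non_interface.rate
    if denom == 0:
        return RelativeRate(ratio=float("nan"), defined=False, excluded=False)
    ratio = interface.rate / denom
    return RelativeRate(ratio=ratio, defined=True, excluded=ratio > cap)


def pairwise_divergence(pair: DuplicatePair) -> dict[str, float]:
    """Whole-sequence divergence, plus Nei–Gojobori Ka/Ks when codons exist.

    Protein divergence is mismatches over gap-free columns. Ka and Ks use
    pathway-averaged substitution counting with NG86 site counts; ``p_n``
    and ``p_s`` are the uncorrected proportions, ``ka``/``ks`` apply the
    Jukes–Cantor correction (nan where the correction is undefined).
    """
    compared = mismatches = 0
    for a, b in zip(pair.aligned_seq_a, pair.aligned_seq_b):
        if GAP in (a, b):
            continue
        compared += 1
        mismatches += a != b
    out: dict[str, float] = {
        "protein_divergence": mismatches / compared if compared else float("nan")
    }
    if pair.codon_seq_a is None or pair.codon_seq_b is None:
        return out
    # Walk aligned columns, consuming codons on non-gap positions; codon
    # pairs are only compared at columns where both members are present.
    ai = bi = 0
    nd = sd = n_sites = s_sites = 0.0
    for a, b in zip(pair.aligned_seq_a, pair.aligned_seq_b):
        codon_a = pair.codon_seq_a[3 * ai : 3 * ai + 3] if a != GAP else None
        codon_b = pair.codon_seq_b[3 * bi : 3 * bi + 3] if b != GAP else None
        ai += a != GAP
        bi += b != GAP
        if codon_a is None or codon_b is None:
            continue
        dn, ds = pathway_counts(codon_a, codon_b)
        nd += dn
        sd += ds
        na, sa = ng86_site_counts(codon_a)
        nb, sb = ng86_site_counts(codon_b)
        n_sites += (na + nb) / 2
        s_sites += (sa + sb) / 2
    p_n = nd / n_sites if n_sites else float("nan")
    p_s = sd / s_sites if s_sites else float("nan")
    out.update(p_n=p_n, p_s=p_s, ka=_jukes_cantor(p_n), ks=_jukes_cantor(p_s))
    return out


def _jukes_cantor(p: float) -> float:
    if not np.isfinite(p) or p >= 0.75:
        return float("nan")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def classify_pair_divergence(
    pair: DuplicatePair,
    network: InteractionNetwork,
    interface_columns: np.ndarray | None = None,
    count_gaps_as_divergence: bool = True,
) -> DivergenceCall:
    """Classify a pair into the interface x interaction 2x2 table.

    Interface status is ``diverged`` iff any interface column carries a
    substitution (or, by default, a gap). Interaction status is
    ``diverged`` iff the pair does not share all interactions (SIR < 1).
    Raises :class:`PairExcluded` when a member is absent from the network.
    """
    if interface_columns is None:
        interface_columns = map_interface_to_alignment(pair)
    iface, _ = count_substitutions(pair, interface_columns)
    changed = iface.n_subs + (iface.n_gaps if count_gaps_as_divergence else 0)
    sir = compute_sir(pair.pair_id, pair.gene_a, pair.gene_b, network)
    return DivergenceCall(
        pair_id=pair.pair_id,
        interface_status="diverged" if changed > 0 else "conserved",
        interaction_status="diverged" if sir.sir < 1.0 else "conserved",
    )


def contingency_table(calls: Iterable[DivergenceCall]) -> dict[str, int]:
    """2x2 cell counts keyed ``interface<status>_interaction<status>``."""
    cells = {
        "conserved_conserved": 0,
        "diverged_conserved": 0,
        "conserved_diverged": 0,
        "diverged_diverged": 0,
    }
    for c in calls:
        cells[f"{c.interface_status}_{c.interaction_status}"] += 1
    return cells


class SubstitutionMatrixCounts:
    """Undirected 21x21 interface substitution counts by interaction status.

    Alphabet: 20 amino acids + gap. Substitutions are undirected (A->R and
    R->A accumulate in the same unordered cell; the stored matrices are
    kept symmetric). ``proportions`` gives, per non-empty cell, the share
    of that substitution seen in interaction-conserved vs -diverged pairs
    (the two shares sum to 1).
    """

    def __init__(self) -> None:
        k = len(MATRIX_ALPHABET)
        self.counts: dict[str, np.ndarray] = {
            "conserved": np.zeros((k, k)),
            "diverged": np.zeros((k, k)),
        }

    def add(self, res_a: str, res_b: str, status: str) -> None:
        if status not in self.counts:
            raise ValueError(f"unknown interaction status {status!r}")
        try:
            i, j = MATRIX_ALPHABET.index(res_a), MATRIX_ALPHABET.index(res_b)
        except ValueError:
            raise ValueError(
                f"non-standard residue in substitution ({res_a!r}, {res_b!r})"
            ) from None
        self.counts[status][i, j] += 1
        if i != j:
            self.counts[status][j, i] += 1

    def total(self, status: str | None = None) -> float:
        """Total substitution events (each unordered event counted once)."""
        keys = [status] if status else list(self.counts)
        tot = 0.0
        for k in keys:
            m = self.counts[k]
            tot += np.triu(m).sum()  # symmetric storage: count upper triangle
        return float(tot)

    def proportions(self) -> dict[tuple[str, str], dict[str, float]]:
        out: dict[tuple[str, str], dict[str, float]] = {}
        con, div = self.counts["conserved"], self.counts["diverged"]
        for i, a in enumerate(MATRIX_ALPHABET):
            for j, b in enumerate(MATRIX_ALPHABET[i:], start=i):
                tot = con[i, j] + div[i, j]
                if tot:
                    out[(a, MATRIX_ALPHABET[j])] = {
                        "conserved": con[i, j] / tot,
                        "diverged": div[i, j] / tot,
                    }
        return out

    def to_long_tsv(self) -> str:
        lines = ["res_a\tres_b\tstatus\tcount\tproportion"]
        props = self.proportions()
        for (a, b), prop in sorted(props.items()):
            i, j = MATRIX_ALPHABET.index(a), MATRIX_ALPHABET.index(b)
            for status in ("conserved", "diverged"):
                lines.append(
                    f"{a}\t{b}\t{status}\t"
                    f"{int(self.counts[status][i, j])}\t{prop[status]:.4f}"
                )
        return "\n".join(lines) + "\n"


def build_substitution_matrix(
    pairs: Sequence[DuplicatePair],
    calls: Sequence[DivergenceCall],
    interface_columns: Sequence[np.ndarray] | None = None,
) -> SubstitutionMatrixCounts:
    """Accumulate interface substitutions (+ gaps) across pairs by status."""
    if len(pairs) != len(calls):
        raise ValueError("pairs and calls must align")
    matrix = SubstitutionMatrixCounts()
    for idx, (pair, call) in enumerate(zip(pairs, calls)):
        cols = (
            interface_columns[idx]
            if interface_columns is not None
            else map_interface_to_alignment(pair)
        )
        for col in np.flatnonzero(np.asarray(cols, dtype=bool)):
            a, b = pair.aligned_seq_a[col], pair.aligned_seq_b[col]
            if a == b:
                continue
            matrix.add(a, b, call.interaction_status)
    return matrix
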
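"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, with
machine-readable truth, so the full analysis is testable offline:

* two-chain complexes with a planted contact interface
  (:func:`gen_toy_complex`),
* duplicate pairs whose paralogue model carries substitutions at controlled
  densities inside/outside the interface, each interface substitution
  planted to preserve or break its atom contact (:func:`gen_duplicate_pair`),
* interaction networks where both members of each duplicate pair inherit an
  identical ancestral partner set and lose each interaction independently
  with probability loss_rate x divergence_time
  (:func:`simulate_interaction_loss`),
* codon alignments evolved down a fixed tree with per-site omega classes
  (:func:`gen_codon_alignment`).

Geometry of the toy complexes: two parallel rails of residues 26 Å apart
(6 Å residue spacing). Backbone atoms stay on the rails; side chains are
idealised linear chains of the residue type's canonical heavy atoms,
growing away from the partner chain except at planted interface positions,
where the two side chains reach towards each other so that exactly the two
tip atoms meet at r_a + r_b + margin/2 — a contact but not a clash. All
other inter-chain atom pairs exceed the contact threshold by at least 1 Å
by construction. Interface positions are restricted to residue types with
2–6 side-chain heavy atoms so the contact is always side-chain-mediated
and the >=1 Å margin guarantee holds for every non-planted pair.

Determinism: all randomness derives from ``ScenarioConfig.seed``; the same
config yields bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .constants import (
    AA3_TO_AA1,
    BONDI_RADII,
    CODONS_FOR_AA,
    GENETIC_CODE,
    NUCLEOTIDES,
    SENSE_CODONS,
    SIDE_CHAIN_ATOMS,
    element_of,
)
from .codons import is_stop
from .divergence import DuplicatePair
from .geometry import ContactPair, Interface
from .network import EvidenceRecord
from .structures import AtomRecord, ComplexStructure

__all__ = [
    "ScenarioConfig",
    "GenerationError",
    "SiteTruth",
    "CodonSiteTruth",
    "gen_toy_complex",
    "gen_duplicate_pair",
    "simulate_interaction_loss",
    "gen_codon_alignment",
    "DEFAULT_TREE",
]


class GenerationError(RuntimeError):
    """Synthetic-data generation failed (invalid request or placement)."""


# Ten-taxon tree: the duplicate pair plus eight yeast-like outgroup taxa.
# Branch lengths are expected nucleotide mutation events per site.
DEFAULT_TREE = (
    "((dupA:0.15,dupB:0.15):0.45,"
    "(((ortho1:0.36,ortho2:0.36):0.24,(ortho3:0.30,ortho4:0.30):0.30):0.30,"
    "((ortho5:0.45,ortho6:0.45):0.30,(ortho7:0.60,ortho8:0.75):0.15):0.15)"
    ":0.30);"
)

# Residue types eligible for planted interface positions: side chains of
# 2-6 heavy atoms keep the geometric margin guarantees (see module doc).
INTERFACE_TYPES: tuple[str, ...] = tuple(
    sorted(t for t, sc in SIDE_CHAIN_ATOMS.items() if 2 <= len(sc) <= 6)
)
ALL_TYPES: tuple[str, ...] = tuple(sorted(SIDE_CHAIN_ATOMS))

_RESIDUE_SPACING = 6.0  # Å between residue centres along a chain
_CHAIN_GAP = 26.0  # Å between the two backbone rails
_SIDE_CHAIN_STEP = 1.5  # Å between successive side-chain atoms
_BACKBONE = (  # (atom name, dx, dy, dz) relative to CA; dy stays 0
    ("N", -1.3, 0.0, 0.0),
    ("CA", 0.0, 0.0, 0.0),
    ("C", 1.3, 0.0, 0.0),
    ("O", 1.9, 0.0, 1.2),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic scenario.

    Defaults mirror the analysed system: 204 whole-genome duplicate pairs
    ~100 Myr old losing interactions at 6.0e-3 per PPI per Myr, interfaces
    more conserved than the rest of the protein (planted substitution
    densities 0.1 vs 0.2 per site; omega 0.1 in interfaces vs 0.5 outside).
    """

    seed: int = 0
    n_pairs: int = 204
    chain_length: int = 100
    interface_size: int = 10
    p_sub_interface: float = 0.1
    p_sub_noninterface: float = 0.2
    loss_rate: float = 6.0e-3  # losses per PPI per Myr
    divergence_time: float = 100.0  # Myr since duplication
    ancestral_degree_mean: float = 5.0
    tree: str = DEFAULT_TREE
    site_classes: tuple[tuple[str, float, int], ...] = (
        ("negative", 0.1, 50),
        ("neutral", 1.0, 50),
    )
    omega_interface: float = 0.1
    omega_noninterface: float = 0.5
    p_contact_preserved: float = 0.5
    p_del: float = 0.0  # per-site deletion probability in the paralogue
    couple_loss_to_contacts: bool = False

    def __post_init__(self) -> None:
        probs = {
            "p_sub_interface": self.p_sub_interface,
            "p_sub_noninterface": self.p_sub_noninterface,
            "p_contact_preserved": self.p_contact_preserved,
            "p_del": self.p_del,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.loss_rate < 0:
            raise ValueError("loss_rate must be >= 0")
        if self.divergence_time <= 0:
            raise ValueError("divergence_time must be positive")
        if self.interface_size > self.chain_length:
            raise ValueError("interface_size cannot exceed chain_length")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for label, omega, n in self.site_classes:
            if omega < 0 or n < 0:
                raise ValueError(f"invalid site class {(label, omega, n)}")

    def rng(self, *subkeys: int) -> np.random.Generator:
        """Child generator for a named substream (deterministic per config)."""
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *subkeys])

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass(frozen=True)
class SiteTruth:
    """Planted truth for one template residue of a duplicate pair."""

    site: int  # 1-based template residue index (chain A)
    interface: bool
    substituted: bool
    deleted: bool
    contact_preserved: bool | None  # None off-interface / no substitution


@dataclass(frozen=True)
class CodonSiteTruth:
    """Planted truth for one codon alignment column."""

    column: int
    class_label: str
    omega: float
    n_true: int  # accepted nonsynonymous events over the whole tree
    s_true: int


# -- toy complexes ----------------------------------------------------------


def _radius(atom_name: str) -> float:
    return BONDI_RADII[element_of(atom_name)]


def _side_chain_positions(
    n_atoms: int, x: float, y0: float, direction: float, tip_y: float | None
) -> list[tuple[float, float, float]]:
    """y-coordinates of a linear side chain; tip pinned to ``tip_y`` if given."""
    if tip_y is None:
        return [
            (x, y0 + direction * _SIDE_CHAIN_STEP * (k + 1), 0.0)
            for k in range(n_atoms)
        ]
    start = y0 + direction * _SIDE_CHAIN_STEP
    if n_atoms == 1:
        return [(x, tip_y, 0.0)]
    return [
        (x, start + (tip_y - start) * k / (n_atoms - 1), 0.0)
        for k in range(n_atoms)
    ]


def _build_residue(
    chain_id: str,
    index: int,
    res_type: str,
    x: float,
    y0: float,
    direction: float,
    tip_y: float | None = None,
) -> list[AtomRecord]:
    atoms = [
        AtomRecord(
            chain_id=chain_id,
            residue_index=index,
            residue_type=res_type,
            atom_name=name,
            element=element_of(name),
            position=(x + dx, y0 + dy, dz),
            vdw_radius=_radius(name),
        )
        for name, dx, dy, dz in _BACKBONE
    ]
    side = SIDE_CHAIN_ATOMS[res_type]
    for name, pos in zip(
        side, _side_chain_positions(len(side), x, y0, direction, tip_y)
    ):
        atoms.append(
            AtomRecord(
                chain_id=chain_id,
                residue_index=index,
                residue_type=res_type,
                atom_name=name,
                element=element_of(name),
                position=pos,
                vdw_radius=_radius(name),
            )
        )
    return atoms


def gen_toy_complex(
    config: ScenarioConfig,
    pair_index: int = 0,
    margin: float = 0.5,
    name: str | None = None,
) -> tuple[ComplexStructure, Interface]:
    """Generate a two-chain complex with a planted contact interface.

    Exactly ``interface_size`` residues per chain (matching indices on the
    two chains) have one atom pair within the contact threshold of the
    partner chain; every other inter-chain atom pair exceeds the threshold
    by at least 1 Å. Returns the structure and the ground-truth interface.
    """
    if config.interface_size < 1:
        raise GenerationError("interface_size must be >= 1")
    rng = config.rng(1, pair_index)
    L = config.chain_length
    iface_idx = np.sort(
        rng.choice(L, size=config.interface_size, replace=False) + 1
    )
    iface_set = set(int(i) for i in iface_idx)

    types: dict[str, list[str]] = {}
    for chain in ("A", "B"):
        picks = []
        for i in range(1, L + 1):
            pool = INTERFACE_TYPES if i in iface_set else ALL_TYPES
            picks.append(str(rng.choice(pool)))
        types[chain] = picks

    atoms: list[AtomRecord] = []
    tip_atoms: dict[tuple[str, int], AtomRecord] = {}
    mid = _CHAIN_GAP / 2.0
    for chain, y0, toward in (("A", 0.0, +1.0), ("B", _CHAIN_GAP, -1.0)):
        for i in range(1, L + 1):
            res_type = types[chain][i - 1]
            x = _RESIDUE_SPACING * (i - 1)
            if i in iface_set:
                # Tip gap fixed after both tip elements are known; place
                # provisionally at the midline and adjust below.
                res_atoms = _build_residue(
                    chain, i, res_type, x, y0, toward, tip_y=mid - toward * 2.0
                )
                tip_atoms[(chain, i)] = res_atoms[-1]
            else:
                res_atoms = _build_residue(chain, i, res_type, x, y0, -toward)
            atoms.extend(res_atoms)

    # Second pass: pin each planted tip pair at r_a + r_b + margin/2 apart,
    # symmetric about the midline.
    adjusted: dict[tuple[str, int, str], float] = {}
    contacts: list[tuple[int, float]] = []
    for i in iface_set:
        ra = tip_atoms[("A", i)].vdw_radius
        rb = tip_atoms[("B", i)].vdw_radius
        gap = ra + rb + margin / 2.0
        adjusted[("A", i, tip_atoms[("A", i)].atom_name)] = mid - gap / 2.0
        adjusted[("B", i, tip_atoms[("B", i)].atom_name)] = mid + gap / 2.0
        contacts.append((i, gap))
    # Rebuild interface residues completely with the exact tip positions.
    final: list[AtomRecord] = []
    done: set[tuple[str, int]] = set()
    for a in atoms:
        rkey = (a.chain_id, a.residue_index)
        if a.residue_index in iface_set:
            if rkey in done:
                continue
            done.add(rkey)
            chain = a.chain_id
            y0 = 0.0 if chain == "A" else _CHAIN_GAP
            toward = +1.0 if chain == "A" else -1.0
            tip_name = tip_atoms[rkey].atom_name
            tip_y = adjusted[(chain, a.residue_index, tip_name)]
            final.extend(
                _build_residue(
                    chain,
                    a.residue_index,
                    a.residue_type,
                    _RESIDUE_SPACING * (a.residue_index - 1),
                    y0,
                    toward,
                    tip_y=tip_y,
                )
            )
        else:
            final.append(a)

    structure = ComplexStructure(
        final, name=name or f"toy_{config.seed}_{pair_index}"
    )
    contact_pairs = []
    for i, gap in sorted(contacts):
        ta = next(
            a
            for a in structure.residue_atoms("A", i)
            if a.atom_name == tip_atoms[("A", i)].atom_name
        )
        tb = next(
            a
            for a in structure.residue_atoms("B", i)
            if a.atom_name == tip_atoms[("B", i)].atom_name
        )
        d = float(np.linalg.norm(np.subtract(ta.position, tb.position)))
        if not d < ta.vdw_radius + tb.vdw_radius + margin:
            raise GenerationError(
                f"planted contact at residue {i} failed placement (d={d:.2f})"
            )
        contact_pairs.append(
            ContactPair(ta, tb, d, clash=d < ta.vdw_radius + tb.vdw_radius)
        )
    interface = Interface(
        chain_pair=("A", "B"),
        residues_a=frozenset(iface_set),
        residues_b=frozenset(iface_set),
        contacts=tuple(contact_pairs),
    )
    return structure, interface


# -- duplicate pairs --------------------------------------------------------


def gen_duplicate_pair(
    complex_structure: ComplexStructure,
    interface: Interface,
    config: ScenarioConfig,
    pair_id: str = "pair0000",
    pair_index: int = 0,
) -> tuple[DuplicatePair, ComplexStructure, list[SiteTruth]]:
    """Plant a paralogue of chain A with controlled substitutions.

    Each site is substituted with its region's probability; interface
    substitutions carry a planted flag deciding whether the new side chain
    keeps the template's contact-tip position (contact preserved) or is
    reoriented away from the interface (contact broken). Deleted sites
    (probability ``p_del``) appear as gaps in the paralogue alignment and
    are absent from the model. Returns the pair record, the paralogue model
    (modified chain A + unchanged partner chain B, shared frame) and the
    per-site truth table.
    """
    rng = config.rng(2, pair_index)
    chain_a, chain_b = interface.chain_pair
    L = complex_structure.chain_length(chain_a)
    iface = set(interface.residues_a)

    truth: list[SiteTruth] = []
    new_types: dict[int, str | None] = {}  # None = deleted
    for i in range(1, L + 1):
        old = complex_structure.residue_type(chain_a, i)
        in_iface = i in iface
        deleted = bool(rng.random() < config.p_del)
        substituted = False
        preserved: bool | None = None
        if deleted:
            new_types[i] = None
            if in_iface:
                preserved = False  # a gap never preserves contacts
        else:
            p = config.p_sub_interface if in_iface else config.p_sub_noninterface
            substituted = bool(rng.random() < p)
            if substituted:
                if in_iface:
                    preserved = bool(rng.random() < config.p_contact_preserved)
                    pool = INTERFACE_TYPES if preserved else ALL_TYPES
                else:
                    pool = ALL_TYPES
                choices = [t for t in pool if t != old]
                new_types[i] = str(rng.choice(choices))
            else:
                new_types[i] = old
        truth.append(
            SiteTruth(
                site=i,
                interface=in_iface,
                substituted=substituted,
                deleted=deleted,
                contact_preserved=preserved,
            )
        )

    # Build the paralogue model: modified chain A (renumbered contiguously
    # over non-deleted residues) + an unchanged copy of chain B.
    tip_y_by_res: dict[int, float] = {}
    for c in interface.contacts:
        tip_y_by_res[c.atom_a.residue_index] = c.atom_a.position[1]
    model_atoms: list[AtomRecord] = []
    model_index = 0
    for i in range(1, L + 1):
        nt = new_types[i]
        if nt is None:
            continue
        model_index += 1
        t = next(s for s in truth if s.site == i)
        x = _RESIDUE_SPACING * (i - 1)
        if t.substituted and t.interface and t.contact_preserved:
            tip_y = tip_y_by_res[i]
            direction = +1.0
        elif t.substituted:
            tip_y = None
            direction = -1.0  # reoriented away from the interface
        elif i in iface:
            tip_y = tip_y_by_res[i]
            direction = +1.0
        else:
            tip_y = None
            direction = -1.0
        model_atoms.extend(
            _build_residue(chain_a, model_index, nt, x, 0.0, direction, tip_y)
        )
    for a in complex_structure.chain_atoms(chain_b):
        model_atoms.append(a)
    model = ComplexStructure(model_atoms, name=f"{pair_id}_model")

    seq_a = complex_structure.sequence(chain_a)
    aligned_b = "".join(
        "-" if new_types[i] is None else AA3_TO_AA1[new_types[i]]
        for i in range(1, L + 1)
    )
    codon_a = []
    codon_b = []
    for i in range(1, L + 1):
        aa_a = seq_a[i - 1]
        codon = str(rng.choice(CODONS_FOR_AA[aa_a]))
        codon_a.append(codon)
        nt = new_types[i]
        if nt is None:
            continue
        aa_b = AA3_TO_AA1[nt]
        codon_b.append(
            codon if aa_b == aa_a else str(rng.choice(CODONS_FOR_AA[aa_b]))
        )
    pair = DuplicatePair(
        pair_id=pair_id,
        gene_a=f"{pair_id}a",
        gene_b=f"{pair_id}b",
        aligned_seq_a=seq_a,
        aligned_seq_b=aligned_b,
        duplication_class="WGD",
        age_myr=config.divergence_time,
        codon_seq_a="".join(codon_a),
        codon_seq_b="".join(codon_b),
        interface_residues_a=frozenset(iface),
        # member B's interface residues in B's own ungapped numbering:
        # the rank of each surviving interface site among non-deleted sites
        interface_residues_b=frozenset(
            sum(1 for j in range(1, t.site + 1) if new_types[j] is not None)
            for t in truth
            if t.interface and not t.deleted
        ),
    )
    return pair, model, truth


# -- interaction-loss simulation --------------------------------------------


def simulate_interaction_loss(
    config: ScenarioConfig,
    diverged_pair_flags: Mapping[str, bool] | None = None,
) -> tuple[list[EvidenceRecord], dict]:
    """Simulate post-duplication interaction loss for all pairs.

    Both members of each pair inherit an identical ancestral partner set
    (size 1 + Poisson(mean - 1)); each (gene, partner) interaction is then
    lost independently with probability loss_rate x divergence_time.
    Surviving interactions are emitted with two distinct synthetic study
    ids each, so the multiple-confidence filter retains them.

    When ``couple_loss_to_contacts`` is set and ``diverged_pair_flags``
    maps pair ids to the planted contact truth, losses are forced/cleared
    so that a pair's interactions diverge iff its flag is True.

    Returns the evidence records and a truth dict with the per-pair
    ancestral sets and losses plus aggregate counts.
    """
    p_loss = config.loss_rate * config.divergence_time
    if p_loss > 1.0:
        raise ValueError(
            f"loss probability loss_rate*divergence_time = {p_loss} > 1"
        )
    rng = config.rng(3)
    records: list[EvidenceRecord] = []
    pairs_truth: dict[str, dict] = {}
    total_anc = 0
    total_lost = 0
    coupling = config.couple_loss_to_contacts and diverged_pair_flags is not None
    for k in range(config.n_pairs):
        pid = f"pair{k:04d}"
        gene_a, gene_b = f"{pid}a", f"{pid}b"
        size = 1 + int(rng.poisson(max(config.ancestral_degree_mean - 1.0, 0.0)))
        partners = [f"{pid}_P{j}" for j in range(size)]
        lost = {
            gene: set(
                p for p in partners if rng.random() < p_loss
            )
            for gene in (gene_a, gene_b)
        }
        if coupling:
            flag = bool(diverged_pair_flags.get(pid, False))
            if flag and not (lost[gene_a] or lost[gene_b]):
                lost[gene_a].add(partners[0])
            if not flag:
                lost[gene_a].clear()
                lost[gene_b].clear()
        for gene in (gene_a, gene_b):
            for j, partner in enumerate(partners):
                if partner in lost[gene]:
                    continue
                tag = "a" if gene == gene_a else "b"
                records.append(
                    EvidenceRecord(gene, partner, f"S{pid}_{j}{tag}_1")
                )
                records.append(
                    EvidenceRecord(gene, partner, f"S{pid}_{j}{tag}_2")
                )
        pairs_truth[pid] = {
            "ancestral": partners,
            "lost_a": sorted(lost[gene_a]),
            "lost_b": sorted(lost[gene_b]),
        }
        total_anc += 2 * size
        total_lost += len(lost[gene_a]) + len(lost[gene_b])
    truth = {
        "p_loss": p_loss,
        "pairs": pairs_truth,
        "total_ancestral_interactions": total_anc,
        "total_losses": total_lost,
    }
    return records, truth


# -- codon alignments --------------------------------------------------------


def _mutate_codon(
    codon: str, omega: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """One attempted point mutation; returns (codon, dN, dS) accepted counts."""
    pos = int(rng.integers(3))
    alternatives = [n for n in NUCLEOTIDES if n != codon[pos]]
    nt = alternatives[int(rng.integers(3))]
    alt = codon[:pos] + nt + codon[pos + 1 :]
    if is_stop(alt):
        return codon, 0, 0
    if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
        return alt, 0, 1
    if rng.random() < omega:
        return alt, 1, 0
    return codon, 0, 0


def gen_codon_alignment(
    config: ScenarioConfig,
    per_site_omegas: Sequence[tuple[str, float]] | None = None,
    stream: int = 0,
) -> tuple[dict[str, str], list[CodonSiteTruth]]:
    """Evolve a codon alignment down the configured tree.

    Sites follow ``config.site_classes`` (label, omega, n_sites) laid out
    in order, or an explicit per-column (label, omega) list. Each branch of
    length t attempts Poisson(3t) point mutations per codon; mutations to
    stop codons are rejected, synonymous changes always fix, and
    nonsynonymous changes fix with probability omega. Returns taxon ->
    codon sequence plus the per-column truth (class and the accepted
    substitution counts over the whole tree).
    """
    try:
        tree = dendropy.Tree.get(data=config.tree, schema="newick")
    except Exception as exc:
        raise ValueError(f"invalid Newick tree: {exc}") from exc
    if per_site_omegas is None:
        per_site_omegas = [
            (label, omega)
            for label, omega, n in config.site_classes
            for _ in range(n)
        ]
    n_sites = len(per_site_omegas)
    if n_sites == 0:
        raise ValueError("no sites configured")
    rng = config.rng(4, stream)
    root_codons = [
        str(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))])
        for _ in range(n_sites)
    ]
    seqs: dict[int, list[str]] = {}
    n_true = np.zeros(n_sites, dtype=int)
    s_true = np.zeros(n_sites, dtype=int)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = list(root_codons)
            continue
        parent = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = list(parent)
        for site, (_, omega) in enumerate(per_site_omegas):
            for _ in range(int(rng.poisson(3.0 * t))):
                new, dn, ds = _mutate_codon(child[site], omega, rng)
                child[site] = new
                n_true[site] += dn
                s_true[site] += ds
        seqs[id(node)] = child
    alignment = {
        leaf.taxon.label: "".join(seqs[id(leaf)])
        for leaf in tree.leaf_node_iter()
    }
    truth = [
        CodonSiteTruth(
            column=i,
            class_label=label,
            omega=omega,
            n_true=int(n_true[i]),
            s_true=int(s_true[i]),
        )
        for i, (label, omega) in enumerate(per_site_omegas)
    ]
    return alignment, truth


# -- scenario file output -----------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    lines = []
    for name in sequences:
        lines.append(f">{name}")
        lines.append(sequences[name])
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
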
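"""Interface geometry: atom contacts, interfaces, SASA, burial, atom roles.

Two atoms on different chains are *in contact* when their distance is less
than the sum of their van der Waals radii plus a margin (default 0.5 Å).
Pairs closer than the radii sum alone are clashes and are still counted as
contacts — side-chain placement errors in modelled structures should not
remove interface residues. All residues with at least one contacting atom
form the interface between two chains.

Solvent-accessible surface area uses the Shrake–Rupley sphere-point
quadrature; burial is SASA ≤ 5 % of the residue type's theoretical maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import MAX_SASA, SIDE_CHAIN_ATOMS
from .structures import AtomRecord, ComplexStructure

__all__ = [
    "ContactPair",
    "Interface",
    "detect_atom_contacts",
    "identify_interface",
    "shrake_rupley_sasa",
    "classify_buried",
    "classify_atom_role",
    "interface_to_tsv",
    "DEFAULT_CONTACT_MARGIN",
    "BURIED_SASA_FRACTION",
]

DEFAULT_CONTACT_MARGIN = 0.5  # Å added to the radii sum
BURIED_SASA_FRACTION = 0.05  # ≤5 % of max SASA counts as buried


@dataclass(frozen=True)
class ContactPair:
    """An inter-chain atom pair satisfying the contact criterion."""

    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    clash: bool  # distance < r_a + r_b (bad overlap; still a contact)


@dataclass(frozen=True)
class Interface:
    """Contacting residue sets between one chain pair, with their contacts."""

    chain_pair: tuple[str, str]
    residues_a: frozenset[int]
    residues_b: frozenset[int]
    contacts: tuple[ContactPair, ...]

    def __post_init__(self) -> None:
        in_contacts_a = {c.atom_a.residue_index for c in self.contacts}
        in_contacts_b = {c.atom_b.residue_index for c in self.contacts}
        if in_contacts_a != set(self.residues_a) or in_contacts_b != set(
            self.residues_b
        ):
            raise ValueError("interface residue sets inconsistent with contacts")


def detect_atom_contacts(
    structure: ComplexStructure,
    chain_a: str,
    chain_b: str,
    margin: float = DEFAULT_CONTACT_MARGIN,
) -> list[ContactPair]:
    """All inter-chain atom pairs with ``d < r_a + r_b + margin``.

    Uses a k-d tree so expected cost is near-linear in atom count; the
    result is defined (and tested) as identical to the brute-force
    all-pairs scan. Output order is deterministic: sorted by
    (residue_a, atom_a, residue_b, atom_b).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    atoms_a = structure.chain_atoms(chain_a)
    atoms_b = structure.chain_atoms(chain_b)
    xyz_a = np.array([a.position for a in atoms_a], dtype=float)
    xyz_b = np.array([b.position for b in atoms_b], dtype=float)
    r_a = np.array([a.vdw_radius for a in atoms_a])
    r_b = np.array([b.vdw_radius for b in atoms_b])
    cutoff = float(r_a.max() + r_b.max() + margin)
    tree_a, tree_b = cKDTree(xyz_a), cKDTree(xyz_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    out: list[ContactPair] = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            rsum = float(r_a[i] + r_b[j])
            if d < rsum + margin:
                out.append(
                    ContactPair(atoms_a[i], atoms_b[j], d, clash=d < rsum)
                )
    out.sort(
        key=lambda c: (
            c.atom_a.residue_index,
            c.atom_a.atom_name,
            c.atom_b.residue_index,
            c.atom_b.atom_name,
        )
    )
    return out


def identify_interface(
    contacts: Sequence[ContactPair],
    chain_pair: tuple[str, str] | None = None,
) -> Interface:
    """Collect the interface residue sets from a contact list.

    Every residue owning at least one contacting atom is an interface
    residue; clash contacts contribute exactly like ordinary ones.

    ``chain_pair`` is only needed when ``contacts`` is empty (an empty
    interface has no atoms to name its chains).
    """
    if contacts:
        pairs = {(c.atom_a.chain_id, c.atom_b.chain_id) for c in contacts}
        if len(pairs) > 1:
            raise ValueError(f"contacts span multiple chain pairs: {pairs}")
        found = next(iter(pairs))
        if chain_pair is not None and tuple(chain_pair) != found:
            raise ValueError(
                f"contacts belong to {found}, not {tuple(chain_pair)}"
            )
        chain_pair = found
    elif chain_pair is None:
        raise ValueError("empty contact list needs an explicit chain_pair")
    return Interface(
        chain_pair=tuple(chain_pair),
        residues_a=frozenset(c.atom_a.residue_index for c in contacts),
        residues_b=frozenset(c.atom_b.residue_index for c in contacts),
        contacts=tuple(contacts),
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    structure: ComplexStructure,
    chain: str,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[int, float]:
    """Per-residue solvent-accessible surface area of one chain, Å².

    Shrake–Rupley quadrature: each atom's solvent sphere (radius r + probe)
    is sampled at ``n_points`` quasi-uniform points; a point is exposed when
    outside every other atom's solvent sphere. Residue SASA is the sum of
    its atoms' exposed areas. The chain is evaluated in isolation.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    atoms = structure.chain_atoms(chain)
    xyz = np.array([a.position for a in atoms], dtype=float)
    solv_r = np.array([a.vdw_radius + probe_radius for a in atoms])
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    sasa: dict[int, float] = {}
    max_r = solv_r.max()
    for i, atom in enumerate(atoms):
        pts = xyz[i] + solv_r[i] * unit
        # Neighbours whose solvent sphere could occlude any point of i.
        nbrs = [
            j
            for j in tree.query_ball_point(xyz[i], r=solv_r[i] + max_r)
            if j != i
        ]
        exposed = np.ones(n_points, dtype=bool)
        if nbrs:
            d = np.linalg.norm(
                pts[:, None, :] - xyz[np.asarray(nbrs)][None, :, :], axis=2
            )
            exposed = np.all(d >= solv_r[np.asarray(nbrs)][None, :], axis=1)
        area = 4.0 * np.pi * solv_r[i] ** 2 * exposed.sum() / n_points
        sasa[atom.residue_index] = sasa.get(atom.residue_index, 0.0) + area
    return sasa


def classify_buried(
    residue_sasa: float,
    max_sasa_for_type: float,
    threshold: float = BURIED_SASA_FRACTION,
) -> str:
    """``buried`` iff SASA / max-SASA ≤ threshold (inclusive), else ``exposed``."""
    if residue_sasa < 0:
        raise ValueError("negative SASA")
    if max_sasa_for_type <= 0:
        raise ValueError("max_sasa_for_type must be positive")
    return "buried" if residue_sasa / max_sasa_for_type <= threshold else "exposed"


_MAIN_CHAIN = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
_KNOWN_SIDE_CHAIN = {
    name for atoms in SIDE_CHAIN_ATOMS.values() for name in atoms
}


def classify_atom_role(atom: AtomRecord) -> str:
    """Role of an atom in residue-type specificity.

    ``main_chain`` (backbone), ``c_beta``, ``h_beta`` (hydrogens on CB) or
    ``side_chain_specific`` — the residue-type-specific atoms whose contact
    fraction across interfaces the pipeline reports.
    """
    name = atom.atom_name.upper()
    if name in _MAIN_CHAIN:
        return "main_chain"
    if name == "CB":
        return "c_beta"
    if name in {"HB", "HB1", "HB2", "HB3", "1HB", "2HB", "3HB"}:
        return "h_beta"
    if name in _KNOWN_SIDE_CHAIN or (
        name.startswith("H") and len(name) <= 3
    ):
        return "side_chain_specific"
    raise ValueError(f"unknown atom name {atom.atom_name!r}")


def side_chain_specific_fraction(contacts: Iterable[ContactPair]) -> float:
    """Fraction of contacting atoms that are residue-type specific."""
    roles = []
    for c in contacts:
        roles.append(classify_atom_role(c.atom_a))
        roles.append(classify_atom_role(c.atom_b))
    if not roles:
        return float("nan")
    return sum(r == "side_chain_specific" for r in roles) / len(roles)


def interface_to_tsv(interface: Interface, path: str | Path) -> None:
    """Write an interface as TSV: chain_a, res_a, chain_b, res_b, distance, clash."""
    ca, cb = interface.chain_pair
    lines = ["chain_a\tres_a\tchain_b\tres_b\tdistance\tclash"]
    for c in interface.contacts:
        lines.append(
            f"{ca}\t{c.atom_a.residue_index}\t{cb}\t{c.atom_b.residue_index}"
            f"\t{c.distance:.3f}\t{int(c.clash)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
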
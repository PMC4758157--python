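"""Protein-complex containers and minimal PDB I/O.

The package works on two-chain complexes represented as flat lists of
:class:`AtomRecord`. Structures are written and read as a minimal PDB
dialect (ATOM records only, single model, no altLocs or insertion codes):
this is the format the synthetic generator emits, and the only dialect the
loader accepts. Real-world PDBs with insertion codes or alternate locations
are rejected with a clear error rather than silently misread.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import AA3_TO_AA1, BONDI_RADII, element_of

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "read_pdb",
    "write_pdb",
    "MIN_CHAIN_LENGTH",
]

# Chains shorter than this are dropped at load time (spurious peptides and
# protein fragments are excluded from interface analysis).
MIN_CHAIN_LENGTH = 50


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with coordinates and a van der Waals radius."""

    chain_id: str
    residue_index: int  # 1-based, contiguous per chain
    residue_type: str  # 3-letter code
    atom_name: str
    element: str
    position: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(
                f"vdw_radius must be positive for atom {self.atom_name}"
            )
        if not all(np.isfinite(self.position)):
            raise ValueError(
                f"non-finite coordinates for atom {self.atom_name}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.atom_name)


class ComplexStructure:
    """A protein complex: ordered chains of residues of heavy atoms.

    Parameters
    ----------
    atoms:
        Atom records. Residue indices must be 1-based and contiguous within
        each chain, and (chain, residue, atom name) must be unique.
    name:
        Optional identifier carried through to output files.
    """

    def __init__(self, atoms: Iterable[AtomRecord], name: str = "complex"):
        self.atoms: list[AtomRecord] = list(atoms)
        self.name = name
        if not self.atoms:
            raise ValueError("structure has no atoms")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom {a.key}")
            seen.add(a.key)
        self.chains: list[str] = []
        for a in self.atoms:
            if a.chain_id not in self.chains:
                self.chains.append(a.chain_id)
        self._residues: dict[str, dict[int, str]] = {c: {} for c in self.chains}
        for a in self.atoms:
            prev = self._residues[a.chain_id].setdefault(
                a.residue_index, a.residue_type
            )
            if prev != a.residue_type:
                raise ValueError(
                    f"conflicting residue types at {a.chain_id}:{a.residue_index}"
                )
        for c, res in self._residues.items():
            idx = sorted(res)
            if idx != list(range(1, len(idx) + 1)):
                raise ValueError(f"residue indices not contiguous in chain {c}")

    # -- queries ---------------------------------------------------------

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in structure {self.name}")
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residue_atoms(self, chain_id: str, residue_index: int) -> list[AtomRecord]:
        return [
            a
            for a in self.chain_atoms(chain_id)
            if a.residue_index == residue_index
        ]

    def chain_length(self, chain_id: str) -> int:
        return len(self._residues[chain_id])

    def residue_type(self, chain_id: str, residue_index: int) -> str:
        return self._residues[chain_id][residue_index]

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain in residue-index order."""
        res = self._residues[chain_id]
        return "".join(AA3_TO_AA1[res[i]] for i in sorted(res))

    def coordinates(self, chain_id: str) -> np.ndarray:
        return np.array(
            [a.position for a in self.chain_atoms(chain_id)], dtype=float
        )


# -- PDB I/O -------------------------------------------------------------


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write ATOM records in fixed-column PDB format (deterministic bytes)."""
    lines = []
    serial = 0
    for a in structure.atoms:
        serial += 1
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3}"
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:5d} {name}{'':1}{a.residue_type:>3} "
            f"{a.chain_id:1}{a.residue_index:4d}{'':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"{'':10}{a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(
    path: str | Path,
    radii: Mapping[str, float] | None = None,
    min_chain_length: int = MIN_CHAIN_LENGTH,
    name: str | None = None,
) -> ComplexStructure:
    """Read a minimal-PDB file into a :class:`ComplexStructure`.

    HETATM records (ligands, waters) are dropped, as are protein chains
    shorter than ``min_chain_length`` residues. Files with insertion codes
    or alternate locations are rejected.

    Parameters
    ----------
    radii:
        Element -> van der Waals radius table; defaults to Bondi radii.
    min_chain_length:
        Minimum residues per retained chain. Pass 0 to keep everything.
    """
    radii = dict(radii) if radii is not None else dict(BONDI_RADII)
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        rec = line[:6]
        if rec == "HETATM":
            continue
        if rec != "ATOM  ":
            continue
        altloc = line[16]
        if altloc not in (" ", ""):
            raise ValueError(
                f"{path}:{lineno}: alternate location {altloc!r} not supported"
            )
        icode = line[26]
        if icode not in (" ", ""):
            raise ValueError(
                f"{path}:{lineno}: insertion code {icode!r} not supported; "
                "renumber residues 1..n first"
            )
        atom_name = line[12:16].strip()
        res_type = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_index = int(line[22:26])
        pos = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        elem = line[76:78].strip() or element_of(atom_name)
        if elem not in radii:
            raise ValueError(
                f"{path}:{lineno}: no van der Waals radius for element "
                f"{elem!r} (atom {chain_id}:{res_index}:{atom_name})"
            )
        atoms.append(
            AtomRecord(
                chain_id=chain_id,
                residue_index=res_index,
                residue_type=res_type,
                atom_name=atom_name,
                element=elem,
                position=pos,
                vdw_radius=radii[elem],
            )
        )
    if not atoms:
        raise ValueError(f"{path}: no ATOM records")
    # Drop short chains, then renumber nothing: indices must already be
    # 1-based contiguous (generator guarantee; enforced by the constructor).
    lengths: dict[str, set[int]] = {}
    for a in atoms:
        lengths.setdefault(a.chain_id, set()).add(a.residue_index)
    keep = {c for c, idx in lengths.items() if len(idx) >= min_chain_length}
    kept = [a for a in atoms if a.chain_id in keep]
    if not kept:
        raise ValueError(
            f"{path}: no chain meets the {min_chain_length}-residue minimum"
        )
    return ComplexStructure(kept, name=name or Path(path).stem)
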
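"""Shared fixtures: small synthetic scenarios and brute-force helpers."""

from __future__ import annotations

import numpy as np
import pytest

from interevol.simulate import ScenarioConfig, gen_toy_complex
from interevol.structures import AtomRecord, ComplexStructure


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return ScenarioConfig(
        seed=101, n_pairs=6, chain_length=60, interface_size=8
    )


@pytest.fixture(scope="session")
def toy_complex(small_config):
    """One generated complex with its planted interface."""
    return gen_toy_complex(small_config)


def brute_force_contacts(structure, chain_a, chain_b, margin=0.5):
    """O(n^2) all-pairs contact scan: the correctness oracle."""
    out = []
    for a in structure.chain_atoms(chain_a):
        for b in structure.chain_atoms(chain_b):
            d = float(np.linalg.norm(np.subtract(a.position, b.position)))
            if d < a.vdw_radius + b.vdw_radius + margin:
                out.append((a.key, b.key, round(d, 9), d < a.vdw_radius + b.vdw_radius))
    return sorted(out)


def contact_keys(contacts):
    return sorted(
        (c.atom_a.key, c.atom_b.key, round(c.distance, 9), c.clash)
        for c in contacts
    )


def two_atom_structure(distance: float, element: str = "C", radius: float = 1.70):
    """Two single-atom chains separated by ``distance`` along x.

    Uses CB atoms (present in nearly all side chains) so that atom-role and
    residue bookkeeping stay valid.
    """
    mk = lambda chain, x: AtomRecord(  # noqa: E731
        chain_id=chain,
        residue_index=1,
        residue_type="ALA",
        atom_name="CB",
        element=element,
        position=(x, 0.0, 0.0),
        vdw_radius=radius,
    )
    return ComplexStructure([mk("A", 0.0), mk("B", distance)], name="two_atoms")
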
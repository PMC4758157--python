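"""Contact-preservation predictor of interaction conservation.

An interface substitution that still makes at least one atom contact across
the interface in the paralogue model is predicted to maintain the
interaction; any substitution that withdraws all contacts (or a deletion at
an interface column) is predicted to alter it. A pair is predicted
``diverged`` when any of its interface substitutions fails to preserve
contacts, ``conserved`` otherwise. Predictions are evaluated against the
observed interaction status with conserved interactions as the positive
class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .geometry import DEFAULT_CONTACT_MARGIN, detect_atom_contacts, Interface
from .structures import ComplexStructure

__all__ = [
    "SubstitutionContactOutcome",
    "ClassificationEvaluation",
    "substitution_contact_outcome",
    "predict_interaction_conservation",
    "evaluate_predictions",
]

VALID_STATUSES = ("conserved", "diverged")


@dataclass(frozen=True)
class SubstitutionContactOutcome:
    """Whether one interface substitution keeps contacts across the interface."""

    pair_id: str
    chain_id: str
    residue_index: int
    from_type: str
    to_type: str  # 3-letter code, or "-" for a deletion
    preserved: bool


@dataclass(frozen=True)
class ClassificationEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "tp": self.tp,
                    "fp": self.fp,
                    "fn": self.fn,
                    "tn": self.tn,
                    "precision": self.precision,
                    "recall": self.recall,
                    "f_score": self.f_score,
                },
                indent=2,
            )
            + "\n"
        )


def substitution_contact_outcome(
    template: ComplexStructure,
    model: ComplexStructure,
    interface: Interface,
    pair_id: str,
    residue_index: int,
    model_residue_index: int | None = ...,  # type: ignore[assignment]
    margin: float = DEFAULT_CONTACT_MARGIN,
) -> SubstitutionContactOutcome:
    """Contact outcome of one substituted interface residue.

    The paralogue ``model`` must share the template's coordinate frame. The
    substitution preserves contacts when any atom of the substituted
    residue in the model lies within the contact threshold of any atom of
    the partner chain (the same criterion as interface detection). A
    residue deleted from the model (to_type ``-``) never preserves.

    ``model_residue_index`` is the residue's index in the model chain,
    which differs from ``residue_index`` when the model carries deletions
    (models are renumbered contiguously); ``None`` marks the residue as
    deleted. By default the template numbering is used.
    """
    chain_a, chain_b = interface.chain_pair
    if residue_index not in interface.residues_a:
        raise ValueError(
            f"residue {chain_a}:{residue_index} is not an interface residue"
        )
    from_type = template.residue_type(chain_a, residue_index)
    if model_residue_index is ...:
        model_residue_index = residue_index
    deleted = model_residue_index is None or (
        chain_a not in model.chains
        or model_residue_index
        not in {a.residue_index for a in model.chain_atoms(chain_a)}
    )
    if model_residue_index is not None and chain_a in model.chains and deleted:
        raise ValueError(
            f"residue {chain_a}:{model_residue_index} absent from model"
        )
    if deleted:
        return SubstitutionContactOutcome(
            pair_id=pair_id,
            chain_id=chain_a,
            residue_index=residue_index,
            from_type=from_type,
            to_type="-",
            preserved=False,
        )
    to_type = model.residue_type(chain_a, model_residue_index)
    contacts = detect_atom_contacts(model, chain_a, chain_b, margin=margin)
    preserved = any(
        c.atom_a.residue_index == model_residue_index for c in contacts
    )
    return SubstitutionContactOutcome(
        pair_id=pair_id,
        chain_id=chain_a,
        residue_index=residue_index,
        from_type=from_type,
        to_type=to_type,
        preserved=preserved,
    )


def predict_interaction_conservation(
    outcomes: Iterable[SubstitutionContactOutcome],
) -> str:
    """``diverged`` iff any substitution fails to preserve contacts.

    No interface substitutions at all predicts a conserved interaction.
    """
    return (
        "diverged"
        if any(not o.preserved for o in outcomes)
        else "conserved"
    )


def evaluate_predictions(
    predicted: Sequence[str], observed: Sequence[str]
) -> ClassificationEvaluation:
    """Contingency counts and precision/recall/F of interaction predictions.

    The positive class is a *conserved* interaction. Zero-denominator
    metrics are 0 by convention.
    """
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed lists must align")
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for p, o in zip(predicted, observed):
        if p not in VALID_STATUSES or o not in VALID_STATUSES:
            raise ValueError(f"labels must be in {VALID_STATUSES}: ({p!r}, {o!r})")
        if p == "conserved":
            counts["tp" if o == "conserved" else "fp"] += 1
        else:
            counts["fn" if o == "conserved" else "tn"] += 1
    return ClassificationEvaluation(**counts)
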
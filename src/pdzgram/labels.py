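"""Peptide class rules, domain class assignment, and dataset construction.

PDZ ligand classes are read off the peptide C-terminus. Writing position 0
for the terminal residue and -2 for the residue two before it:

* Class I:   S/T at -2 and a hydrophobic residue (``Φ``) at 0,
* Class II:  ``Φ`` at -2 and ``Φ`` at 0,
* Class III: D/E at -2 and ``Φ`` at 0.

The hydrophobic set ``Φ`` is configurable; because it may not contain
S, T, D or E, the three rules are mutually exclusive. A domain observed
(in the binding records) to bind Class I peptides only is a Class I domain,
Class II only a Class II domain, and one binding both a promiscuous
Class I-II domain.

Interaction instances concatenate the domain's n-gram vector with the
truncated peptide's; class instances carry the domain vector alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np

from .encoding import ngram_frequency_vector, reduce_sequence
from .io import BINDING, ClassRecord, InteractionRecord, Sequence

__all__ = [
    "ClassRuleConfig",
    "PeptideClass",
    "InteractionInstance",
    "ClassInstance",
    "truncate_peptide",
    "peptide_class",
    "assign_domain_class",
    "build_interaction_dataset",
    "build_class_dataset",
    "as_arrays",
]

DEFAULT_HYDROPHOBIC = frozenset("ACFILMVWY")


@dataclass(frozen=True)
class ClassRuleConfig:
    """Parameters of the C-terminal class rules.

    ``hydrophobic`` is the residue set Φ; it must exclude S/T (Class I
    anchors) and D/E (Class III anchors) so the class rules stay disjoint.
    ``truncation_length`` is how many C-terminal residues of a peptide
    enter the feature space (binding specificity extends to about the
    last ten positions).
    """

    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC
    truncation_length: int = 10

    def __post_init__(self) -> None:
        if not self.hydrophobic:
            raise ValueError("hydrophobic set must be non-empty")
        clash = set(self.hydrophobic) & set("STDE")
        if clash:
            raise ValueError(f"hydrophobic set may not contain {sorted(clash)}")
        if self.truncation_length < 1:
            raise ValueError("truncation_length must be positive")


class PeptideClass(Enum):
    I = "I"
    II = "II"
    III = "III"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class InteractionInstance:
    """One labelled domain-peptide pair in feature space."""

    pdz_id: str
    peptide_id: str
    vector: np.ndarray = field(repr=False)
    label: str


@dataclass(frozen=True)
class ClassInstance:
    """One labelled domain in (domain-only) feature space."""

    pdz_id: str
    vector: np.ndarray = field(repr=False)
    label: str


def truncate_peptide(seq: Sequence, cfg: ClassRuleConfig = ClassRuleConfig()) -> Sequence:
    """Keep the C-terminal ``truncation_length`` residues (id preserved)."""
    if not seq.residues:
        raise ValueError(f"peptide '{seq.id}' is empty")
    return Sequence(id=seq.id, residues=seq.residues[-cfg.truncation_length:])


def peptide_class(seq: Sequence, cfg: ClassRuleConfig = ClassRuleConfig()) -> PeptideClass:
    """Classify a peptide by its C-terminal motif (needs >= 3 residues)."""
    residues = seq.residues.upper()
    if len(residues) < 3:
        raise ValueError(f"peptide '{seq.id}' too short to classify (length {len(residues)})")
    p0, pm2 = residues[-1], residues[-3]
    if p0 not in cfg.hydrophobic:
        return PeptideClass.UNCLASSIFIED
    if pm2 in "ST":
        return PeptideClass.I
    if pm2 in cfg.hydrophobic:
        return PeptideClass.II
    if pm2 in "DE":
        return PeptideClass.III
    return PeptideClass.UNCLASSIFIED


def assign_domain_class(pdz_id: str,
                        interactions: Iterable[InteractionRecord],
                        peptides: Mapping[str, Sequence],
                        cfg: ClassRuleConfig = ClassRuleConfig()) -> str:
    """Assign I / II / I-II from a domain's binding partners.

    Only records with the binding label count. Domains binding neither a
    Class I nor a Class II peptide (e.g. only Class III or unclassified
    partners) come back ``"unassigned"``.
    """
    bound_classes = set()
    for rec in interactions:
        if rec.pdz_id != pdz_id or rec.label != BINDING:
            continue
        pep = peptides.get(rec.peptide_id)
        if pep is None:
            raise KeyError(f"peptide id '{rec.peptide_id}' not found for domain '{pdz_id}'")
        bound_classes.add(peptide_class(pep, cfg))
    has_i = PeptideClass.I in bound_classes
    has_ii = PeptideClass.II in bound_classes
    if has_i and has_ii:
        return "I-II"
    if has_i:
        return "I"
    if has_ii:
        return "II"
    return "unassigned"


def _sequence_index(sequences: Iterable[Sequence]) -> dict[str, Sequence]:
    return {s.id: s for s in sequences}


def _vector(seq: Sequence, n: int, ambiguous: str) -> np.ndarray:
    reduced = reduce_sequence(seq.residues, seq.id, ambiguous=ambiguous)
    return ngram_frequency_vector(reduced, n).values


def build_interaction_dataset(sequences: Iterable[Sequence],
                              interactions: Iterable[InteractionRecord],
                              n: int = 3,
                              cfg: ClassRuleConfig = ClassRuleConfig(),
                              *,
                              ambiguous: str = "error") -> list[InteractionInstance]:
    """Build (X, Y, W) instances: domain block + truncated-peptide block + label.

    The vector is the concatenation of two independently normalized n-gram
    blocks, so it has dimension ``2 * 7**n`` (686 for trigrams, 98 for
    bigrams) and total mass 2.
    """
    index = _sequence_index(sequences)
    domain_cache: dict[str, np.ndarray] = {}
    peptide_cache: dict[str, np.ndarray] = {}
    instances = []
    for rec in interactions:
        for key, cache, transform in (
            (rec.pdz_id, domain_cache, lambda s: s),
            (rec.peptide_id, peptide_cache, lambda s: truncate_peptide(s, cfg)),
        ):
            if key not in cache:
                seq = index.get(key)
                if seq is None:
                    raise KeyError(f"interaction ({rec.pdz_id}, {rec.peptide_id}) "
                                   f"references unknown sequence id '{key}'")
                cache[key] = _vector(transform(seq), n, ambiguous)
        vector = np.concatenate([domain_cache[rec.pdz_id], peptide_cache[rec.peptide_id]])
        instances.append(InteractionInstance(rec.pdz_id, rec.peptide_id, vector, rec.label))
    return instances


def build_class_dataset(sequences: Iterable[Sequence],
                        class_records: Iterable[ClassRecord],
                        n: int = 3,
                        *,
                        ambiguous: str = "error") -> list[ClassInstance]:
    """Build domain-only instances (dimension ``7**n``) with I/II/I-II labels."""
    index = _sequence_index(sequences)
    instances = []
    for rec in class_records:
        seq = index.get(rec.pdz_id)
        if seq is None:
            raise KeyError(f"class table references unknown domain id '{rec.pdz_id}'")
        instances.append(ClassInstance(rec.pdz_id, _vector(seq, n, ambiguous), rec.label))
    return instances


def as_arrays(instances: TypingSequence[InteractionInstance | ClassInstance],
              ) -> tuple[np.ndarray, np.ndarray]:
    """Stack instances into an (n_samples, n_features) matrix and label array."""
    if not instances:
        raise ValueError("empty instance list")
    X = np.vstack([inst.vector for inst in instances])
    y = np.asarray([inst.label for inst in instances])
    return X, y
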
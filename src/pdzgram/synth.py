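"""Synthetic domains, peptides, interactions and alignments with planted truth.

The generator emulates the shape of a PDZ interaction screen — by default
85 domain sequences of length 80-90, 181 peptides of length 10, and an
interaction table whose binding label follows the class-matching rule
(a domain binds a peptide iff the peptide's C-terminal class is in the
domain's specificity set; promiscuous I-II domains accept both Class I and
Class II ligands) with independent label-flip noise ``ε``, so the
Bayes-optimal accuracy is ``1 - ε`` by construction.

Recoverable signal is planted at two levels:

* every domain carries a few copies of its class's tag trigrams (reduced
  digit strings realized as random residues of the right classes) on an
  otherwise i.i.d. background, and
* every peptide carries both its C-terminal class motif (anchor residues
  drawn from a hydrophobic generation set) and one interior class-tag
  trigram, making the peptide's class legible to a bag-of-n-grams model
  that cannot see residue positions.

Default tag grams are built around cysteine/double-cysteine patterns
(digit 7, the rarest class under a uniform background) so chance
collisions stay negligible. Ground truth is always returned alongside the
observed labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import CLASS_MEMBERS
from .io import BINDING, NON_BINDING, InteractionRecord, Sequence
from .labels import ClassRuleConfig, peptide_class

__all__ = [
    "SynthConfig",
    "DomainSet",
    "PeptideSet",
    "InteractionTable",
    "generate_domains",
    "generate_peptides",
    "generate_interactions",
    "generate_alignment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR = "-"

#: Domain-class tag trigrams; I-II domains carry both specificities' tags.
DEFAULT_PLANTED_GRAMS = {
    "I": ("774",),
    "II": ("775",),
    "I-II": ("774", "775"),
}

#: Interior tag trigrams marking each peptide class.
DEFAULT_PEPTIDE_GRAMS = {"I": ("747",), "II": ("757",), "III": ("767",)}

#: Which peptide classes each domain class accepts.
BINDING_RULE = {"I": {"I"}, "II": {"II"}, "I-II": {"I", "II"}}


def _check_gram(gram: str) -> None:
    if not gram or any(ch not in "1234567" for ch in gram):
        raise ValueError(f"planted gram {gram!r} is not a digit string over 1..7")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic world.

    Domain class proportions follow the 45:20:21 split of a real screen;
    peptide classes default to a 40/30/30 mix of Class I/II/III so that
    roughly half of random pairs bind. ``hydrophobic_gen`` is the residue
    pool used for the Φ anchor positions during generation (C-terminal
    valine/isoleucine/leucine, the anchors that dominate natural PDZ
    ligands); it avoids M/Y, whose reduced digit collides with the S/T
    anchor of Class I, keeping peptide classes separable in reduced space.
    """

    n_domains: int = 85
    n_peptides: int = 181
    domain_length: tuple[int, int] = (80, 90)
    peptide_length: int = 10
    label_noise: float = 0.05
    class_proportions: dict = field(default_factory=lambda: {
        "I": 45 / 86, "II": 20 / 86, "I-II": 21 / 86})
    peptide_class_proportions: dict = field(default_factory=lambda: {
        "I": 0.4, "II": 0.3, "III": 0.3})
    planted_grams: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_GRAMS))
    peptide_planted_grams: dict = field(default_factory=lambda: dict(DEFAULT_PEPTIDE_GRAMS))
    planted_copies: int = 2
    background: str = AMINO_ACIDS
    hydrophobic_gen: str = "VIL"
    motif: str = "12"
    motif_occupancy: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for grams in (*self.planted_grams.values(), *self.peptide_planted_grams.values()):
            for g in grams:
                _check_gram(g)
        _check_gram(self.motif)
        if self.domain_length[0] > self.domain_length[1] or self.domain_length[0] < 1:
            raise ValueError("domain_length must be a valid (min, max) range")
        if self.peptide_length < 4:
            raise ValueError("peptide_length must be at least 4")


@dataclass(frozen=True)
class DomainSet:
    sequences: list[Sequence]
    classes: dict[str, str]        # id -> "I" | "II" | "I-II"


@dataclass(frozen=True)
class PeptideSet:
    sequences: list[Sequence]
    classes: dict[str, str]        # id -> "I" | "II" | "III"


@dataclass(frozen=True)
class InteractionTable:
    records: list[InteractionRecord]           # observed labels
    true_labels: dict[tuple[str, str], str]    # noise-free labels
    n_flipped: int


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _background(rng: np.random.Generator, length: int, cfg: SynthConfig) -> list[str]:
    return list(rng.choice(list(cfg.background), size=length))


def _realize_gram(rng: np.random.Generator, gram: str) -> str:
    """Draw one residue per digit from that digit's amino-acid class."""
    return "".join(rng.choice(list(CLASS_MEMBERS[int(d)])) for d in gram)


def _plant(rng: np.random.Generator, residues: list[str], grams: list[str],
           lo: int, hi: int) -> None:
    """Overwrite non-overlapping windows in [lo, hi) with realized grams."""
    taken: list[tuple[int, int]] = []
    for gram in grams:
        span = len(gram)
        if hi - lo < span:
            raise ValueError(f"sequence region too short to plant gram {gram!r}")
        for _ in range(200):
            start = int(rng.integers(lo, hi - span + 1))
            if all(start + span <= s or start >= e for s, e in taken):
                break
        else:
            raise ValueError("planted gram density exceeds sequence capacity")
        taken.append((start, start + span))
        residues[start:start + span] = list(_realize_gram(rng, gram))


def _draw_classes(rng: np.random.Generator, n: int, proportions: dict) -> list[str]:
    labels = sorted(proportions)
    p = np.asarray([proportions[k] for k in labels], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("class proportions must be non-negative and sum > 0")
    return list(rng.choice(labels, size=n, p=p / p.sum()))


def generate_domains(cfg: SynthConfig = SynthConfig()) -> DomainSet:
    """Domains with class-tag trigrams planted on an i.i.d. background."""
    rng = _rng(cfg, 1)
    classes = _draw_classes(rng, cfg.n_domains, cfg.class_proportions)
    sequences, class_map = [], {}
    for i, cls in enumerate(classes):
        length = int(rng.integers(cfg.domain_length[0], cfg.domain_length[1] + 1))
        residues = _background(rng, length, cfg)
        grams = [g for g in cfg.planted_grams.get(cls, ()) for _ in range(cfg.planted_copies)]
        _plant(rng, residues, grams, 0, length)
        seq = Sequence(id=f"pdz{i:03d}", residues="".join(residues))
        sequences.append(seq)
        class_map[seq.id] = cls
    return DomainSet(sequences=sequences, classes=class_map)


def generate_peptides(cfg: SynthConfig = SynthConfig()) -> PeptideSet:
    """Peptides with a C-terminal class motif and one interior tag trigram.

    Every generated peptide is re-checked against the class rules; the
    construction cannot silently produce a peptide of the wrong class.
    """
    rng = _rng(cfg, 2)
    classes = _draw_classes(rng, cfg.n_peptides, cfg.peptide_class_proportions)
    anchor_pool = {
        "I": "ST",
        "II": cfg.hydrophobic_gen,
        "III": "DE",
    }
    rule_cfg = ClassRuleConfig()
    sequences, class_map = [], {}
    for i, cls in enumerate(classes):
        residues = _background(rng, cfg.peptide_length, cfg)
        grams = list(cfg.peptide_planted_grams.get(cls, ()))
        # keep the last three positions for the class motif
        _plant(rng, residues, grams, 0, cfg.peptide_length - 3)
        residues[-3] = str(rng.choice(list(anchor_pool[cls])))
        residues[-1] = str(rng.choice(list(cfg.hydrophobic_gen)))
        seq = Sequence(id=f"pep{i:03d}", residues="".join(residues))
        observed = peptide_class(seq, rule_cfg).value
        if observed != cls:
            raise AssertionError(f"generated peptide {seq.id} classifies as "
                                 f"{observed}, intended {cls}")
        sequences.append(seq)
        class_map[seq.id] = cls
    return PeptideSet(sequences=sequences, classes=class_map)


def generate_interactions(domains: DomainSet, peptides: PeptideSet,
                          cfg: SynthConfig = SynthConfig(),
                          n_pairs: int | None = None) -> InteractionTable:
    """Interaction table from the class-matching rule plus label noise.

    The noise-free label of a pair is binding iff the peptide's class is
    accepted by the domain's class; each observed label then flips
    independently with probability ``cfg.label_noise``. ``n_pairs`` draws
    that many distinct pairs uniformly (default: the full cross product).
    """
    rng = _rng(cfg, 3)
    all_pairs = [(d.id, p.id) for d in domains.sequences for p in peptides.sequences]
    if n_pairs is not None:
        if not 1 <= n_pairs <= len(all_pairs):
            raise ValueError(f"n_pairs must lie in [1, {len(all_pairs)}]")
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[i] for i in sorted(idx)]
    else:
        pairs = all_pairs
    records, truth = [], {}
    n_flipped = 0
    for pdz_id, pep_id in pairs:
        accepts = BINDING_RULE[domains.classes[pdz_id]]
        true = BINDING if peptides.classes[pep_id] in accepts else NON_BINDING
        truth[(pdz_id, pep_id)] = true
        observed = true
        if rng.random() < cfg.label_noise:
            observed = NON_BINDING if true == BINDING else BINDING
            n_flipped += 1
        records.append(InteractionRecord(pdz_id, pep_id, observed))
    return InteractionTable(records=records, true_labels=truth, n_flipped=n_flipped)


def generate_alignment(domains: DomainSet,
                       cfg: SynthConfig = SynthConfig()) -> tuple[list[Sequence], int]:
    """Gap-pad domains to one width and plant a conserved motif column block.

    Sequences are right-padded with terminal gaps; one gap-free column
    window (within every row's residue span) is overwritten so that its
    reduced digits equal ``cfg.motif`` in at least ``cfg.motif_occupancy``
    of rows. Returns the alignment and the planted start column.
    """
    if not domains.sequences:
        raise ValueError("cannot align an empty domain set")
    rng = _rng(cfg, 4)
    lengths = [len(s.residues) for s in domains.sequences]
    width, shortest = max(lengths), min(lengths)
    span = len(cfg.motif)
    if shortest < span:
        raise ValueError("motif longer than the shortest sequence")
    column = int(rng.integers(0, shortest - span + 1))
    rows = []
    for seq in domains.sequences:
        residues = list(seq.residues)
        if rng.random() < cfg.motif_occupancy:
            residues[column:column + span] = list(_realize_gram(rng, cfg.motif))
        padded = "".join(residues) + GAP_CHAR * (width - len(residues))
        rows.append(Sequence(id=seq.id, residues=padded))
    return rows, column
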
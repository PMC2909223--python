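"""Map selected n-gram features onto an alignment and report conserved motifs.

A motif here is a reduced-alphabet gram (e.g. ``"12"`` = small-apolar
followed by large-apolar, the signature of the GLGF carboxylate-binding
loop). For every alignment column window, each row whose window is
gap-free is checked against the motif after reduction; the column's
occupancy is the fraction of gap-free rows that match. Columns at or above
a conservation threshold are reported as hits, optionally annotated with
user-supplied secondary-structure regions (βA-βF strands, αA/αB helices)
given as half-open column intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd

from .encoding import AA_CLASS
from .io import Sequence
from .select import consensus_features

__all__ = ["MotifHit", "motif_occurrences", "annotate_regions", "motif_report"]

GAP = "-"


@dataclass(frozen=True)
class MotifHit:
    """One conserved occurrence of a motif at an alignment column."""

    motif: str
    column: int
    occupancy: float
    region: str = "unassigned"

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def _window_matches(window: str, motif: str) -> bool:
    for aa, digit in zip(window, motif):
        cls = AA_CLASS.get(aa.upper())
        if cls is None or str(cls) != digit:
            return False
    return True


def motif_occurrences(alignment: TypingSequence[Sequence], motif: str,
                      min_occupancy: float = 0.7) -> list[MotifHit]:
    """Columns where ``motif`` is conserved across the alignment.

    Rows with a gap anywhere in the window are excluded from both the
    numerator and the denominator of that column's occupancy; columns with
    no gap-free row are skipped.
    """
    if not alignment:
        raise ValueError("alignment is empty")
    if any(ch not in "1234567" for ch in motif) or not motif:
        raise ValueError(f"malformed motif {motif!r}")
    width = len(alignment[0].residues)
    if len(motif) > width:
        raise ValueError(f"motif {motif!r} longer than alignment width {width}")
    hits = []
    for col in range(width - len(motif) + 1):
        eligible = matched = 0
        for row in alignment:
            window = row.residues[col:col + len(motif)]
            if GAP in window:
                continue
            eligible += 1
            if _window_matches(window, motif):
                matched += 1
        if eligible == 0:
            continue
        occupancy = matched / eligible
        if occupancy >= min_occupancy:
            hits.append(MotifHit(motif=motif, column=col, occupancy=occupancy))
    return hits


def annotate_regions(hits: Iterable[MotifHit],
                     regions: TypingSequence[tuple[str, int, int]]) -> list[MotifHit]:
    """Label each hit with the half-open region interval containing its start.

    Regions may not overlap; hits outside every region keep ``"unassigned"``.
    """
    ordered = sorted(regions, key=lambda r: r[1])
    for (la, sa, ea), (lb, sb, eb) in zip(ordered, ordered[1:]):
        if sb < ea:
            raise ValueError(f"overlapping regions {la!r} [{sa},{ea}) and {lb!r} [{sb},{eb})")
    out = []
    for hit in hits:
        label = "unassigned"
        for name, start, end in ordered:
            if start <= hit.column < end:
                label = name
                break
        out.append(replace(hit, region=label))
    return out


def motif_report(selected_trigrams: Iterable[str],
                 selected_bigrams: Iterable[str],
                 alignment: TypingSequence[Sequence],
                 regions: TypingSequence[tuple[str, int, int]] | None = None,
                 min_occupancy: float = 0.7) -> pd.DataFrame:
    """Rank consensus motifs by their best conservation on the alignment.

    Consensus motifs are the selected bigrams contained in at least one
    selected trigram. Each is scanned across the alignment; the report has
    one row per (motif, column) hit, sorted by occupancy descending (ties:
    motif then column), with host trigrams and region labels attached.
    """
    consensus = consensus_features(selected_trigrams, selected_bigrams)
    rows = []
    for motif, hosts in consensus.items():
        hits = motif_occurrences(alignment, motif, min_occupancy)
        if regions is not None:
            hits = annotate_regions(hits, regions)
        for hit in hits:
            rows.append({"motif": motif, "column": hit.column,
                         "occupancy": hit.occupancy, "region": hit.region,
                         "host_trigrams": ",".join(hosts)})
    report = pd.DataFrame(rows, columns=["motif", "column", "occupancy",
                                         "region", "host_trigrams"])
    return report.sort_values(["occupancy", "motif", "column"],
                              ascending=[False, True, True]).reset_index(drop=True)
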
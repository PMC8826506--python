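"""Candidate-residue screening between two ancestral receptor sequences.

Columns where the two ancestors differ are nominated for chimeric /
point-mutant follow-up when the substitution (a) is radical — crosses
physicochemical classes, (b) has a BLOSUM62 score of 0 or below (a
relatively infrequent replacement), and (c) is conserved: every extant
sequence carries the second ancestor's residue. The class partition is
configurable so other definitions of "radical" can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "ChimeraCandidate",
    "DEFAULT_CLASS_MAP",
    "classify_substitution",
    "conservation_check",
    "screen_candidates",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Default five-class physicochemical partition for radical calls.
DEFAULT_CLASSES = {
    "hydrophobic": "AVLIMFWY",
    "polar": "STNQ",
    "positive": "KRH",
    "negative": "DE",
    "special": "GCP",
}

DEFAULT_CLASS_MAP: dict = {
    aa: cls for cls, members in DEFAULT_CLASSES.items() for aa in members
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ChimeraCandidate:
    """One alignment column where the two ancestors differ."""

    column: int  # 1-based alignment position
    domain: str  # VFT / CRD / TMD / unassigned
    res_anc1: str
    res_anc2: str
    radical: bool
    blosum: int
    conserved: bool
    passes_all: bool


def classify_substitution(
    aa1: str,
    aa2: str,
    class_map: Mapping[str, str] = DEFAULT_CLASS_MAP,
) -> tuple[bool, int]:
    """Classify one substitution: (radical?, BLOSUM62 score).

    A substitution is radical when the two residues fall in different
    classes of ``class_map``. Both residues must be canonical and
    distinct.
    """
    for aa in (aa1, aa2):
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {aa!r}")
        if aa not in class_map:
            raise ValueError(f"residue {aa!r} missing from class map")
    if aa1 == aa2:
        raise ValueError("classify_substitution requires two distinct residues")
    radical = class_map[aa1] != class_map[aa2]
    return radical, int(_BLOSUM62[aa1][aa2])


def conservation_check(
    column_states: Sequence[str], reference_state: str
) -> bool:
    """True iff every extant residue equals the reference residue.

    Gaps (or any non-matching character) count as mismatches.
    """
    states = list(column_states)
    if not states:
        raise ValueError("empty extant column")
    return all(res == reference_state for res in states)


def _assign_domain(column: int, domain_ranges: Mapping[str, tuple]) -> str:
    for name, (start, end) in domain_ranges.items():
        if start <= column <= end:
            return name
    return "unassigned"


ALL_CRITERIA = frozenset({"radical", "blosum", "conserved"})


def screen_candidates(
    anc1: str,
    anc2: str,
    extant_alignment: Mapping[str, str],
    domain_ranges: Mapping[str, tuple] | None = None,
    require: frozenset = ALL_CRITERIA,
    class_map: Mapping[str, str] = DEFAULT_CLASS_MAP,
) -> list[ChimeraCandidate]:
    """Scan an alignment for candidate columns differing between the
    two ancestral sequences.

    One candidate is produced per column where ``anc1 != anc2``;
    columns where either ancestor carries a gap are skipped (an indel
    column cannot be a point-mutation target). ``passes_all`` is the
    conjunction of the criteria named in ``require`` (subset of
    {"radical", "blosum", "conserved"}); conservation is judged against
    the ``anc2`` residue. ``domain_ranges`` maps domain names to
    1-based inclusive, disjoint column intervals.

    Returns candidates sorted by column.
    """
    unknown = set(require) - ALL_CRITERIA
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    lengths = {len(anc1), len(anc2)} | {len(s) for s in extant_alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    domain_ranges = dict(domain_ranges or {})
    intervals = sorted(domain_ranges.values())
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError("domain ranges overlap")

    extant_rows = list(extant_alignment.values())
    candidates = []
    n_gap_skipped = 0
    for i, (a1, a2) in enumerate(zip(anc1, anc2)):
        if a1 == a2:
            continue
        if a1 == "-" or a2 == "-":
            n_gap_skipped += 1
            continue
        column = i + 1
        radical, blosum = classify_substitution(a1, a2, class_map)
        conserved = conservation_check([row[i] for row in extant_rows], a2)
        checks = {
            "radical": radical,
            "blosum": blosum <= 0,
            "conserved": conserved,
        }
        candidates.append(
            ChimeraCandidate(
                column=column,
                domain=_assign_domain(column, domain_ranges),
                res_anc1=a1,
                res_anc2=a2,
                radical=radical,
                blosum=blosum,
                conserved=conserved,
                passes_all=all(checks[c] for c in require),
            )
        )
    if n_gap_skipped:
        logger.info("skipped %d differing columns with an ancestral gap", n_gap_skipped)
    return candidates
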
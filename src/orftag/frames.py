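"""Cassette frames, frame/phase compatibility and cassette-read classification.

Splice acceptors inside protein-coding exons can sit in any of the three codon
phases, so the tagging cassette comes in three variants whose splice-donor
tails differ by 0, 1 or 2 extra nucleotides after the last complete tag codon
(AAG): AAG-CAG-GT (frame 1), AAG-G-CAG-GT (frame 2), AAG-GC-CAG-GT (frame 3);
GT is the intronic donor dinucleotide.  A 1:1:1 cassette mix therefore covers
every acceptor phase.

Which cassette frame splices in-frame onto which exon phase is a declared
configuration, not derived here.  The screen's published mapping is
frame 1 -> phase 2, frame 2 -> phase 1, frame 3 -> phase 0 and is the default.
Naive codon arithmetic from the printed donor tails under GTF frame semantics
gives the rotated map {1 -> 0, 2 -> 2, 3 -> 1}; the two conventions cannot be
reconciled from the printed material alone, so both ship and the map is a
parameter (see docs/methods.md).

Cassette-derived RNA-seq reads start with a 6-nt degenerate prefix (the random
priming hexamer) followed by a frame-identifying constant region ending in the
tag's last codons; classification matches those anchors allowing a mismatch
budget (default 1), counted over the constant region only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

__all__ = [
    "CassetteFrame",
    "CASSETTES",
    "FramePhaseMap",
    "PAPER_FRAME_PHASE_MAP",
    "CODON_ARITHMETIC_FRAME_PHASE_MAP",
    "PREFIX_LENGTH",
    "is_inframe",
    "inframe_status",
    "classify_read_frame",
    "frame_phase_crosstab",
    "predict_inframe_fraction",
]

PREFIX_LENGTH = 6

_CONSTANT_CORE = "CCACGACGGAGACTACAAGGATCATGATATTGATTACAAAGACGATGACGAT"
ANCHORS: Dict[int, str] = {
    1: _CONSTANT_CORE + "AAGCAG",
    2: _CONSTANT_CORE + "AAGGCAG",
    3: _CONSTANT_CORE + "AAGGCCAG",
}


@dataclass(frozen=True)
class CassetteFrame:
    """One of the three splice-donor cassette variants."""

    frame_id: int
    dangling_nt: int  # exonic nt beyond the last complete tag codon
    donor_tail_sequence: str  # ends in the intronic GT dinucleotide
    rnaseq_anchor: str  # constant region after the 6-nt degenerate prefix

    def __post_init__(self):
        if self.dangling_nt != self.frame_id - 1:
            raise ValueError("dangling_nt must equal frame_id - 1")
        if not self.donor_tail_sequence.endswith("GT"):
            raise ValueError("donor tail must end in the GT donor dinucleotide")


CASSETTES: Dict[int, CassetteFrame] = {
    1: CassetteFrame(1, 0, "AAGCAGGT", ANCHORS[1]),
    2: CassetteFrame(2, 1, "AAGGCAGGT", ANCHORS[2]),
    3: CassetteFrame(3, 2, "AAGGCCAGGT", ANCHORS[3]),
}


class FramePhaseMap:
    """Bijection cassette frame {1,2,3} -> compatible exon phase {0,1,2}."""

    def __init__(self, mapping: Mapping[int, int]):
        if sorted(mapping) != [1, 2, 3] or sorted(mapping.values()) != [0, 1, 2]:
            raise ValueError(
                f"frame-phase map must biject {{1,2,3}} onto {{0,1,2}}, got {dict(mapping)}"
            )
        self._map = dict(mapping)

    def __getitem__(self, frame_id: int) -> int:
        return self._map[frame_id]

    def items(self):
        return self._map.items()

    def as_dict(self) -> Dict[int, int]:
        return dict(self._map)

    def __eq__(self, other) -> bool:
        return isinstance(other, FramePhaseMap) and self._map == other._map

    def __repr__(self) -> str:
        return f"FramePhaseMap({self._map})"


PAPER_FRAME_PHASE_MAP = FramePhaseMap({1: 2, 2: 1, 3: 0})
CODON_ARITHMETIC_FRAME_PHASE_MAP = FramePhaseMap({1: 0, 2: 2, 3: 1})

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
UNKNOWN = "unknown"


def inframe_status(
    frame: "CassetteFrame | int",
    exon_phase: Optional[int],
    frame_phase_map: FramePhaseMap = PAPER_FRAME_PHASE_MAP,
) -> str:
    """'in_frame' / 'out_of_frame' / 'unknown' (undefined phase)."""
    frame_id = frame.frame_id if isinstance(frame, CassetteFrame) else int(frame)
    if exon_phase is None:
        return UNKNOWN
    if exon_phase not in (0, 1, 2):
        raise ValueError(f"exon phase must be in {{0,1,2}} or None, got {exon_phase!r}")
    return IN_FRAME if frame_phase_map[frame_id] == exon_phase else OUT_OF_FRAME


def is_inframe(
    frame: "CassetteFrame | int",
    exon_phase: Optional[int],
    frame_phase_map: FramePhaseMap = PAPER_FRAME_PHASE_MAP,
) -> bool:
    """True iff the cassette frame splices in-frame onto the exon phase.

    An undefined phase is never in frame (use :func:`inframe_status` to
    distinguish 'unknown' from a genuine mismatch).
    """
    return inframe_status(frame, exon_phase, frame_phase_map) == IN_FRAME


def _hamming_vs_anchor(read: str, anchor: str) -> Optional[int]:
    """Mismatches of the read's constant region vs an anchor; None if too short.

    'N' (or anything else that is not the anchor base) counts as a mismatch.
    """
    if len(read) < PREFIX_LENGTH + len(anchor):
        return None
    region = read[PREFIX_LENGTH : PREFIX_LENGTH + len(anchor)]
    return sum(1 for a, b in zip(region, anchor) if a != b)


def classify_read_frame(
    read_sequence: str,
    max_mismatches: int = 1,
) -> tuple[Optional[int], Optional[str], Optional[int]]:
    """Assign a cassette-derived read to a frame by its anchor.

    Returns (frame_id, trimmed_remainder, n_mismatches); (None, None, None)
    when no anchor fits the budget, the read is too short, or two anchors tie
    at the minimal mismatch count (ambiguity is worse than discarding).  The
    remainder is everything after prefix + anchor — the first bases of the
    spliced acceptor exon.
    """
    read = read_sequence.upper()
    candidates: list[tuple[int, int]] = []  # (mismatches, frame_id)
    for frame_id, anchor in ANCHORS.items():
        mm = _hamming_vs_anchor(read, anchor)
        if mm is not None and mm <= max_mismatches:
            candidates.append((mm, frame_id))
    if not candidates:
        return None, None, None
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        return None, None, None
    mm, frame_id = candidates[0]
    remainder = read[PREFIX_LENGTH + len(ANCHORS[frame_id]) :]
    return frame_id, remainder, mm


def _phase_of(item) -> Optional[int]:
    # accepts raw phases, ExonRecords, or Assignments
    if item is None or isinstance(item, int):
        return item
    exon = getattr(item, "exon", item)
    return getattr(exon, "phase", None)


def frame_phase_crosstab(
    assignments_by_frame: Mapping[int, Iterable],
    frame_phase_map: FramePhaseMap = PAPER_FRAME_PHASE_MAP,
):
    """Cassette frame x assigned exon phase contingency table.

    ``assignments_by_frame`` maps frame_id (1..3) to assignments (or bare
    phase values) from the corresponding frame-specific screen.  Returns
    (table, inframe_fraction) where ``table`` is a 3x4 DataFrame (columns:
    phases 0..2 plus 'undefined') whose row sums equal the per-frame assigned
    counts, and ``inframe_fraction`` maps frame_id to the fraction of
    defined-phase assignments matching the map (None when empty).
    """
    import pandas as pd

    rows = {}
    inframe: Dict[int, Optional[float]] = {}
    for frame_id in (1, 2, 3):
        phases = [_phase_of(x) for x in assignments_by_frame.get(frame_id, [])]
        counts = {0: 0, 1: 0, 2: 0, "undefined": 0}
        for ph in phases:
            counts[ph if ph in (0, 1, 2) else "undefined"] += 1
        rows[frame_id] = counts
        defined = counts[0] + counts[1] + counts[2]
        inframe[frame_id] = (
            counts[frame_phase_map[frame_id]] / defined if defined else None
        )
    table = pd.DataFrame.from_dict(rows, orient="index")[[0, 1, 2, "undefined"]]
    table.index.name = "frame"
    return table, inframe


def predict_inframe_fraction(
    reads: Iterable[tuple[str, str]],
    exon_lookup: Mapping[str, Optional[int]],
    frame_phase_map: FramePhaseMap = PAPER_FRAME_PHASE_MAP,
    max_mismatches: int = 1,
    key_length: int = 24,
):
    """Per-frame fraction of in-frame splicing events among cassette reads.

    ``reads`` yields (read_id, sequence); ``exon_lookup`` maps the first
    ``key_length`` nt of each candidate acceptor exon (transcript orientation)
    to that exon's (corrected) phase — see
    :func:`orftag.simulate.exon_start_lookup` for building one from a toy
    genome.  Reads whose remainder cannot be located are excluded and counted.

    Returns (fractions, stats): fractions maps frame_id -> in-frame fraction
    (None when the frame has no located reads); stats counts classified /
    unclassified / unlocated reads.
    """
    located: Dict[int, list[Optional[int]]] = {1: [], 2: [], 3: []}
    stats = {"total": 0, "unclassified": 0, "unlocated": 0, "located": 0}
    for _read_id, seq in reads:
        stats["total"] += 1
        frame_id, remainder, _mm = classify_read_frame(seq, max_mismatches=max_mismatches)
        if frame_id is None:
            stats["unclassified"] += 1
            continue
        key = remainder[:key_length]
        if len(key) < key_length or key not in exon_lookup:
            stats["unlocated"] += 1
            continue
        stats["located"] += 1
        located[frame_id].append(exon_lookup[key])
    fractions: Dict[int, Optional[float]] = {}
    for frame_id, phases in located.items():
        defined = [p for p in phases if p is not None]
        if not defined:
            fractions[frame_id] = None
            continue
        hits = sum(1 for p in defined if p == frame_phase_map[frame_id])
        fractions[frame_id] = hits / len(defined)
    return fractions, stats
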
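"""Presence/absence genotyping of a known insertion from junction reads.

The caller builds two breakpoint *targets* — short reference sequences
spliced from genomic flank and insertion end around each junction — maps
short reads end-to-end against them by edit distance (via edlib's infix
alignment: the whole read aligns inside the target, gaps allowed), keeps
placements within a 5% difference budget, and counts *core-mapping* reads:
reads whose alignment places the junction within the inner 50% of the read.
A sample carries the insertion when at least ``min_reads`` unique
core-mapping reads support *both* the left and the right breakpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Iterable, Sequence

import edlib

from .simulate import reverse_complement

__all__ = [
    "BreakpointTarget",
    "ReadAlignment",
    "InsertionCall",
    "build_breakpoint_targets",
    "map_reads_to_targets",
    "classify_core_reads",
    "call_insertion_presence",
    "genotype_sample",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BreakpointTarget:
    """Junction reference sequence with the junction position marked.

    ``junction_offset`` is the 0-based index of the first base on the 3'
    side of the breakpoint within ``sequence``.
    """

    name: str  # "left" or "right"
    sequence: str
    junction_offset: int

    def __post_init__(self) -> None:
        if not 0 < self.junction_offset < len(self.sequence):
            raise ValueError("junction_offset must be strictly inside the sequence")


@dataclass
class ReadAlignment:
    read_id: str
    target_name: str
    strand: str  # "+" or "-"
    start: int  # 0-based start on the target
    read_len: int
    edit_distance: int
    unique: bool
    core: bool | None = None
    seq_key: tuple = field(default=(), repr=False)  # for optional deduplication


@dataclass(frozen=True)
class InsertionCall:
    sample: str
    support_left: int
    support_right: int
    present: bool
    min_reads: int = 2


def build_breakpoint_targets(
    ref_seq: str,
    insert_seq: str,
    insertion_pos: int,
    flank: int = 140,
) -> tuple[BreakpointTarget, BreakpointTarget]:
    """Left/right junction targets: ``flank`` bp of genomic flank + insert end.

    left  = ref[pos−flank : pos] + insert[:flank]
    right = insert[−flank:] + ref[pos : pos+flank]

    Both targets have ``junction_offset = flank``. Insufficient flank on
    either side raises instead of silently truncating.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if insertion_pos < flank:
        raise ValueError(f"only {insertion_pos} bp of left genomic flank; need {flank}")
    if len(ref_seq) - insertion_pos < flank:
        raise ValueError(
            f"only {len(ref_seq) - insertion_pos} bp of right genomic flank; need {flank}"
        )
    if len(insert_seq) < flank:
        raise ValueError(f"insert is only {len(insert_seq)} bp; need {flank}")
    left = BreakpointTarget(
        name="left",
        sequence=ref_seq[insertion_pos - flank : insertion_pos] + insert_seq[:flank],
        junction_offset=flank,
    )
    right = BreakpointTarget(
        name="right",
        sequence=insert_seq[-flank:] + ref_seq[insertion_pos : insertion_pos + flank],
        junction_offset=flank,
    )
    return left, right


def map_reads_to_targets(
    reads: Iterable[tuple[str, str]],
    targets: Sequence[BreakpointTarget],
    max_diff_frac: float = 0.05,
) -> list[ReadAlignment]:
    """Best end-to-end placements of each read (and its reverse complement).

    For every read, each target and strand is scanned for the minimal
    edit-distance placement of the full read (unit costs, gaps allowed);
    placements with edit distance ≤ floor(``max_diff_frac`` × read length)
    are retained. Only best-scoring placements are reported; a read is
    ``unique`` when exactly one placement — across both targets, both
    strands and all offsets — attains that minimum. Reads longer than a
    target are skipped with a warning.
    """
    alignments: list[ReadAlignment] = []
    for read_id, seq in reads:
        L = len(seq)
        budget = floor(max_diff_frac * L)
        candidates: list[tuple[str, str, int, int]] = []  # (target, strand, start, ed)
        best = budget + 1
        skipped = False
        for target in targets:
            if L > len(target.sequence):
                logger.warning("read %s (%d bp) longer than target %s; skipped", read_id, L, target.name)
                skipped = True
                continue
            for strand, query in (("+", seq), ("-", reverse_complement(seq))):
                res = edlib.align(query, target.sequence, mode="HW", task="locations", k=budget)
                ed = res["editDistance"]
                if ed < 0 or ed > budget:
                    continue
                for loc in res["locations"]:
                    start = loc[0] if loc[0] is not None else 0
                    candidates.append((target.name, strand, int(start), int(ed)))
                best = min(best, ed)
        if skipped and not candidates:
            continue
        winners = [c for c in candidates if c[3] == best]
        # Deduplicate identical placements edlib may report twice
        winners = sorted(set(winners))
        unique = len(winners) == 1
        for tname, strand, start, ed in winners:
            alignments.append(
                ReadAlignment(
                    read_id=read_id,
                    target_name=tname,
                    strand=strand,
                    start=start,
                    read_len=L,
                    edit_distance=ed,
                    unique=unique,
                    seq_key=(tname, strand, start, min(seq, reverse_complement(seq))),
                )
            )
    return alignments


def classify_core_reads(
    alignments: list[ReadAlignment],
    targets: Sequence[BreakpointTarget],
) -> list[ReadAlignment]:
    """Annotate alignments as core/non-core under the inner-50% rule.

    With read length L and junction offset o = junction_offset − start (the
    junction's 0-based offset within the read), an alignment is *core* iff
    ceil(L/4) ≤ o ≤ floor(3L/4): the junction falls within the inner half of
    the read, so at least a quarter of the read lies on each side. Reads not
    overlapping the junction (o ≤ 0 or o ≥ L) are non-core.
    """
    offsets = {t.name: t.junction_offset for t in targets}
    for aln in alignments:
        if aln.target_name not in offsets:
            raise ValueError(f"alignment refers to unknown target {aln.target_name!r}")
        o = offsets[aln.target_name] - aln.start
        L = aln.read_len
        aln.core = ceil(L / 4) <= o <= floor(3 * L / 4)
    return alignments


def call_insertion_presence(
    alignments: list[ReadAlignment],
    min_reads: int = 2,
    dedup: bool = False,
    sample: str = "sample",
) -> InsertionCall:
    """Count unique core-mapping reads per breakpoint and call presence.

    ``dedup`` counts reads with identical sequence and identical placement
    (same target, strand, start) once, guarding against optical/PCR
    duplicates inflating support.
    """
    support: dict[str, int] = {"left": 0, "right": 0}
    seen: set[tuple] = set()
    for aln in alignments:
        if aln.core is None:
            raise ValueError("alignments must pass classify_core_reads first")
        if not (aln.unique and aln.core):
            continue
        if dedup:
            if aln.seq_key in seen:
                continue
            seen.add(aln.seq_key)
        support[aln.target_name] = support.get(aln.target_name, 0) + 1
    present = support["left"] >= min_reads and support["right"] >= min_reads
    return InsertionCall(
        sample=sample,
        support_left=support["left"],
        support_right=support["right"],
        present=present,
        min_reads=min_reads,
    )


def genotype_sample(
    reads: Iterable[tuple[str, str]],
    ref_seq: str,
    insert_seq: str,
    insertion_pos: int,
    flank: int = 140,
    max_diff_frac: float = 0.05,
    min_reads: int = 2,
    dedup: bool = False,
    sample: str = "sample",
) -> InsertionCall:
    """Convenience wrapper: build targets, map, classify, call."""
    targets = build_breakpoint_targets(ref_seq, insert_seq, insertion_pos, flank=flank)
    alignments = map_reads_to_targets(reads, targets, max_diff_frac=max_diff_frac)
    classify_core_reads(alignments, targets)
    return call_insertion_presence(alignments, min_reads=min_reads, dedup=dedup, sample=sample)
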
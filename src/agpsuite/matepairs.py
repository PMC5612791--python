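"""Mate-pair alignment filtering and scaffold-end junction calling.

Mate pairs come from ~2 kb circularized inserts; when the two reads of a
pair land near the extremities of two *different* scaffolds they evidence
that those scaffold ends are adjacent in the chromosome.  Alignments are
filtered on end distance, mapping quality and the bowtie2 XM/XO/XG tags
(mismatches, gap opens, gap extensions); surviving cross-scaffold pairs are
tallied per scaffold-end geometry and called as junctions when a majority
geometry has enough support.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .formats import AlignmentRecord, ValidationError

HEAD = "head"
TAIL = "tail"


@dataclass
class FilterConfig:
    """Alignment-level filter thresholds.

    Defaults: reads must align within 5000 bp of a scaffold end, with
    MAPQ >= 20, and at most 2 mismatches (XM), 1 gap open (XO) and
    4 gap extensions (XG).
    """

    max_end_distance: int = 5000
    min_mapq: int = 20
    max_xm: int = 2
    max_xo: int = 1
    max_xg: int = 4

    def __post_init__(self):
        for name in ("max_end_distance", "min_mapq", "max_xm", "max_xo", "max_xg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MatePairLink:
    """One filtered read pair linking two scaffold ends.

    Normalized so that scaffold_a < scaffold_b lexicographically.
    """

    scaffold_a: str
    end_a: str
    scaffold_b: str
    end_b: str
    pair_id: str

    def __post_init__(self):
        if self.scaffold_a == self.scaffold_b:
            raise ValidationError("link endpoints on the same scaffold")
        if self.scaffold_a > self.scaffold_b:
            raise ValidationError("link not normalized (scaffold_a must sort first)")

    @property
    def geometry(self) -> tuple[str, str]:
        return (self.end_a, self.end_b)


@dataclass
class MatePairJunction:
    """A supported adjacency between two scaffold ends.

    ``support`` counts concordant links for the majority geometry;
    ``conflict`` counts links between the same scaffold pair with a
    different geometry.  Any conflict sets ``review_flag`` — the stand-in
    for the by-eye screening of multiply-connected scaffolds.
    """

    scaffold_a: str
    end_a: str
    scaffold_b: str
    end_b: str
    support: int
    conflict: int = 0

    @property
    def review_flag(self) -> bool:
        return self.conflict > 0

    def scaffolds(self) -> tuple[str, str]:
        return (self.scaffold_a, self.scaffold_b)

    def end_of(self, scaffold: str) -> str:
        if scaffold == self.scaffold_a:
            return self.end_a
        if scaffold == self.scaffold_b:
            return self.end_b
        raise KeyError(scaffold)


def end_distances(pos: int, scaffold_length: int) -> tuple[int, int]:
    """Distances (bp) from the read's leftmost base to the head (coordinate 1)
    and tail (last base) of the scaffold."""
    return pos - 1, scaffold_length - pos


def filter_alignment(aln: AlignmentRecord, scaffold_length: Optional[int],
                     cfg: FilterConfig = FilterConfig()) -> tuple[bool, str]:
    """Apply the end-distance / MAPQ / XM / XO / XG filter to one alignment.

    Returns ``(keep, reason)`` where ``reason`` names the first failed
    criterion ("end_distance", "mapq", "xm", "xo", "xg") or "pass".  The end
    distance is measured from the read's leftmost base to the nearer scaffold
    extremity and the bound is inclusive at exactly ``max_end_distance``.
    """
    if scaffold_length is None:
        raise ValidationError(f"unknown scaffold length for {aln.scaffold}")
    d_head, d_tail = end_distances(aln.pos, scaffold_length)
    if min(d_head, d_tail) > cfg.max_end_distance:
        return False, "end_distance"
    if aln.mapq < cfg.min_mapq:
        return False, "mapq"
    if aln.xm > cfg.max_xm:
        return False, "xm"
    if aln.xo > cfg.max_xo:
        return False, "xo"
    if aln.xg > cfg.max_xg:
        return False, "xg"
    return True, "pass"


def _which_end(aln: AlignmentRecord, scaffold_length: int, cfg: FilterConfig) -> str:
    d_head, d_tail = end_distances(aln.pos, scaffold_length)
    in_head = d_head <= cfg.max_end_distance
    in_tail = d_tail <= cfg.max_end_distance
    if not in_head and not in_tail:
        raise ValidationError(
            f"read {aln.read_id} near neither end of {aln.scaffold} "
            "(filter precondition violated)")
    if in_head and in_tail:        # short scaffold: both windows — take nearer
        return HEAD if d_head <= d_tail else TAIL
    return HEAD if in_head else TAIL


def pair_to_link(aln1: AlignmentRecord, aln2: AlignmentRecord,
                 scaffold_lengths: Mapping[str, int],
                 cfg: FilterConfig = FilterConfig()) -> Optional[MatePairLink]:
    """Turn two filtered mates into a scaffold-end link.

    Returns ``None`` when both reads map to the same scaffold (an intra-
    scaffold pair carries no joining information).
    """
    if aln1.mate_of != aln2.mate_of:
        raise ValidationError("records are not mates of the same pair")
    if aln1.scaffold == aln2.scaffold:
        return None
    end1 = _which_end(aln1, scaffold_lengths[aln1.scaffold], cfg)
    end2 = _which_end(aln2, scaffold_lengths[aln2.scaffold], cfg)
    a = (aln1.scaffold, end1)
    b = (aln2.scaffold, end2)
    if a[0] > b[0]:
        a, b = b, a
    return MatePairLink(scaffold_a=a[0], end_a=a[1], scaffold_b=b[0], end_b=b[1],
                        pair_id=aln1.mate_of)


def call_junctions(links: Iterable[MatePairLink],
                   min_support: int = 2) -> list[MatePairJunction]:
    """Call junctions from links by per-scaffold-pair majority geometry.

    For each scaffold pair the links are tallied by (end_a, end_b) geometry;
    the majority geometry becomes a junction when its count reaches
    ``min_support`` and strictly exceeds all other geometries combined.
    Non-majority links are reported as ``conflict`` and flag the junction
    for review.  Output is sorted by scaffold names and independent of the
    input link order.
    """
    if min_support < 2:
        raise ValidationError("min_support must be >= 2 (junctions need multiple pairs)")
    tallies: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for link in links:
        tallies[(link.scaffold_a, link.scaffold_b)][link.geometry] += 1
    junctions = []
    for (sa, sb), counter in sorted(tallies.items()):
        # deterministic majority: highest count, ties broken by geometry name
        (geom, best), *rest = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        others = sum(n for _, n in rest)
        if best >= min_support and best > others:
            junctions.append(MatePairJunction(
                scaffold_a=sa, end_a=geom[0], scaffold_b=sb, end_b=geom[1],
                support=best, conflict=others))
    return junctions


def links_from_alignments(records: Iterable[AlignmentRecord],
                          scaffold_lengths: Mapping[str, int],
                          cfg: FilterConfig = FilterConfig()) -> tuple[list[MatePairLink], Counter]:
    """Filter alignments, pair them by pair id, and build links.

    Returns the links plus a tally of discard reasons (including pairs
    dropped because a mate failed or was missing).
    """
    reasons: Counter = Counter()
    kept: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in records:
        keep, reason = filter_alignment(aln, scaffold_lengths.get(aln.scaffold), cfg)
        reasons[reason] += 1
        if keep:
            kept[aln.mate_of].append(aln)
    links = []
    for pair_id, alns in kept.items():
        if len(alns) != 2:
            reasons["unpaired"] += 1
            continue
        link = pair_to_link(alns[0], alns[1], scaffold_lengths, cfg)
        if link is None:
            reasons["same_scaffold"] += 1
        else:
            links.append(link)
    return links, reasons
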
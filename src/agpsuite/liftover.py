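"""Annotation liftover between assembly versions via shared scaffolds.

When a new assembly is a re-ordering/re-orientation of the same scaffold
set, feature coordinates transfer exactly: decompose each chromosome
coordinate to (scaffold, scaffold coordinate) through the old AGP, then
re-compose through the new AGP.  Features that land in a gap, span two
scaffolds, or sit on a scaffold absent from the new assembly are reported,
never silently moved.
"""
from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .formats import ChromosomeAssembly, Feature, GeneModel, ScaffoldPlacement

LIFTED = "lifted"
STRAND_FLIPPED = "strand_flipped"
TO_CHR00 = "to_chr00"
FAILED_GAP_SPAN = "failed_gap_span"
FAILED_UNPLACED = "failed_unplaced"


class GapSpanError(ValueError):
    """Coordinate falls inside an AGP gap row."""


class UnplacedError(ValueError):
    """Scaffold absent from the target assembly."""


@dataclass
class LiftResult:
    feature: GeneModel
    status: str
    new_seqid: Optional[str] = None
    new_start: Optional[int] = None
    new_end: Optional[int] = None
    new_strand: Optional[str] = None
    lifted: Optional[GeneModel] = None


class _AgpIndex:
    """Bisect index over component rows, by object and by scaffold."""

    def __init__(self, assembly: ChromosomeAssembly):
        self.by_object: dict[str, tuple[list[int], list[ScaffoldPlacement]]] = {}
        self.by_scaffold: dict[str, ScaffoldPlacement] = {}
        tmp: dict[str, list[ScaffoldPlacement]] = {}
        for p in assembly.placements():
            tmp.setdefault(p.object, []).append(p)
            self.by_scaffold[p.component] = p
        for obj, rows in tmp.items():
            rows.sort(key=lambda r: r.object_beg)
            self.by_object[obj] = ([r.object_beg for r in rows], rows)

    def row_at(self, seqid: str, coord: int) -> ScaffoldPlacement:
        if seqid not in self.by_object:
            raise KeyError(f"unknown sequence {seqid!r}")
        begs, rows = self.by_object[seqid]
        i = bisect.bisect_right(begs, coord) - 1
        if i < 0 or coord > rows[i].object_end:
            raise GapSpanError(f"{seqid}:{coord} falls in a gap")
        return rows[i]


def chrom_to_scaffold(seqid: str, coord: int, old_agp: ChromosomeAssembly,
                      _index: Optional[_AgpIndex] = None
                      ) -> tuple[str, int, str]:
    """Map a chromosome coordinate to (scaffold, scaffold coord, orientation).

    For '+' placements scaffold_coord = component_beg + (coord - object_beg);
    for '-' placements scaffold_coord = component_end - (coord - object_beg).
    A coordinate inside a gap row raises :class:`GapSpanError`.
    """
    index = _index or _AgpIndex(old_agp)
    row = index.row_at(seqid, coord)
    offset = coord - row.object_beg
    if row.orientation == "-":
        return row.component, row.component_end - offset, "-"
    return row.component, row.component_beg + offset, row.orientation


def scaffold_to_chrom(scaffold: str, coord: int, new_agp: ChromosomeAssembly,
                      _index: Optional[_AgpIndex] = None
                      ) -> tuple[str, int, str]:
    """Inverse of :func:`chrom_to_scaffold`; scaffolds placed in chr00 map
    into chr00 coordinates.  Raises :class:`UnplacedError` when the scaffold
    is absent from the target assembly."""
    index = _index or _AgpIndex(new_agp)
    row = index.by_scaffold.get(scaffold)
    if row is None:
        raise UnplacedError(f"scaffold {scaffold!r} not placed in the target assembly")
    if not (row.component_beg <= coord <= row.component_end):
        raise GapSpanError(
            f"{scaffold}:{coord} outside placed span "
            f"{row.component_beg}-{row.component_end}")
    if row.orientation == "-":
        return row.object, row.object_beg + (row.component_end - coord), "-"
    return row.object, row.object_beg + (coord - row.component_beg), row.orientation


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, strand)


def _lift_span(seqid: str, start: int, end: int, old_idx: _AgpIndex,
               new_idx: _AgpIndex) -> tuple[str, int, int, bool]:
    """Lift one interval; returns (new_seqid, start, end, flipped)."""
    sc1, c1, o1 = chrom_to_scaffold(seqid, start, None, old_idx)  # type: ignore[arg-type]
    sc2, c2, _ = chrom_to_scaffold(seqid, end, None, old_idx)  # type: ignore[arg-type]
    if sc1 != sc2:
        raise GapSpanError(f"{seqid}:{start}-{end} spans scaffolds {sc1} and {sc2}")
    n_seq, n1, o2 = scaffold_to_chrom(sc1, c1, None, new_idx)  # type: ignore[arg-type]
    _, n2, _ = scaffold_to_chrom(sc1, c2, None, new_idx)  # type: ignore[arg-type]
    flipped = (o1 == "-") != (o2 == "-")
    return n_seq, min(n1, n2), max(n1, n2), flipped


def lift_feature(feature: GeneModel, old_agp: ChromosomeAssembly,
                 new_agp: ChromosomeAssembly,
                 _old_idx: Optional[_AgpIndex] = None,
                 _new_idx: Optional[_AgpIndex] = None) -> LiftResult:
    """Lift one gene model (with children) between assemblies.

    The gene is lifted atomically: if any child fails, the whole gene is
    reported with that failure status.  When the scaffold's placement
    orientation differs between assemblies the strand is flipped, start/end
    swapped to keep start <= end, children re-sorted by new coordinates and
    the status is ``strand_flipped``.
    """
    old_idx = _old_idx or _AgpIndex(old_agp)
    new_idx = _new_idx or _AgpIndex(new_agp)
    try:
        n_seq, n_start, n_end, flipped = _lift_span(
            feature.seqid, feature.start, feature.end, old_idx, new_idx)
        new_children = []
        for ch in feature.children:
            cseq, cs, ce, _ = _lift_span(feature.seqid, ch.start, ch.end,
                                         old_idx, new_idx)
            if cseq != n_seq or cs < n_start or ce > n_end:
                raise GapSpanError(
                    f"child {ch.type} of {feature.id} leaves the lifted gene span")
            new_children.append(replace(
                ch, start=cs, end=ce,
                strand=_flip(ch.strand) if flipped else ch.strand))
    except UnplacedError:
        return LiftResult(feature=feature, status=FAILED_UNPLACED)
    except GapSpanError:
        return LiftResult(feature=feature, status=FAILED_GAP_SPAN)

    new_children.sort(key=lambda c: (c.start, c.end, c.type))
    new_strand = _flip(feature.strand) if flipped else feature.strand
    lifted = GeneModel(
        id=feature.id, source=feature.source, seqid=n_seq,
        start=n_start, end=n_end, strand=new_strand,
        children=new_children, protein_length=feature.protein_length)
    if n_seq == "chr00":
        status = TO_CHR00
    elif flipped:
        status = STRAND_FLIPPED
    else:
        status = LIFTED
    return LiftResult(feature=feature, status=status, new_seqid=n_seq,
                      new_start=n_start, new_end=n_end, new_strand=new_strand,
                      lifted=lifted)


@dataclass
class LiftReport:
    counts: Counter = field(default_factory=Counter)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (gene id, status)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def lift_annotation(models: Iterable[GeneModel], old_agp: ChromosomeAssembly,
                    new_agp: ChromosomeAssembly
                    ) -> tuple[list[GeneModel], LiftReport]:
    """Lift a whole annotation; failed genes are excluded from the output
    and listed in the report.  Output is sorted by new coordinates."""
    old_idx, new_idx = _AgpIndex(old_agp), _AgpIndex(new_agp)
    out: list[GeneModel] = []
    report = LiftReport()
    for model in models:
        res = lift_feature(model, old_agp, new_agp, old_idx, new_idx)
        report.counts[res.status] += 1
        if res.lifted is not None:
            out.append(res.lifted)
        else:
            report.failures.append((model.id, res.status))
    out.sort(key=lambda m: (m.seqid, m.start, m.end, m.id))
    return out, report
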
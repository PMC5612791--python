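"""Ordering and orienting scaffolds into chromosome pseudomolecules.

Evidence model: scaffolds are anchored to linkage groups by genetic markers
shared between scaffold coordinates (bp) and parental maps (cM); mate-pair
junctions confirm adjacencies and orient scaffolds lacking a cM gradient.
A scaffold is retained on a chromosome only with multiple evidence — at
least two maps, or one map plus a junction to a retained neighbor.  Maps are
the primary ordering signal; junctions confirm but never override a
consistent multi-map order.  Everything not retained goes to the chr00
random pseudomolecule.
"""
from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .formats import (ChromosomeAssembly, GapRow, MarkerRecord, ScaffoldPlacement,
                      ValidationError)
from .matepairs import HEAD, TAIL, MatePairJunction

INCREASING = "increasing"
DECREASING = "decreasing"
FLAT = "flat"
SINGLE = "single"


@dataclass
class MapAnchor:
    """One (scaffold, map) anchor: where a map places a scaffold.

    ``cM_gradient`` is the direction of cM versus scaffold coordinate over
    the scaffold's markers in this map — the orientation signal.
    """

    scaffold: str
    map: str
    linkage_group: str
    marker_count: int
    median_cM: float
    cM_gradient: str

    def __post_init__(self):
        if self.marker_count < 1:
            raise ValidationError("anchor with no markers")


@dataclass
class EvidenceRecord:
    """Retention decision for one scaffold under the multiple-evidence rule."""

    scaffold: str
    chromosome: Optional[str]
    n_maps: int
    n_junctions: int
    verdict: str  # "retained" | "chr00"


@dataclass
class TelomereHit:
    scaffold: str
    which_end: str  # head | tail
    strand: str     # + | -
    copies: int


def anchor_scaffolds(markers: Iterable[MarkerRecord],
                     scaffold_lengths: Optional[Mapping[str, int]] = None,
                     ) -> tuple[list[MapAnchor], list[str]]:
    """Aggregate markers into per-(scaffold, map) anchors.

    The linkage group is a majority vote among the scaffold's markers in
    that map; an exact tie is a conflict — the anchor is dropped and a
    warning recorded.  ``median_cM`` is taken over the majority group and
    the gradient from the slope of cM against scaffold coordinate.
    Returns (anchors, warnings).
    """
    groups: dict[tuple[str, str], list[tuple[int, str, float]]] = defaultdict(list)
    for marker in markers:
        if scaffold_lengths is not None and marker.scaffold not in scaffold_lengths:
            raise ValidationError(
                f"marker {marker.marker_id} on unknown scaffold {marker.scaffold}")
        for mp in marker.map_positions:
            groups[(marker.scaffold, mp.map)].append(
                (marker.scaffold_pos, mp.linkage_group, mp.cM))

    anchors: list[MapAnchor] = []
    warnings: list[str] = []
    for (scaffold, map_name), obs in sorted(groups.items()):
        votes = Counter(lg for _, lg, _ in obs)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            warnings.append(
                f"{scaffold}/{map_name}: linkage-group tie "
                f"({top[0][0]} vs {top[1][0]}), anchor dropped")
            continue
        lg = top[0][0]
        majority = sorted((pos, cm) for pos, g, cm in obs if g == lg)
        cms = [cm for _, cm in majority]
        median_cm = _median(cms)
        anchors.append(MapAnchor(
            scaffold=scaffold, map=map_name, linkage_group=lg,
            marker_count=len(majority), median_cM=median_cm,
            cM_gradient=_gradient(majority)))
    return anchors, warnings


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def _gradient(pos_cm: Sequence[tuple[int, float]]) -> str:
    if len(pos_cm) == 1 or len({cm for _, cm in pos_cm}) == 1:
        return SINGLE
    xs = [p for p, _ in pos_cm]
    ys = [c for _, c in pos_cm]
    xbar = sum(xs) / len(xs)
    ybar = sum(ys) / len(ys)
    slope = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    if slope > 0:
        return INCREASING
    if slope < 0:
        return DECREASING
    return FLAT


def assign_chromosomes(anchors: Iterable[MapAnchor]) -> dict[str, str]:
    """Chromosome per scaffold: majority linkage group over its map anchors
    (ties broken by total marker support, then label)."""
    votes: dict[str, Counter] = defaultdict(Counter)
    support: dict[str, Counter] = defaultdict(Counter)
    for a in anchors:
        votes[a.scaffold][a.linkage_group] += 1
        support[a.scaffold][a.linkage_group] += a.marker_count
    out = {}
    for scaffold, counter in votes.items():
        out[scaffold] = min(
            counter,
            key=lambda lg: (-counter[lg], -support[scaffold][lg], lg))
    return out


def decide_retention(anchors: Iterable[MapAnchor],
                     junctions: Iterable[MatePairJunction]) -> list[EvidenceRecord]:
    """Apply the multiple-evidence rule: retained iff anchored by >= 2 maps,
    or by >= 1 map plus a junction to a retained neighbor on the same
    chromosome (fixed-point iteration until stable)."""
    anchors = list(anchors)
    chrom = assign_chromosomes(anchors)
    n_maps: Counter = Counter()
    for a in anchors:
        if a.linkage_group == chrom[a.scaffold]:
            n_maps[a.scaffold] += 1
    neighbors: dict[str, set[str]] = defaultdict(set)
    for j in junctions:
        neighbors[j.scaffold_a].add(j.scaffold_b)
        neighbors[j.scaffold_b].add(j.scaffold_a)

    retained = {s for s, n in n_maps.items() if n >= 2}
    changed = True
    while changed:
        changed = False
        for s, n in n_maps.items():
            if s in retained or n < 1:
                continue
            if any(t in retained and chrom.get(t) == chrom[s] for t in neighbors[s]):
                retained.add(s)
                changed = True

    records = []
    for s in sorted(chrom):
        n_j = sum(1 for t in neighbors[s] if t in retained and chrom.get(t) == chrom[s])
        records.append(EvidenceRecord(
            scaffold=s, chromosome=chrom[s], n_maps=n_maps[s], n_junctions=n_j,
            verdict="retained" if s in retained else "chr00"))
    return records


@dataclass
class OrderResult:
    scaffolds: list[str]
    consensus: dict[str, float]
    uncertain: set[str] = field(default_factory=set)
    cycles: list[list[str]] = field(default_factory=list)


def order_scaffolds(chromosome: str, anchors: Iterable[MapAnchor],
                    junctions: Iterable[MatePairJunction] = (),
                    scaffold_lengths: Optional[Mapping[str, int]] = None,
                    ) -> OrderResult:
    """Order one chromosome's scaffolds by consensus genetic position.

    Consensus position = mean over maps of the rank-normalized median cM of
    the scaffold in that map; ties broken by scaffold length (descending)
    then name.  Adjacent scaffolds whose per-map orders disagree are flagged
    ``uncertain_order`` unless a junction fixes their adjacency.  Cyclic
    junction constraints are reported and the map order stands.
    """
    anchors = [a for a in anchors if a.linkage_group == chromosome]
    per_map: dict[str, list[MapAnchor]] = defaultdict(list)
    for a in anchors:
        per_map[a.map].append(a)

    positions: dict[str, list[float]] = defaultdict(list)
    map_cm: dict[str, dict[str, float]] = {}
    for map_name, alist in per_map.items():
        ordered = sorted(alist, key=lambda a: (a.median_cM, a.scaffold))
        n = len(ordered)
        for rank, a in enumerate(ordered):
            positions[a.scaffold].append(0.5 if n == 1 else rank / (n - 1))
        map_cm[map_name] = {a.scaffold: a.median_cM for a in alist}

    lengths = scaffold_lengths or {}
    consensus = {s: sum(v) / len(v) for s, v in positions.items()}
    ordered = sorted(consensus,
                     key=lambda s: (consensus[s], -lengths.get(s, 0), s))

    jset: dict[frozenset, MatePairJunction] = {
        frozenset(j.scaffolds()): j for j in junctions}
    uncertain: set[str] = set()
    for a, b in zip(ordered, ordered[1:]):
        disagree = any(
            a in cm and b in cm and cm[a] > cm[b]
            for cm in map_cm.values())
        if disagree and frozenset((a, b)) not in jset:
            uncertain.update((a, b))

    graph = nx.Graph()
    graph.add_nodes_from(ordered)
    for pair in jset:
        sa, sb = tuple(pair)
        if sa in consensus and sb in consensus:
            graph.add_edge(sa, sb)
    cycles = [sorted(c) for c in nx.cycle_basis(graph)]

    return OrderResult(scaffolds=ordered, consensus=consensus,
                       uncertain=uncertain, cycles=cycles)


def orient_scaffolds(ordered: Sequence[str], anchors: Iterable[MapAnchor],
                     junctions: Iterable[MatePairJunction] = (),
                     ) -> tuple[dict[str, str], dict[str, str], list[str]]:
    """Assign an orientation {+, -, ?} to each ordered scaffold.

    The chromosome runs in the direction of increasing cM, so a scaffold
    whose markers' cM increases with its own coordinate is '+' and one whose
    cM decreases is '-'.  Scaffolds without a usable gradient are oriented
    from junction geometry with an adjacent neighbor: the junction end named
    on a scaffold is the extremity facing its downstream/upstream neighbor
    (tail faces downstream in '+' sense).  Gradient wins over a conflicting
    junction; the conflict is logged.  Returns (orientation, source, conflicts).
    """
    ordered = list(ordered)
    index = {s: i for i, s in enumerate(ordered)}
    orientation: dict[str, str] = {s: "?" for s in ordered}
    source: dict[str, str] = {s: "none" for s in ordered}
    conflicts: list[str] = []

    votes: dict[str, Counter] = defaultdict(Counter)
    for a in anchors:
        if a.scaffold in index and a.cM_gradient in (INCREASING, DECREASING):
            votes[a.scaffold][("+" if a.cM_gradient == INCREASING else "-")] += 1
    for s, counter in votes.items():
        if len(counter) == 2 and counter["+"] == counter["-"]:
            conflicts.append(f"{s}: map gradients disagree, orientation left open")
            continue
        orientation[s] = counter.most_common(1)[0][0]
        source[s] = "map"

    for j in junctions:
        sa, sb = j.scaffolds()
        if sa not in index or sb not in index:
            continue
        if abs(index[sa] - index[sb]) != 1:
            continue
        up, down = (sa, sb) if index[sa] < index[sb] else (sb, sa)
        implied = {
            up: "+" if j.end_of(up) == TAIL else "-",
            down: "+" if j.end_of(down) == HEAD else "-",
        }
        for s, orient in implied.items():
            if source[s] == "map":
                if orientation[s] != orient:
                    conflicts.append(
                        f"{s}: junction with "
                        f"{down if s == up else up} implies {orient} but map "
                        f"gradient says {orientation[s]}; gradient kept")
            elif source[s] == "junction" and orientation[s] != orient:
                conflicts.append(f"{s}: conflicting junction orientations")
            else:
                orientation[s] = orient
                source[s] = "junction"
    return orientation, source, conflicts


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _max_tandem_copies(seq: str, motif: str) -> int:
    best = 0
    for m in re.finditer(f"(?:{re.escape(motif)})+", seq):
        best = max(best, len(m.group(0)) // len(motif))
    return best


def scan_telomere(sequence: str, which_end: str, motif: str = "TTTAGGG",
                  window: int = 10_000, min_copies: int = 10,
                  scaffold: str = "") -> Optional[TelomereHit]:
    """Look for a tandem telomere repeat within the terminal window.

    The motif is searched on both strands (the reverse complement is
    reported as strand '-'); a hit needs at least ``min_copies`` consecutive
    copies.  Used to confirm chromosome-terminal scaffolds and to fix their
    orientation: by convention a chromosome-start scaffold carries the
    motif's '-' strand at its outward end.
    """
    if not motif:
        raise ValidationError("telomere motif must be non-empty")
    if window > len(sequence):
        raise ValidationError("window larger than the sequence")
    if which_end not in (HEAD, TAIL):
        raise ValidationError(f"which_end must be head or tail, got {which_end!r}")
    terminal = sequence[:window] if which_end == HEAD else sequence[-window:]
    terminal = terminal.upper()
    fwd = _max_tandem_copies(terminal, motif.upper())
    rev = _max_tandem_copies(terminal, reverse_complement(motif.upper()))
    if max(fwd, rev) < min_copies:
        return None
    strand, copies = ("+", fwd) if fwd >= rev else ("-", rev)
    return TelomereHit(scaffold=scaffold, which_end=which_end, strand=strand, copies=copies)


def build_agp(chromosomes: Mapping[str, Sequence[tuple[str, str, str]]],
              chr00_members: Iterable[str],
              scaffold_lengths: Mapping[str, int],
              gap_length: int = 100) -> ChromosomeAssembly:
    """Assemble the AGP from ordered, oriented scaffolds.

    ``chromosomes`` maps a pseudomolecule name to ordered
    (scaffold, orientation, uncertainty) triples; the remaining scaffolds go
    to chr00 ordered by descending length.  Gap rows of ``gap_length`` bp
    (AGP type U, linkage yes) separate consecutive components.
    """
    rows: list = []
    assigned: set[str] = set()

    def add_object(name: str, members: Sequence[tuple[str, str, str]]):
        pos = 1
        for i, (scaffold, orient, uncertainty) in enumerate(members):
            if scaffold in assigned:
                raise ValidationError(f"scaffold {scaffold} assigned twice")
            assigned.add(scaffold)
            length = scaffold_lengths[scaffold]
            if i > 0:
                rows.append(GapRow(object=name, object_beg=pos,
                                   object_end=pos + gap_length - 1))
                pos += gap_length
            rows.append(ScaffoldPlacement(
                object=name, object_beg=pos, object_end=pos + length - 1,
                component=scaffold, component_beg=1, component_end=length,
                orientation=orient, uncertainty=uncertainty))
            pos += length

    for name in sorted(chromosomes):
        if chromosomes[name]:
            add_object(name, chromosomes[name])
    chr00 = sorted(chr00_members, key=lambda s: (-scaffold_lengths[s], s))
    if chr00:
        add_object("chr00", [(s, "?", "unanchored") for s in chr00])
    return ChromosomeAssembly(rows=rows, gap_length=gap_length)


@dataclass
class AnchorReportRow:
    scaffold: str
    chromosome: str
    n_maps: int
    n_junctions: int
    orientation: str
    orientation_source: str
    uncertainty: str
    telomere: str


def assemble_chromosomes(markers: Iterable[MarkerRecord],
                         junctions: Iterable[MatePairJunction],
                         scaffold_lengths: Mapping[str, int],
                         sequences: Optional[Mapping[str, str]] = None,
                         gap_length: int = 100,
                         telomere_motif: str = "TTTAGGG",
                         telomere_window: int = 10_000,
                         telomere_min_copies: int = 10,
                         chromosome_name: Optional[dict] = None,
                         strict: bool = False,
                         ) -> tuple[ChromosomeAssembly, list[AnchorReportRow], list[str]]:
    """Full anchoring pipeline: markers + junctions -> AGP + report.

    ``chromosome_name`` maps linkage-group labels to pseudomolecule names
    (defaults to the label itself).  With ``strict`` set, junctions flagged
    for review are ignored as evidence.
    """
    junctions = [j for j in junctions if not (strict and j.review_flag)]
    anchors, warnings = anchor_scaffolds(markers, scaffold_lengths)
    evidence = decide_retention(anchors, junctions)
    ev_by_scaffold = {e.scaffold: e for e in evidence}
    retained_by_chrom: dict[str, list[str]] = defaultdict(list)
    for e in evidence:
        if e.verdict == "retained":
            retained_by_chrom[e.chromosome].append(e.scaffold)

    name_of = chromosome_name or {}
    chrom_members: dict[str, list[tuple[str, str, str]]] = {}
    report: dict[str, AnchorReportRow] = {}

    for lg, members in sorted(retained_by_chrom.items()):
        chrom_anchors = [a for a in anchors
                         if a.scaffold in members and a.linkage_group == lg]
        order = order_scaffolds(lg, chrom_anchors, junctions, scaffold_lengths)
        orientation, src, conflicts = orient_scaffolds(
            order.scaffolds, chrom_anchors, junctions)
        warnings.extend(conflicts)
        for cyc in order.cycles:
            warnings.append(f"{lg}: cyclic junction constraints among {cyc}; map order kept")
        report_telomere: dict[str, str] = {}
        if sequences is not None:
            _telomere_check(order.scaffolds, orientation, src, sequences,
                            telomere_motif, telomere_window, telomere_min_copies,
                            report_telomere)
        triples = []
        for s in order.scaffolds:
            unc = "uncertain_order" if s in order.uncertain else "certain"
            triples.append((s, orientation[s], unc))
            telo = ""
            if sequences is not None and s in (order.scaffolds[0], order.scaffolds[-1]):
                telo = report_telomere.get(s, "")
            e = ev_by_scaffold[s]
            report[s] = AnchorReportRow(
                scaffold=s, chromosome=name_of.get(lg, lg), n_maps=e.n_maps,
                n_junctions=e.n_junctions, orientation=orientation[s],
                orientation_source=src[s], uncertainty=unc, telomere=telo)
        chrom_members[name_of.get(lg, lg)] = triples

    chr00 = [s for s in scaffold_lengths if s not in report]
    for s in sorted(chr00):
        e = ev_by_scaffold.get(s)
        report[s] = AnchorReportRow(
            scaffold=s, chromosome="chr00",
            n_maps=e.n_maps if e else 0, n_junctions=e.n_junctions if e else 0,
            orientation="?", orientation_source="none", uncertainty="unanchored",
            telomere="")

    assembly = build_agp(chrom_members, chr00, scaffold_lengths, gap_length)
    rows = [report[s] for s in sorted(report)]
    return assembly, rows, warnings


def _telomere_check(ordered, orientation, source, sequences, motif, window,
                    min_copies, out):
    """Confirm/flip terminal scaffolds via telomere repeats.

    The outward extremity of the first scaffold (its head in '+' sense)
    should carry the motif on '-'; the last scaffold's outward tail carries
    it on '+'.  A hit at the outward end of an unoriented terminal scaffold
    sets its orientation; a hit conflicting with an existing orientation is
    reported but the prior orientation is kept (telomeres confirm or fill
    in, map/junction evidence stays primary)."""
    if not ordered:
        return
    for which, scaffold, expect_strand in (("start", ordered[0], "-"),
                                           ("end", ordered[-1], "+")):
        seq = sequences.get(scaffold)
        if seq is None:
            continue
        w = min(window, len(seq))
        for end in (HEAD, TAIL):
            hit = scan_telomere(seq, end, motif, w, min_copies, scaffold)
            if hit is None:
                continue
            # outward end in chromosome coordinates given current orientation
            orient = orientation[scaffold]
            if orient == "?":
                # infer: a start scaffold's outward chromosome end is its
                # head if '+'; the hit strand tells which scaffold strand
                # carries the motif
                if which == "start":
                    orientation[scaffold] = "+" if (end == HEAD) == (hit.strand == expect_strand) else "-"
                else:
                    orientation[scaffold] = "+" if (end == TAIL) == (hit.strand == expect_strand) else "-"
                source[scaffold] = "telomere"
            out[scaffold] = f"{end}:{hit.strand}:{hit.copies}"
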
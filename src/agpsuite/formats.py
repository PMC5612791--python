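"""On-disk formats and in-memory domain types.

All coordinates are 1-based inclusive throughout (the GFF3/AGP convention);
any half-open arithmetic is internal to an operation and never serialized.
Readers validate coordinate invariants and refuse malformed input rather than
silently repairing it; writers guarantee byte-stable round trips.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file: carries the path and 1-based line number."""

    def __init__(self, message: str, path: object = None, line: Optional[int] = None):
        self.path = str(path) if path is not None else None
        self.line = line
        loc = ""
        if self.path is not None:
            loc = f" [{self.path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class ValidationError(ValueError):
    """In-memory object violates a type invariant."""


# ---------------------------------------------------------------------------
# gene models / GFF3
# ---------------------------------------------------------------------------

STRANDS = ("+", "-")


@dataclass
class Feature:
    """A child feature (mRNA/exon/CDS/UTR) of a gene model."""

    type: str
    start: int
    end: int
    strand: str
    id: Optional[str] = None
    parent: Optional[str] = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"feature end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A gene with its child features, tagged with its annotation source.

    ``children`` are ordered as read (or constructed); each child lies within
    [start, end]. When ``protein_length`` is set the total CDS length must be
    divisible by 3 and equal 3 * (protein_length + 1) or 3 * protein_length
    (with / without stop codon is left to the caller; only divisibility is
    enforced).
    """

    id: str
    source: str
    seqid: str
    start: int
    end: int
    strand: str
    children: list[Feature] = field(default_factory=list)
    protein_length: Optional[int] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(f"gene {self.id}: end {self.end} < start {self.start}")
        if self.strand not in STRANDS and self.strand != "?":
            raise ValidationError(f"gene {self.id}: bad strand {self.strand!r}")
        for ch in self.children:
            if ch.start < self.start or ch.end > self.end:
                raise ValidationError(
                    f"gene {self.id}: child {ch.type} {ch.start}-{ch.end} "
                    f"outside gene span {self.start}-{self.end}"
                )
        if self.protein_length is not None and self.cds_length() % 3 != 0:
            raise ValidationError(
                f"gene {self.id}: CDS length {self.cds_length()} not divisible by 3"
            )

    def cds_length(self) -> int:
        return sum(c.length for c in self.children if c.type == "CDS")

    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Sorted CDS intervals; identical tuples imply identical proteins
        for two models on the same assembly and strand."""
        return tuple(sorted((c.start, c.end) for c in self.children if c.type == "CDS"))

    def utr_length(self) -> int:
        """Combined UTR extent: gene-span bases outside the CDS envelope."""
        cds = self.cds_intervals()
        if not cds:
            return 0
        return (cds[0][0] - self.start) + (self.end - cds[-1][1])

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_GFF_ESCAPE = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09", "\n": "%0A"}


def _gff_escape(value: str) -> str:
    return "".join(_GFF_ESCAPE.get(c, c) for c in value)


def _gff_unescape(value: str) -> str:
    return re.sub(r"%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def _parse_attrs(col9: str, path, lineno) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed attribute {item!r}", path, lineno)
        key, value = item.split("=", 1)
        attrs[key] = _gff_unescape(value)
    return attrs


GENE_TYPES = {"gene", "pseudogene"}


def read_gff3(path: Union[str, Path], source_label: str) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/exon/CDS hierarchy into GeneModels.

    Every gene becomes one GeneModel tagged with ``source_label``;
    coordinates are preserved verbatim and models are returned sorted by
    (seqid, start).  A child whose Parent chain does not resolve to a gene,
    or any coordinate-invariant violation, raises :class:`FormatError` with
    the offending line number.
    """
    genes: dict[str, dict] = {}
    owner: dict[str, str] = {}  # feature id -> gene id, for Parent chains
    pending: list[tuple[int, str, dict, int, int, str]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"expected 9 columns, got {len(cols)}", path, lineno)
            seqid, source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"non-integer coordinates {start_s!r}/{end_s!r}", path, lineno)
            if end < start:
                raise FormatError(f"end {end} < start {start}", path, lineno)
            if start < 1:
                raise FormatError(f"start {start} < 1", path, lineno)
            attrs = _parse_attrs(col9, path, lineno)
            if ftype in GENE_TYPES:
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError("gene without ID attribute", path, lineno)
                if gid in genes:
                    raise FormatError(f"duplicate gene ID {gid!r}", path, lineno)
                plen = attrs.get("protein_length")
                genes[gid] = dict(
                    id=gid, seqid=seqid, start=start, end=end, strand=strand,
                    children=[], line=lineno,
                    protein_length=int(plen) if plen is not None else None,
                )
                owner[gid] = gid
            else:
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{ftype} feature without Parent", path, lineno)
                pending.append((lineno, ftype, attrs, start, end, strand))
                fid = attrs.get("ID")
                # resolve eagerly when the parent is already known (the usual
                # parent-before-child layout); otherwise FormatError below
                if parent not in owner:
                    raise FormatError(
                        f"{ftype} refers to unknown Parent {parent!r}", path, lineno
                    )
                gene = genes[owner[parent]]
                if start < gene["start"] or end > gene["end"]:
                    raise FormatError(
                        f"{ftype} {start}-{end} extends outside gene "
                        f"{gene['id']} span {gene['start']}-{gene['end']}",
                        path, lineno,
                    )
                gene["children"].append(
                    Feature(type=ftype, start=start, end=end, strand=strand,
                            id=fid, parent=parent)
                )
                if fid is not None:
                    owner[fid] = owner[parent]

    models = []
    for g in genes.values():
        g.pop("line")
        models.append(GeneModel(source=source_label, **g))
    models.sort(key=lambda m: (m.seqid, m.start, m.end, m.id))
    return models


def _attr_string(pairs: dict[str, str]) -> str:
    # fixed order: ID, Name, Parent, then alphabetical — byte-stable rewrites
    head = [k for k in ("ID", "Name", "Parent") if k in pairs]
    rest = sorted(k for k in pairs if k not in ("ID", "Name", "Parent"))
    return ";".join(f"{k}={_gff_escape(pairs[k])}" for k in head + rest)


def write_gff3(models: Iterable[GeneModel], path: Union[str, Path]) -> None:
    """Write GeneModels as GFF3. Round trip: read_gff3(write_gff3(M)) == M.

    Refuses duplicate gene ids and unresolved ('?') strands.
    """
    models = sorted(models, key=lambda m: (m.seqid, m.start, m.end, m.id))
    seen: set[str] = set()
    lines = ["##gff-version 3"]
    for m in models:
        if m.id in seen:
            raise ValidationError(f"duplicate gene id {m.id!r}")
        seen.add(m.id)
        if m.strand == "?":
            raise ValidationError(f"gene {m.id}: strand '?' must be resolved before writing")
        m.validate()
        attrs = {"ID": m.id}
        if m.protein_length is not None:
            attrs["protein_length"] = str(m.protein_length)
        lines.append("\t".join(
            [m.seqid, m.source, "gene", str(m.start), str(m.end), ".", m.strand, ".",
             _attr_string(attrs)]))
        # parents must precede children in the file: mRNAs first
        ordered_children = [c for c in m.children if c.type == "mRNA"] + \
            [c for c in m.children if c.type != "mRNA"]
        for ch in ordered_children:
            cattrs = {}
            if ch.id is not None:
                cattrs["ID"] = ch.id
            cattrs["Parent"] = ch.parent if ch.parent is not None else m.id
            lines.append("\t".join(
                [m.seqid, m.source, ch.type, str(ch.start), str(ch.end), ".", ch.strand, ".",
                 _attr_string(cattrs)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

UNCERTAINTY = ("certain", "uncertain_order", "unanchored")


@dataclass
class ScaffoldPlacement:
    """One scaffold's position and orientation inside a pseudomolecule
    (an AGP component row)."""

    object: str
    object_beg: int
    object_end: int
    component: str
    component_beg: int
    component_end: int
    orientation: str  # +, -, ?
    uncertainty: str = "certain"

    def __post_init__(self):
        if self.component_beg < 1:
            raise ValidationError(f"{self.component}: component_beg < 1")
        if self.object_end - self.object_beg != self.component_end - self.component_beg:
            raise ValidationError(
                f"{self.component}: object span {self.object_beg}-{self.object_end} and "
                f"component span {self.component_beg}-{self.component_end} differ in length"
            )
        if self.orientation not in ("+", "-", "?"):
            raise ValidationError(f"{self.component}: bad orientation {self.orientation!r}")
        if self.uncertainty not in UNCERTAINTY:
            raise ValidationError(f"{self.component}: bad uncertainty {self.uncertainty!r}")

    @property
    def length(self) -> int:
        return self.object_end - self.object_beg + 1


@dataclass
class GapRow:
    """An AGP gap row (type U or N)."""

    object: str
    object_beg: int
    object_end: int
    gap_kind: str = "U"          # U = unknown size, N = known size
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "paired-ends;map"

    @property
    def length(self) -> int:
        return self.object_end - self.object_beg + 1


AgpRow = Union[ScaffoldPlacement, GapRow]


@dataclass
class ChromosomeAssembly:
    """Ordered AGP rows (component placements and gaps) per pseudomolecule.

    Invariants: within each object the rows tile [1, object length]
    contiguously and in order; every scaffold appears at most once across
    all objects.
    """

    rows: list[AgpRow] = field(default_factory=list)
    gap_length: int = 100

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen: dict[str, str] = {}
        last: dict[str, AgpRow] = {}
        order: list[str] = []
        for row in self.rows:
            if row.object not in last:
                order.append(row.object)
                if row.object_beg != 1:
                    raise ValidationError(
                        f"{row.object}: first row starts at {row.object_beg}, not 1")
            else:
                prev = last[row.object]
                if row.object_beg <= prev.object_end:
                    pname = prev.component if isinstance(prev, ScaffoldPlacement) else "gap"
                    rname = row.component if isinstance(row, ScaffoldPlacement) else "gap"
                    raise ValidationError(
                        f"{row.object}: rows overlap — {pname} "
                        f"({prev.object_beg}-{prev.object_end}) and {rname} "
                        f"({row.object_beg}-{row.object_end})")
                if row.object_beg != prev.object_end + 1:
                    raise ValidationError(
                        f"{row.object}: gap in tiling at {prev.object_end + 1}")
            last[row.object] = row
            if isinstance(row, ScaffoldPlacement):
                if row.component in seen:
                    raise ValidationError(
                        f"scaffold {row.component} placed on both "
                        f"{seen[row.component]} and {row.object}")
                seen[row.component] = row.object

    @property
    def objects(self) -> list[str]:
        out, seen = [], set()
        for row in self.rows:
            if row.object not in seen:
                seen.add(row.object)
                out.append(row.object)
        return out

    def placements(self, obj: Optional[str] = None) -> list[ScaffoldPlacement]:
        return [r for r in self.rows
                if isinstance(r, ScaffoldPlacement) and (obj is None or r.object == obj)]

    def placement_of(self, scaffold: str) -> Optional[ScaffoldPlacement]:
        for r in self.rows:
            if isinstance(r, ScaffoldPlacement) and r.component == scaffold:
                return r
        return None


def read_agp(path: Union[str, Path]) -> ChromosomeAssembly:
    """Read an AGP v2.0 file (W component rows, U/N gap rows).

    Accepts the toolkit's optional 10th uncertainty column; rows are sorted
    by (object, object_beg) before the tiling invariants are checked.
    """
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (9, 10):
                raise FormatError(f"expected 9 or 10 columns, got {len(cols)}", path, lineno)
            obj, beg_s, end_s, _part, comp_type = cols[:5]
            try:
                beg, end = int(beg_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer object coordinates", path, lineno)
            if comp_type == "W":
                try:
                    cbeg, cend = int(cols[6]), int(cols[7])
                except ValueError:
                    raise FormatError("non-integer component coordinates", path, lineno)
                unc = cols[9] if len(cols) == 10 else "certain"
                try:
                    rows.append(ScaffoldPlacement(
                        object=obj, object_beg=beg, object_end=end,
                        component=cols[5], component_beg=cbeg, component_end=cend,
                        orientation=cols[8], uncertainty=unc))
                except ValidationError as exc:
                    raise FormatError(str(exc), path, lineno)
            elif comp_type in ("U", "N"):
                rows.append(GapRow(
                    object=obj, object_beg=beg, object_end=end, gap_kind=comp_type,
                    gap_type=cols[6], linkage=cols[7], evidence=cols[8]))
            else:
                raise FormatError(f"unsupported component type {comp_type!r}", path, lineno)
    rows.sort(key=lambda r: (r.object, r.object_beg))
    return ChromosomeAssembly(rows=rows)


def write_agp(assembly: ChromosomeAssembly, path: Union[str, Path]) -> None:
    """Write an AGP v2.0 file; round-trip stable with :func:`read_agp`."""
    assembly.validate()
    lines = ["##agp-version 2.0"]
    part: dict[str, int] = {}
    rows = sorted(assembly.rows, key=lambda r: (r.object, r.object_beg))
    for row in rows:
        part[row.object] = part.get(row.object, 0) + 1
        if isinstance(row, ScaffoldPlacement):
            cols = [row.object, str(row.object_beg), str(row.object_end), str(part[row.object]),
                    "W", row.component, str(row.component_beg), str(row.component_end),
                    row.orientation]
            if row.uncertainty != "certain":
                cols.append(row.uncertainty)
        else:
            cols = [row.object, str(row.object_beg), str(row.object_end), str(part[row.object]),
                    row.gap_kind, str(row.length), row.gap_type, row.linkage, row.evidence]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

@dataclass
class BlastHit:
    """One protein BLAST alignment with explicit query/subject lengths."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_len: int
    s_len: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: query coords "
                f"{self.q_start}-{self.q_end} invalid for length {self.q_len}")
        if not (1 <= self.s_start <= self.s_end <= self.s_len):
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: subject coords "
                f"{self.s_start}-{self.s_end} invalid for length {self.s_len}")
        if self.evalue < 0:
            raise ValidationError("negative e-value")

    @property
    def q_coverage(self) -> float:
        return (self.q_end - self.q_start + 1) / self.q_len

    @property
    def s_coverage(self) -> float:
        return (self.s_end - self.s_start + 1) / self.s_len


#: blast outfmt "6 std qlen slen"
BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore",
                 "qlen", "slen"]


def read_blast_tab(path: Union[str, Path]) -> list[BlastHit]:
    """Read extended BLAST tabular output (the standard 12 columns plus
    qlen and slen). One hit per line, order preserved, no filtering."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 14:
                raise FormatError(f"expected 14 columns, got {len(cols)}", path, lineno)
            try:
                hits.append(BlastHit(
                    query_id=cols[0], subject_id=cols[1],
                    q_start=int(cols[6]), q_end=int(cols[7]),
                    s_start=int(cols[8]), s_end=int(cols[9]),
                    q_len=int(cols[12]), s_len=int(cols[13]),
                    evalue=float(cols[10]), bitscore=float(cols[11])))
            except ValidationError as exc:
                raise FormatError(str(exc), path, lineno)
            except ValueError:
                raise FormatError("non-numeric field", path, lineno)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: Union[str, Path]) -> None:
    lines = []
    for h in hits:
        alen = max(h.q_end - h.q_start + 1, h.s_end - h.s_start + 1)
        lines.append("\t".join(map(str, [
            h.query_id, h.subject_id, "100.00", alen, 0, 0,
            h.q_start, h.q_end, h.s_start, h.s_end,
            f"{h.evalue:.2e}", f"{h.bitscore:.1f}", h.q_len, h.s_len])))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# SAM subset
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One mate-pair read alignment (SAM columns 1-11 plus XM/XO/XG tags)."""

    read_id: str
    scaffold: str
    pos: int          # leftmost, 1-based
    mapq: int
    xm: int = 0
    xo: int = 0
    xg: int = 0
    mate_of: str = ""
    read_len: int = 0

    def __post_init__(self):
        if self.mapq < 0 or self.xm < 0 or self.xo < 0 or self.xg < 0:
            raise ValidationError(f"{self.read_id}: negative quality/flag value")
        if not self.mate_of:
            self.mate_of = self.read_id


def read_sam(path: Union[str, Path]) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Read mapped records from a SAM file.

    Returns the alignment records plus the scaffold lengths from the @SQ
    header (needed by the end-distance filter). Unmapped records are skipped.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            records.append(AlignmentRecord(
                read_id=aln.query_name + ("/2" if aln.is_read2 else "/1" if aln.is_read1 else ""),
                scaffold=aln.reference_name,
                pos=aln.reference_start + 1,
                mapq=aln.mapping_quality,
                xm=aln.get_tag("XM") if aln.has_tag("XM") else 0,
                xo=aln.get_tag("XO") if aln.has_tag("XO") else 0,
                xg=aln.get_tag("XG") if aln.has_tag("XG") else 0,
                mate_of=aln.query_name,
                read_len=aln.query_length or aln.infer_read_length() or 0))
    return records, lengths


# ---------------------------------------------------------------------------
# marker / map tables
# ---------------------------------------------------------------------------

@dataclass
class MapPosition:
    map: str
    linkage_group: str
    cM: float

    def __post_init__(self):
        if self.cM < 0:
            raise ValidationError(f"negative cM {self.cM}")


@dataclass
class MarkerRecord:
    """A marker located on a scaffold (bp) and on one or more genetic maps (cM)."""

    marker_id: str
    marker_type: str  # SSR or SNP
    scaffold: str
    scaffold_pos: int
    map_positions: list[MapPosition] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for mp in self.map_positions:
            if mp.map in seen:
                raise ValidationError(
                    f"marker {self.marker_id}: duplicate entry for map {mp.map}")
            seen.add(mp.map)


MARKER_HEADER = ["marker_id", "type", "scaffold", "pos", "map", "linkage_group", "cM"]


def read_markers(path: Union[str, Path]) -> list[MarkerRecord]:
    """Read the marker/map TSV (one row per marker x map observation)."""
    by_id: dict[str, MarkerRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MARKER_HEADER:
            raise FormatError(f"bad header {header}", path, 1)
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise FormatError(f"expected 7 columns, got {len(cols)}", path, lineno)
            mid, mtype, scaffold, pos_s, map_name, lg, cm_s = cols
            try:
                pos, cm = int(pos_s), float(cm_s)
            except ValueError:
                raise FormatError("non-numeric pos/cM", path, lineno)
            mp = MapPosition(map=map_name, linkage_group=lg, cM=cm)
            if mid in by_id:
                rec = by_id[mid]
                if rec.scaffold != scaffold or rec.scaffold_pos != pos:
                    raise FormatError(
                        f"marker {mid} placed at conflicting scaffold positions",
                        path, lineno)
                if any(p.map == map_name for p in rec.map_positions):
                    raise FormatError(
                        f"marker {mid} listed twice for map {map_name}", path, lineno)
                rec.map_positions.append(mp)
            else:
                by_id[mid] = MarkerRecord(
                    marker_id=mid, marker_type=mtype, scaffold=scaffold,
                    scaffold_pos=pos, map_positions=[mp])
    return list(by_id.values())


def write_markers(markers: Iterable[MarkerRecord], path: Union[str, Path]) -> None:
    lines = ["\t".join(MARKER_HEADER)]
    for m in markers:
        for mp in m.map_positions:
            lines.append("\t".join([
                m.marker_id, m.marker_type, m.scaffold, str(m.scaffold_pos),
                mp.map, mp.linkage_group, f"{mp.cM:.4f}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
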
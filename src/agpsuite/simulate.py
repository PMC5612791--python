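"""Synthetic genomes, maps, mate pairs, annotations and homology tables.

The generator emulates — at desk scale — the inputs of a map-plus-mate-pair
chromosome assembly project with a multi-source annotation merge: random
scaffolds carrying tandem telomere repeats at chromosome-terminal outward
ends; several parental genetic maps whose cM positions increase along the
true chromosome with per-map scale and jitter; ~2 kb-insert mate pairs
landing near facing scaffold ends (plus decoy pairs violating each
alignment filter); and three annotation sources derived from one truth set
with engineered missing models, chimeric merges and splits, with BLAST hit
tables constructed so that true models score high HO and QO, chimeras high
HO / low QO and fragments low HO / high QO.

Every stream is driven by its own generator derived from the single seed,
so changing e.g. mate-pair settings does not perturb the gene simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .anchor import build_agp, reverse_complement
from .formats import (ChromosomeAssembly, Feature, GeneModel, BlastHit,
                      MapPosition, MarkerRecord, write_agp, write_blast_tab,
                      write_fasta, write_gff3, write_markers)
from .liftover import _AgpIndex

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Scale defaults are deliberately desk-sized (a few chromosomes, tens of
    scaffolds, tens of genes); structural constants mirror the emulated
    project: six parental maps, 2 kb inserts, 100 bp reads, TTTAGGG
    telomere motif.
    """

    seed: int = 0
    n_chromosomes: int = 3
    scaffolds_per_chromosome: tuple[int, int] = (4, 6)
    scaffold_length: tuple[int, int] = (8_000, 14_000)
    n_maps: int = 6
    markers_per_scaffold: tuple[int, int] = (2, 4)
    map_presence: float = 0.6        # chance a map anchors a scaffold beyond the 2 guaranteed
    map_error_rate: float = 0.0
    matepair_coverage: int = 5       # pass-filter pairs per true junction
    decoys_per_junction: int = 4     # pairs violating one filter each
    insert_size: int = 2_000
    read_length: int = 100
    n_genes: int = 90
    chimera_rate: float = 0.1
    split_rate: float = 0.1
    missing_rate: float = 0.1
    curated_fraction: float = 0.05
    telomere_motif: str = "TTTAGGG"
    telomere_copies: int = 15
    gap_length: int = 100
    hits_per_gene: int = 30
    cm_per_bp: float = 0.001
    cm_jitter: float = 0.05

    def __post_init__(self):
        for name in ("map_error_rate", "chimera_rate", "split_rate",
                     "missing_rate", "curated_fraction", "map_presence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Ground truth behind one synthetic dataset."""

    assembly: ChromosomeAssembly
    sequences: dict[str, str]
    scaffold_lengths: dict[str, int]
    chromosomes: dict[str, list[tuple[str, str]]]  # chrom -> ordered (scaffold, orientation)
    genes: list[GeneModel] = field(default_factory=list)
    error_labels: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def adjacencies(self):
        """True (scaffold, facing end) adjacencies per chromosome."""
        out = []
        for members in self.chromosomes.values():
            for (sa, oa), (sb, ob) in zip(members, members[1:]):
                end_a = "tail" if oa == "+" else "head"
                end_b = "head" if ob == "+" else "tail"
                out.append(((sa, end_a), (sb, end_b)))
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def simulate_genome(cfg: SimConfig) -> TruthSet:
    """Random scaffolds assembled into a known chromosome layout.

    Chromosome-terminal scaffolds carry tandem telomere repeats at their
    outward ends: the chromosome 5' end reads the motif's reverse complement
    on the forward strand, the 3' end the motif itself.
    """
    rng = cfg.rng(0)
    n_scaffolds = [int(rng.integers(cfg.scaffolds_per_chromosome[0],
                                    cfg.scaffolds_per_chromosome[1] + 1))
                   for _ in range(cfg.n_chromosomes)]
    total = sum(n_scaffolds)
    names = [f"scaffold_{i:04d}" for i in range(1, total + 1)]
    rng.shuffle(names)  # scaffold names carry no positional information

    sequences: dict[str, str] = {}
    chromosomes: dict[str, list[tuple[str, str]]] = {}
    cursor = 0
    motif = cfg.telomere_motif.upper()
    for ci, n in enumerate(n_scaffolds, start=1):
        chrom = f"chr{ci:02d}"
        members = []
        for si in range(n):
            name = names[cursor]
            cursor += 1
            length = int(rng.integers(cfg.scaffold_length[0], cfg.scaffold_length[1] + 1))
            seq = _random_seq(rng, length)
            orient = "+" if rng.random() < 0.5 else "-"
            if si == 0:   # chromosome 5' end: forward strand shows revcomp(motif)
                block = reverse_complement(motif) * cfg.telomere_copies
                if orient == "+":
                    seq = block + seq[len(block):]
                else:  # chromosome start is this scaffold's tail, flipped strand
                    seq = seq[:-len(block)] + motif * cfg.telomere_copies
            if si == n - 1:  # chromosome 3' end: forward strand shows the motif
                block = motif * cfg.telomere_copies
                if orient == "+":
                    seq = seq[:-len(block)] + block
                else:
                    seq = reverse_complement(motif) * cfg.telomere_copies + seq[len(block):]
            sequences[name] = seq
            members.append((name, orient))
        chromosomes[chrom] = members

    lengths = {s: len(seq) for s, seq in sequences.items()}
    assembly = build_agp(
        {c: [(s, o, "certain") for s, o in m] for c, m in chromosomes.items()},
        chr00_members=[], scaffold_lengths=lengths, gap_length=cfg.gap_length)
    return TruthSet(assembly=assembly, sequences=sequences,
                    scaffold_lengths=lengths, chromosomes=chromosomes)


def simulate_maps(truth: TruthSet, cfg: SimConfig) -> list[MarkerRecord]:
    """Markers on scaffolds with per-map cM positions.

    cM increases along the true chromosome (per-map scale in [0.8, 1.2],
    Gaussian jitter of ``cm_jitter``); each scaffold is anchored by at least
    two maps and by others with probability ``map_presence``.  A
    ``map_error_rate`` fraction of map observations get a shuffled linkage
    group.
    """
    rng = cfg.rng(1)
    maps = [f"map{m + 1}" for m in range(cfg.n_maps)]
    scales = {m: float(rng.uniform(0.8, 1.2)) for m in maps}
    chrom_names = sorted(truth.chromosomes)

    markers: list[MarkerRecord] = []
    mid = 0
    for chrom in chrom_names:
        for placement in truth.assembly.placements(chrom):
            scaffold = placement.component
            n_mk = int(rng.integers(cfg.markers_per_scaffold[0],
                                    cfg.markers_per_scaffold[1] + 1))
            length = truth.scaffold_lengths[scaffold]
            # slots >= 1 kb apart so within-scaffold cM gradients stay clear
            # of the jitter
            slots = max((length - 200) // 1_000, n_mk)
            offsets = sorted(rng.choice(slots, size=n_mk, replace=False) * 1_000 + 100)
            guaranteed = rng.choice(cfg.n_maps, size=2, replace=False)
            present = [m for i, m in enumerate(maps)
                       if i in guaranteed or rng.random() < cfg.map_presence]
            for off in offsets:
                mid += 1
                scaffold_pos = int(off)
                # chromosome position of this marker under the true layout
                if placement.orientation == "-":
                    chrom_pos = placement.object_beg + (placement.component_end - scaffold_pos)
                else:
                    chrom_pos = placement.object_beg + (scaffold_pos - placement.component_beg)
                positions = []
                for m in present:
                    lg = chrom
                    if cfg.map_error_rate > 0 and rng.random() < cfg.map_error_rate:
                        lg = chrom_names[int(rng.integers(len(chrom_names)))]
                    cm = chrom_pos * cfg.cm_per_bp * scales[m] + \
                        float(rng.normal(0, cfg.cm_jitter))
                    positions.append(MapPosition(map=m, linkage_group=lg,
                                                 cM=max(cm, 0.0)))
                markers.append(MarkerRecord(
                    marker_id=f"mk{mid:05d}",
                    marker_type="SSR" if rng.random() < 0.3 else "SNP",
                    scaffold=scaffold, scaffold_pos=scaffold_pos,
                    map_positions=positions))
    return markers


_SAM_FIELDS = "{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*" \
    "\tXM:i:{xm}\tXO:i:{xo}\tXG:i:{xg}"


def simulate_matepairs(truth: TruthSet, cfg: SimConfig) -> str:
    """SAM text for mate pairs supporting every true adjacency, plus decoys.

    Each junction gets ``matepair_coverage`` concordant pairs (high MAPQ,
    clean tags, leftmost base within the insert length of the facing end)
    and ``decoys_per_junction`` pairs that each violate exactly one filter
    (MAPQ 19, XM 3, XO 2, XG 5, or a mid-scaffold position), cycling
    through the violation kinds.
    """
    rng = cfg.rng(2)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in sorted(truth.scaffold_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{truth.scaffold_lengths[name]}")

    def pos_near(scaffold: str, end: str, max_d: Optional[int] = None) -> int:
        length = truth.scaffold_lengths[scaffold]
        d = int(rng.integers(0, max_d if max_d is not None
                             else min(cfg.insert_size, 4_500)))
        return d + 1 if end == "head" else max(length - cfg.read_length + 1 - d, 1)

    def emit(qname, read2, scaffold, pos, mapq, xm=0, xo=0, xg=0):
        flag = 0x1 | (0x80 if read2 else 0x40)
        lines.append(_SAM_FIELDS.format(
            qname=qname, flag=flag, rname=scaffold, pos=pos, mapq=mapq,
            cigar=f"{cfg.read_length}M", xm=xm, xo=xo, xg=xg))

    pid = 0
    violations = ["mapq", "xm", "xo", "xg", "mid"]
    for ji, ((sa, ea), (sb, eb)) in enumerate(truth.adjacencies()):
        for _ in range(cfg.matepair_coverage):
            pid += 1
            q = f"mp{pid:06d}"
            emit(q, False, sa, pos_near(sa, ea), int(rng.integers(30, 61)))
            emit(q, True, sb, pos_near(sb, eb), int(rng.integers(30, 61)))
        for d in range(cfg.decoys_per_junction):
            pid += 1
            q = f"mp{pid:06d}"
            kind = violations[(ji + d) % len(violations)]
            bad = dict(mapq=60, xm=0, xo=0, xg=0)
            pos_a = pos_near(sa, ea)
            if kind == "mapq":
                bad["mapq"] = 19
            elif kind == "xm":
                bad["xm"] = 3
            elif kind == "xo":
                bad["xo"] = 2
            elif kind == "xg":
                bad["xg"] = 5
            else:  # mid-scaffold read, beyond the end window
                mid_lo = 5_001 + cfg.read_length
                mid_hi = truth.scaffold_lengths[sa] - 5_001 - cfg.read_length
                if mid_hi <= mid_lo:  # scaffold too short for a mid decoy
                    bad["mapq"] = 19
                else:
                    pos_a = int(rng.integers(mid_lo, mid_hi))
            emit(q, False, sa, pos_a, bad["mapq"], bad["xm"], bad["xo"], bad["xg"])
            emit(q, True, sb, pos_near(sb, eb), 60)
    return "\n".join(lines) + "\n"


def _make_gene(gid: str, source: str, seqid: str, start: int, end: int,
               strand: str, utr5: int, utr3: int) -> GeneModel:
    cds_start = start + utr5
    cds_end = end - utr3
    excess = (cds_end - cds_start + 1) % 3
    cds_end -= excess  # keep CDS length divisible by 3
    children = [
        Feature(type="mRNA", start=start, end=end, strand=strand,
                id=f"{gid}.t1", parent=gid),
        Feature(type="exon", start=start, end=end, strand=strand,
                parent=f"{gid}.t1"),
        Feature(type="CDS", start=cds_start, end=cds_end, strand=strand,
                parent=f"{gid}.t1"),
    ]
    return GeneModel(id=gid, source=source, seqid=seqid, start=start, end=end,
                     strand=strand, children=children,
                     protein_length=(cds_end - cds_start + 1) // 3)


def _copy_as(model: GeneModel, gid: str, source: str,
             pad5: int = 0, pad3: int = 0) -> GeneModel:
    """Copy a gene under a new id/source, optionally widening the UTRs."""
    start, end = model.start - pad5, model.end + pad3
    children = [Feature(type=c.type,
                        start=start if c.type in ("mRNA", "exon") else c.start,
                        end=end if c.type in ("mRNA", "exon") else c.end,
                        strand=c.strand,
                        id=f"{gid}.t1" if c.type == "mRNA" else None,
                        parent=gid if c.type == "mRNA" else f"{gid}.t1")
                for c in model.children]
    return GeneModel(id=gid, source=source, seqid=model.seqid, start=start,
                     end=end, strand=model.strand, children=children,
                     protein_length=model.protein_length)


@dataclass
class AnnotationSet:
    sources: dict[str, list[GeneModel]]
    curated: list[GeneModel]
    hits: list[BlastHit]

    def hits_by_gene(self) -> dict[str, list[BlastHit]]:
        out: dict[str, list[BlastHit]] = {}
        for h in self.hits:
            out.setdefault(h.query_id, []).append(h)
        return out


def simulate_annotations(truth: TruthSet, cfg: SimConfig) -> AnnotationSet:
    """Three annotation sources plus curated models and their BLAST tables.

    Source errors: "cribi" drops ``missing_rate`` of the true models;
    "vcost" merges ``chimera_rate`` of the eligible adjacent same-strand
    gene pairs into chimeras (and widens UTRs on its clean copies, so the
    identical-protein longer-UTR rule is exercised); "refseq" splits
    ``split_rate`` of the genes into two fragments.  Hit tables are built
    to make true models complete (high HO and QO), chimeras chimeric_suspect
    (high HO, low QO) and fragments truncated (low HO, high QO).
    """
    rng = cfg.rng(3)
    if not truth.genes:
        _place_true_genes(truth, cfg, rng)
    genes = truth.genes
    labels: dict[str, dict[str, list[str]]] = {
        "cribi": {"missing": []}, "vcost": {"chimera": []},
        "refseq": {"split": []}, "curated": {"curated": []}}

    cribi, vcost, refseq, curated = [], [], [], []
    hits: list[BlastHit] = []

    def add_hits(gid: str, q_len: int, mode: str):
        for k in range(cfg.hits_per_gene):
            s_len = max(int(q_len * rng.uniform(0.95, 1.05)), 10)
            evalue = 10.0 ** -float(rng.uniform(40, 150))
            bitscore = float(rng.uniform(200, 900))
            if mode == "true":
                q_a, q_b = 1, max(int(q_len * 0.97), 1)
                s_a, s_b = 1, max(int(s_len * 0.97), 1)
            elif mode == "chimera":      # subject fully covered, query half
                s_a, s_b = 1, max(int(s_len * 0.97), 1)
                half = q_len // 2
                q_a = 1 if k % 2 == 0 else q_len - half + 1
                q_b = min(q_a + half - 1, q_len)
            else:                         # fragment: query covered, subject half
                s_len = max(int(q_len / 0.45), 10)
                q_a, q_b = 1, max(int(q_len * 0.97), 1)
                s_a, s_b = 1, min(q_len, s_len)
            hits.append(BlastHit(
                query_id=gid, subject_id=f"{gid}_sbj{k:03d}",
                q_start=q_a, q_end=q_b, s_start=s_a, s_end=s_b,
                q_len=q_len, s_len=s_len, evalue=evalue, bitscore=bitscore))

    # --- cribi: true models minus a missing fraction -----------------------
    for i, g in enumerate(genes):
        gid = f"cribi_{i + 1:04d}"
        if rng.random() < cfg.missing_rate:
            labels["cribi"]["missing"].append(g.id)
            continue
        model = _copy_as(g, gid, "cribi")
        cribi.append(model)
        add_hits(gid, g.protein_length, "true")

    # --- vcost: chimeric merges of adjacent pairs, widened UTRs otherwise --
    merged_away: set[str] = set()
    pairs = _adjacent_pairs(truth, genes)
    for a, b in pairs:
        if a.id in merged_away or b.id in merged_away:
            continue
        if rng.random() < cfg.chimera_rate:
            merged_away.update((a.id, b.id))
            gid = f"vcost_x{len(merged_away) // 2:03d}"
            chim = _make_gene(gid, "vcost", a.seqid, a.start, b.end, a.strand,
                              utr5=a.children[2].start - a.start,
                              utr3=b.end - b.children[2].end)
            vcost.append(chim)
            labels["vcost"]["chimera"].append(gid)
            add_hits(gid, chim.protein_length, "chimera")
    for i, g in enumerate(genes):
        if g.id in merged_away:
            continue
        gid = f"vcost_{i + 1:04d}"
        model = _copy_as(g, gid, "vcost", pad5=30, pad3=30)
        vcost.append(model)
        add_hits(gid, g.protein_length, "true")

    # --- refseq: splits ----------------------------------------------------
    for i, g in enumerate(genes):
        if rng.random() < cfg.split_rate:
            span = g.end - g.start + 1
            cut = g.start + int(span * 0.45)
            for part, (s, e) in enumerate([(g.start, cut), (cut + int(span * 0.1), g.end)]):
                gid = f"refseq_{i + 1:04d}p{part + 1}"
                frag = _make_gene(gid, "refseq", g.seqid, s, e, g.strand,
                                  utr5=10, utr3=10)
                refseq.append(frag)
                labels["refseq"]["split"].append(gid)
                add_hits(gid, frag.protein_length, "fragment")
        else:
            gid = f"refseq_{i + 1:04d}"
            refseq.append(_copy_as(g, gid, "refseq"))
            add_hits(gid, g.protein_length, "true")

    # --- curated -----------------------------------------------------------
    n_curated = int(round(cfg.curated_fraction * len(genes)))
    if n_curated:
        picks = rng.choice(len(genes), size=n_curated, replace=False)
        for i in sorted(int(p) for p in picks):
            gid = f"curated_{i + 1:04d}"
            curated.append(_copy_as(genes[i], gid, "curated"))
            labels["curated"]["curated"].append(gid)
            add_hits(gid, genes[i].protein_length, "true")

    truth.error_labels = labels
    return AnnotationSet(
        sources={"cribi": cribi, "vcost": vcost, "refseq": refseq},
        curated=curated, hits=hits)


def _place_true_genes(truth: TruthSet, cfg: SimConfig, rng: np.random.Generator):
    """Place non-overlapping true genes inside scaffold placements, in the
    chromosome coordinates of the true assembly."""
    placements = [p for chrom in sorted(truth.chromosomes)
                  for p in truth.assembly.placements(chrom)]
    weights = np.array([p.length for p in placements], dtype=float)
    per = np.floor(weights / weights.sum() * cfg.n_genes).astype(int)
    genes: list[GeneModel] = []
    gi = 0
    for p, n in zip(placements, per):
        margin = 300  # keep genes clear of scaffold edges and inter-gene gaps
        pos = p.object_beg + margin
        for _ in range(int(n)):
            span = int(rng.integers(900, 1_800))
            if pos + span > p.object_end - margin:
                break
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(
                f"true_{gi:04d}", "truth", p.object, pos, pos + span - 1,
                strand, utr5=int(rng.integers(60, 150)),
                utr3=int(rng.integers(60, 150))))
            pos += span + int(rng.integers(300, 700))
    truth.genes = genes


def _adjacent_pairs(truth: TruthSet, genes: list[GeneModel]):
    """Consecutive same-strand gene pairs lying on one scaffold placement."""
    index = _AgpIndex(truth.assembly)
    pairs = []
    for a, b in zip(genes, genes[1:]):
        if a.seqid != b.seqid or a.strand != b.strand:
            continue
        ra = index.row_at(a.seqid, a.start)
        if not (ra.object_beg <= b.end <= ra.object_end):
            continue
        pairs.append((a, b))
    return pairs


@dataclass
class Fixture:
    """One complete synthetic dataset."""

    cfg: SimConfig
    truth: TruthSet
    markers: list[MarkerRecord]
    sam_text: str
    annotations: AnnotationSet


def simulate(cfg: SimConfig) -> Fixture:
    truth = simulate_genome(cfg)
    markers = simulate_maps(truth, cfg)
    sam_text = simulate_matepairs(truth, cfg)
    annotations = simulate_annotations(truth, cfg)
    return Fixture(cfg=cfg, truth=truth, markers=markers, sam_text=sam_text,
                   annotations=annotations)


def write_fixture(fix: Fixture, outdir: Path) -> dict[str, Path]:
    """Serialize a fixture to a directory; every file parses with the
    package's own readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": outdir / "scaffolds.fasta",
        "agp": outdir / "true_assembly.agp",
        "markers": outdir / "markers.tsv",
        "sam": outdir / "matepairs.sam",
        "blast": outdir / "hits.tsv",
        "truth_genes": outdir / "truth_genes.gff3",
        "curated": outdir / "curated.gff3",
    }
    write_fasta(fix.truth.sequences, paths["scaffolds"])
    write_agp(fix.truth.assembly, paths["agp"])
    write_markers(fix.markers, paths["markers"])
    paths["sam"].write_text(fix.sam_text)
    write_blast_tab(fix.annotations.hits, paths["blast"])
    write_gff3(fix.truth.genes, paths["truth_genes"])
    write_gff3(fix.annotations.curated, paths["curated"])
    for name, models in fix.annotations.sources.items():
        p = outdir / f"{name}.gff3"
        write_gff3(models, p)
        paths[name] = p
    return paths
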
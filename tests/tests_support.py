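"""Shared helpers for the test suite: random assemblies and a per-base
mapping oracle, independent of the liftover implementation."""
from agpsuite.anchor import build_agp
from agpsuite.formats import Feature, GeneModel


def random_assembly_pair(rng, n_scaffolds=6, scaffold_len=(500, 2_000)):
    """Two random layouts (chromosome assignment, order, orientation) of
    one shared scaffold set."""
    lengths = {f"s{i}": rng.randint(*scaffold_len) for i in range(n_scaffolds)}

    def layout():
        names = list(lengths)
        rng.shuffle(names)
        n_chrom = rng.randint(1, 3)
        chroms = {f"chr{ci + 1:02d}": [] for ci in range(n_chrom)}
        for s in names:
            chroms[f"chr{rng.randint(1, n_chrom):02d}"].append(
                (s, rng.choice("+-"), "certain"))
        return build_agp({c: m for c, m in chroms.items() if m}, [],
                         lengths, gap_length=rng.choice([50, 100]))

    return layout(), layout(), lengths


def brute_force_map(assembly):
    """Chromosome-coordinate -> (scaffold, coordinate) by direct per-base
    enumeration of every component row."""
    table = {}
    for p in assembly.placements():
        for off in range(p.length):
            coord = p.object_beg + off
            if p.orientation == "-":
                table[(p.object, coord)] = (p.component, p.component_end - off)
            else:
                table[(p.object, coord)] = (p.component, p.component_beg + off)
    return table


def simple_gene(gid, seqid, start, end, strand="+"):
    children = [Feature(type="mRNA", start=start, end=end, strand=strand,
                        id=f"{gid}.t", parent=gid),
                Feature(type="exon", start=start, end=end, strand=strand,
                        parent=f"{gid}.t")]
    return GeneModel(id=gid, source="src", seqid=seqid, start=start, end=end,
                     strand=strand, children=children)
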
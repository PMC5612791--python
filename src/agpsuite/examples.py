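"""A worked example: the chr14 pectinesterase locus.

A tandem array of pectinesterase genes where two annotation sources each
fused adjacent genes into a chimera.  Three non-overlapping models from one
source score high on both hit-coverage indicators; the two chimeras score
high HO but low QO (few homologs span the fused query); and one model is
protein-identical to its neighbor-source counterpart but carries shorter
UTRs.  Resolving the group keeps the three clean models and prefers the
longer-UTR copy of the identical protein.
"""
from __future__ import annotations

from .formats import Feature, GeneModel
from .reconcile import (GeneGroup, HOQOScore, SelectionDecision,
                        select_in_group)


def _model(gid: str, source: str, start: int, end: int,
           cds: tuple[int, int]) -> GeneModel:
    children = [
        Feature(type="mRNA", start=start, end=end, strand="+",
                id=f"{gid}.t1", parent=gid),
        Feature(type="CDS", start=cds[0], end=cds[1], strand="+",
                parent=f"{gid}.t1"),
    ]
    return GeneModel(id=gid, source=source, seqid="chr14", start=start,
                     end=end, strand="+", children=children)


def pectinesterase_group() -> tuple[GeneGroup, dict[str, HOQOScore]]:
    """The pectinesterase overlap group with its observed HO/QO scores.

    Members (all on chr14, '+'):

    * three clean Refseq models — LOC100244276 (30/30), LOC104881362
      (30/25), LOC104881361 (24/29);
    * VIT14s0060g01960 (23/30), protein-identical to LOC104881362 but with
      shorter UTRs on both sides;
    * two chimeras spanning two clean models each — VIT14s0060g01950 (2/25)
      and Vitvi14g00154 (4/29).
    """
    shared_cds = (3201, 4799)  # identical predicted protein, 533 aa
    members = [
        _model("LOC100244276", "refseq", 1000, 2800, (1201, 2601)),
        _model("LOC104881362", "refseq", 3000, 5000, shared_cds),
        _model("LOC104881361", "refseq", 5200, 7000, (5401, 6801)),
        _model("VIT14s0060g01960", "cribi", 3100, 4900, shared_cds),
        _model("VIT14s0060g01950", "cribi", 1500, 4500, (1601, 4399)),
        _model("Vitvi14g00154", "vcost", 4000, 6500, (4101, 6398)),
    ]
    group = GeneGroup(members=members, source_order=("cribi", "vcost", "refseq"))
    printed = {
        "LOC100244276": (30, 30),
        "LOC104881362": (30, 25),
        "LOC104881361": (24, 29),
        "VIT14s0060g01960": (23, 30),
        "VIT14s0060g01950": (2, 25),
        "Vitvi14g00154": (4, 29),
    }
    scores = {gid: HOQOScore(gene_id=gid, ho=ho, qo=qo, n_hits=30)
              for gid, (ho, qo) in printed.items()}
    return group, scores


def resolve_pectinesterase() -> SelectionDecision:
    """Run the group-resolution rules on the pectinesterase locus."""
    group, scores = pectinesterase_group()
    return select_in_group(group, scores)
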
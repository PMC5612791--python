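# agpsuite

Toolkit for finishing a draft genome and its annotation when the raw
material is a fixed set of assembled scaffolds plus several partially
redundant evidence layers:

1. **Chromosome anchoring** — order and orient scaffolds into chromosome
   pseudomolecules from multiple parental genetic maps (markers shared
   between scaffold bp positions and map cM positions) confirmed by
   mate-pair junctions between scaffold ends, and emit the result as an
   AGP (Assembly Golden Path) file, including a `chr00` pseudomolecule
   concatenating everything that could not be anchored.
2. **Coordinate liftover** — transpose gene annotations between two
   assembly versions that share the same scaffold set, by decomposing
   chromosome coordinates through the old AGP and re-composing through the
   new one.
3. **Annotation reconciliation** — merge several independent gene
   annotations (e.g. two academic pipelines and RefSeq, plus manually
   curated gene families) into a single non-redundant gene set using
   protein-homology hit-coverage indicators and explicit precedence rules.

It is aimed at genome-project bioinformaticians working on organisms where
chromosome-scale assembly rests on genetic maps rather than long reads —
the situation of most pre-long-read reference genomes, grapevine among
them. A `simulate` module generates complete synthetic input sets with a
known truth, so the whole pipeline is testable without any external data.

## The core rules

**Scaffold retention (multiple-evidence rule).** A scaffold enters a
chromosome only when anchored by at least two genetic maps, or by one map
plus a mate-pair junction to a retained neighbor on the same chromosome
(applied as a fixed-point iteration). Everything else goes to `chr00`.
Maps are the primary ordering signal — scaffolds are sorted by the mean
over maps of their rank-normalized median cM — while junctions confirm
adjacencies, orient gradient-free scaffolds, and clear `uncertain_order`
flags; they never override a consistent multi-map order.

**Mate-pair filtering.** An alignment is used only if its leftmost base is
within 5000 bp of a scaffold end (inclusive), MAPQ ≥ 20, and its mismatch /
gap-open / gap-extension tags satisfy XM ≤ 2, XO ≤ 1, XG ≤ 4. A junction
needs ≥ 2 concordant pairs whose geometry strictly out-votes all discordant
pairs; any conflict flags the junction for review.

**HO/QO scoring.** Each gene model is searched against cross-species
proteins; of the retained hits (e-value < 1e-20, one per subject, 30 best)
the *hit overlap* HO counts alignments covering > 90% of the subject
protein and the *query overlap* QO those covering > 90% of the query.
High HO + high QO: the structure recurs in other species (likely valid).
High HO + low QO: homologs do not span the model — likely a chimera of two
genes. Low HO + high QO: likely truncated. Overlapping models from
different sources are grouped (same-strand span overlap, transitive);
curated models win outright, singletons are kept as-is, one-per-source
groups keep the model maximizing min(HO, QO) (identical-protein duplicates
are first collapsed by the longer-combined-UTR rule, exact ties fall to a
source-priority order), and groups containing split/merged variants are
resolved by enumerating maximal non-overlapping configurations and
maximizing Σ min(HO, QO), favoring splits on ties and flagging those
decisions for manual review.

## Worked example

The package ships the pectinesterase locus worked example — a tandem gene
array where two sources each fused adjacent genes into a chimera and one
model is protein-identical to another but with shorter UTRs:

```python
>>> from agpsuite.examples import resolve_pectinesterase
>>> d = resolve_pectinesterase()
>>> [m.id for m in d.kept]
['LOC100244276', 'LOC104881362', 'LOC104881361']
>>> d.notes
'LOC104881362 kept over identical-protein VIT14s0060g01960 by longer combined UTR'
```

The three clean models (scores 30/30, 30/25, 24/29 out of 30 hits) beat
every configuration containing a chimera (2/25 and 4/29 — high-coverage
subjects but half-covered queries), and the identical-protein tie is
decided by UTR length, not by source priority.

A full synthetic pipeline from the command line:

```
$ agpsuite simulate --seed 1 --outdir fx
$ agpsuite links --sam fx/matepairs.sam --out junctions.tsv
13 junctions from 65 links (discards: {'pass': 182, 'mapq': 13, 'xm': 10,
 'xo': 11, 'xg': 11, 'end_distance': 7, 'unpaired': 52})
$ agpsuite anchor --markers fx/markers.tsv --junctions junctions.tsv \
      --scaffolds fx/scaffolds.fasta --out assembly.agp --report report.tsv
wrote assembly.agp (3 pseudomolecules)
$ agpsuite reconcile --gff cribi=fx/cribi.gff3 --gff vcost=fx/vcost.gff3 \
      --gff refseq=fx/refseq.gff3 --curated fx/curated.gff3 \
      --blast fx/hits.tsv --out merged.gff3 --summary summary.tsv
kept 80 gene models in merged.gff3
$ cat summary.tsv
category    before  after
single      0       76
pair        9       0
triple      55      0
multi       14      2
total       78      78
```

All 13 true scaffold adjacencies are recovered from the mate pairs, every
decoy pair is rejected with its reason tallied, the rebuilt AGP reproduces
the simulated truth, and the merge keeps exactly one copy of each of the
80 true genes (the two groups still `multi` after resolution are the
chimera groups, where both constituent genes were kept and the fused model
rejected).

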
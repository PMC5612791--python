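"""Small bookkeeping summaries: marker-table totals, sequencing arithmetic,
assembly statistics."""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .formats import ChromosomeAssembly, MarkerRecord, ScaffoldPlacement


def marker_table(markers: Iterable[MarkerRecord]) -> pd.DataFrame:
    """Counts of loci per marker category (rows) and map (columns), with a
    Total row — the layout of a per-map marker summary table."""
    counts: Counter = Counter()
    for m in markers:
        for mp in m.map_positions:
            counts[(m.marker_type, mp.map)] += 1
    types = sorted({t for t, _ in counts})
    maps = sorted({g for _, g in counts})
    df = pd.DataFrame(
        [[counts.get((t, g), 0) for g in maps] for t in types],
        index=types, columns=maps)
    df.loc["Total"] = df.sum(axis=0)
    return df


def marker_table_totals(per_category: Mapping[str, Mapping[str, int]]
                        ) -> dict[str, int]:
    """Column totals of a per-map marker-category table.

    ``per_category`` maps category -> {map -> count}; the result is the
    per-map sum over categories.
    """
    totals: Counter = Counter()
    for by_map in per_category.values():
        for map_name, n in by_map.items():
            totals[map_name] += n
    return dict(totals)


def read_count_from_inserts(n_inserts: int, reads_per_insert: int = 2) -> int:
    """Total reads produced by paired-end/mate-pair sequencing of
    ``n_inserts`` inserts (two reads per circularized insert)."""
    if n_inserts < 0 or reads_per_insert < 1:
        raise ValueError("counts must be non-negative / positive")
    return n_inserts * reads_per_insert


@dataclass
class AssemblyStats:
    n_objects: int
    n_scaffolds: int
    component_bp: int
    gap_bp: int
    anchored_bp: int      # component bases outside chr00
    chr00_bp: int
    n_chr00_scaffolds: int
    uncertain_bp: int     # component bases flagged uncertain_order


def assembly_stats(assembly: ChromosomeAssembly) -> AssemblyStats:
    comp = gap = anchored = chr00 = unc = 0
    n_scaf = n_chr00 = 0
    for row in assembly.rows:
        if isinstance(row, ScaffoldPlacement):
            comp += row.length
            n_scaf += 1
            if row.object == "chr00":
                chr00 += row.length
                n_chr00 += 1
            else:
                anchored += row.length
            if row.uncertainty == "uncertain_order":
                unc += row.length
        else:
            gap += row.length
    return AssemblyStats(
        n_objects=len(assembly.objects), n_scaffolds=n_scaf, component_bp=comp,
        gap_bp=gap, anchored_bp=anchored, chr00_bp=chr00,
        n_chr00_scaffolds=n_chr00, uncertain_bp=unc)
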
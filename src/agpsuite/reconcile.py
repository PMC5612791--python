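"""Reconciling several gene annotations into one merged gene set.

Overlapping gene models from the different annotation sources are grouped,
each model is scored against cross-species protein homology with two hit-
coverage indicators, and one model (or a consistent split) is kept per
locus:

* **HO** (hit overlap): among the retained BLAST hits, how many cover more
  than 90% of the *subject* protein.  High HO with low QO suggests a
  chimera — the model is longer than any single homolog.
* **QO** (query overlap): how many hits cover more than 90% of the *query*
  protein.  High QO with low HO suggests a truncated model.

Retained hits are the 30 best (one per subject, e-value < 1e-20).  Where
the indicators tie, a fixed source-priority order decides; manually curated
models always win; groups mixing split and merged predictions are resolved
by enumerating non-overlapping configurations and maximizing total
min(HO, QO), favoring splits (more, shorter models) on ties and flagging
those decisions for review.
"""
from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .formats import BlastHit, Feature, GeneModel, ValidationError

DEFAULT_PRIORITY = ("cribi", "vcost", "refseq")

CAT_SINGLE = "single"
CAT_PAIR = "pair"
CAT_TRIPLE = "triple"
CAT_MULTI = "multi"


@dataclass
class HOQOConfig:
    evalue_max: float = 1e-20
    top_k: int = 30
    cov_threshold: float = 0.9


@dataclass
class HOQOScore:
    gene_id: str
    ho: int
    qo: int
    n_hits: int

    def __post_init__(self):
        if not (0 <= self.ho <= self.n_hits and 0 <= self.qo <= self.n_hits):
            raise ValidationError(
                f"{self.gene_id}: ho/qo ({self.ho}/{self.qo}) exceed n_hits {self.n_hits}")

    @property
    def min_score(self) -> int:
        return min(self.ho, self.qo)


def compute_hoqo(gene_id: str, hits: Iterable[BlastHit],
                 cfg: HOQOConfig = HOQOConfig()) -> HOQOScore:
    """Score one gene model from its protein BLAST hits.

    Hits with e-value >= ``evalue_max`` are dropped; one hit per subject is
    kept (lowest e-value, then highest bitscore); the survivors are sorted
    by (e-value, -bitscore, subject) and truncated to ``top_k``.  HO counts
    hits with subject coverage > ``cov_threshold``, QO those with query
    coverage > it (both strict, mirroring "> 90%").
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        if h.q_len == 0 or h.s_len == 0:
            raise ValidationError(f"{gene_id}: hit with zero-length sequence")
        if h.evalue >= cfg.evalue_max:
            continue
        prev = best.get(h.subject_id)
        if prev is None or (h.evalue, -h.bitscore) < (prev.evalue, -prev.bitscore):
            best[h.subject_id] = h
    retained = sorted(best.values(),
                      key=lambda h: (h.evalue, -h.bitscore, h.subject_id))[:cfg.top_k]
    ho = sum(1 for h in retained if h.s_coverage > cfg.cov_threshold)
    qo = sum(1 for h in retained if h.q_coverage > cfg.cov_threshold)
    return HOQOScore(gene_id=gene_id, ho=ho, qo=qo, n_hits=len(retained))


COMPLETE = "complete"
TRUNCATED = "truncated"
CHIMERIC_SUSPECT = "chimeric_suspect"
DUBIOUS = "dubious"


def interpret_hoqo(score: HOQOScore, high_threshold: float = 0.5) -> str:
    """Qualitative reading of an HO/QO pair.

    A count is "high" when it exceeds ``high_threshold`` x n_hits.  Both
    high: the exact structure recurs in other species (complete).  Low HO,
    high QO: part of the real gene is missing (truncated).  High HO, low
    QO: homologs do not span the model — likely a chimera.  Both low (or no
    hits at all): dubious.
    """
    if score.n_hits == 0:
        return DUBIOUS
    cut = high_threshold * score.n_hits
    ho_high, qo_high = score.ho > cut, score.qo > cut
    if ho_high and qo_high:
        return COMPLETE
    if qo_high:
        return TRUNCATED
    if ho_high:
        return CHIMERIC_SUSPECT
    return DUBIOUS


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

@dataclass
class GeneGroup:
    """Overlapping gene models from one or more sources, one locus decision."""

    members: list[GeneModel]
    source_order: tuple[str, ...]

    @property
    def signature(self) -> tuple[int, ...]:
        counts = Counter(m.source for m in self.members)
        return tuple(counts.get(s, 0) for s in self.source_order)

    @property
    def category(self) -> str:
        return classify_signature(self.signature)


def classify_signature(signature: Sequence[int]) -> str:
    total = sum(signature)
    nonzero = sum(1 for c in signature if c > 0)
    if total == 1:
        return CAT_SINGLE
    if any(c > 1 for c in signature):
        return CAT_MULTI
    return CAT_PAIR if nonzero == 2 else CAT_TRIPLE if nonzero == 3 else CAT_MULTI


def _spans_overlap(a: GeneModel, b: GeneModel) -> bool:
    return a.seqid == b.seqid and a.strand == b.strand and \
        a.start <= b.end and b.start <= a.end


def group_models(sources: Mapping[str, Sequence[GeneModel]],
                 source_order: Optional[Sequence[str]] = None) -> list[GeneGroup]:
    """Group models into connected components of same-strand span overlap.

    Overlap of >= 1 bp on the same seqid and strand connects two models;
    groups are the transitive closure.  Uses a coordinate sweep per
    (seqid, strand), so grouping is near-linear in the number of models.
    """
    order = tuple(source_order) if source_order else tuple(sources)
    models: list[GeneModel] = []
    for name, collection in sources.items():
        for m in collection:
            if m.source != name:
                raise ValidationError(
                    f"model {m.id} labelled {m.source!r} under source {name!r}")
            models.append(m)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(models)))
    by_track: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, m in enumerate(models):
        by_track[(m.seqid, m.strand)].append(i)
    for idxs in by_track.values():
        idxs.sort(key=lambda i: models[i].start)
        active: list[int] = []
        for i in idxs:
            active = [j for j in active if models[j].end >= models[i].start]
            for j in active:
                graph.add_edge(i, j)
            active.append(i)

    groups = []
    for comp in nx.connected_components(graph):
        members = sorted((models[i] for i in comp),
                         key=lambda m: (m.start, m.end, m.source, m.id))
        groups.append(GeneGroup(members=members, source_order=order))
    groups.sort(key=lambda g: (g.members[0].seqid, g.members[0].start,
                               g.members[0].id))
    return groups


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

RULE_CURATED = "curated_override"
RULE_SINGLETON = "singleton"
RULE_BEST_SCORE = "best_score"
RULE_PRIORITY = "priority_tie"
RULE_LONGEST_NESTED = "longest_nested"
RULE_CONFIG = "config_score"
RULE_REVIEW = "manual_review"


@dataclass
class SelectionDecision:
    group: GeneGroup
    kept: list[GeneModel]
    rule: str
    notes: str = ""

    def __post_init__(self):
        for a, b in itertools.combinations(self.kept, 2):
            if _spans_overlap(a, b):
                raise ValidationError(
                    f"kept members {a.id} and {b.id} overlap")
        if not self.kept and self.rule != RULE_REVIEW:
            raise ValidationError("empty kept set without manual_review")


def _priority_rank(source: str, priority: Sequence[str]) -> int:
    try:
        return priority.index(source)
    except ValueError:
        raise ValidationError(f"source {source!r} not in priority order {priority}")


def _score_of(m: GeneModel, scores: Mapping[str, HOQOScore]) -> HOQOScore:
    return scores.get(m.id) or HOQOScore(gene_id=m.id, ho=0, qo=0, n_hits=0)


def _collapse_identical_proteins(members: list[GeneModel],
                                 scores: Mapping[str, HOQOScore],
                                 priority: Sequence[str],
                                 notes: list[str]) -> list[GeneModel]:
    """Among members with identical CDS structure (hence identical predicted
    protein) keep the one with the longer combined UTR; ties fall back to
    min(ho, qo) then source priority."""
    by_cds: dict[tuple, list[GeneModel]] = defaultdict(list)
    for m in members:
        key = m.cds_intervals()
        by_cds[(m.seqid, m.strand, key) if key else ("", "", id(m))].append(m)
    out = []
    for dups in by_cds.values():
        if len(dups) == 1:
            out.append(dups[0])
            continue
        best = min(dups, key=lambda m: (
            -m.utr_length(), -_score_of(m, scores).min_score,
            _priority_rank(m.source, priority), m.id))
        losers = ", ".join(m.id for m in dups if m is not best)
        notes.append(
            f"{best.id} kept over identical-protein {losers} by longer combined UTR")
        out.append(best)
    return out


def _reduce_nested_same_source(members: list[GeneModel],
                               notes: list[str]) -> list[GeneModel]:
    """Drop same-source models fully nested inside a larger model from the
    same source (overlap-permitting predictors emit these); the largest is
    kept."""
    drop: set[str] = set()
    for a, b in itertools.combinations(members, 2):
        if a.source != b.source or a.seqid != b.seqid or a.strand != b.strand:
            continue
        inner, outer = (a, b) if (b.start <= a.start and a.end <= b.end) else \
                       (b, a) if (a.start <= b.start and b.end <= a.end) else (None, None)
        if inner is not None and inner.id != outer.id:
            drop.add(inner.id)
            notes.append(f"{inner.id} nested inside {outer.id} ({outer.source}); larger kept")
    return [m for m in members if m.id not in drop]


def select_in_group(group: GeneGroup, scores: Mapping[str, HOQOScore],
                    curated_sources: Sequence[str] = ("curated",),
                    priority: Sequence[str] = DEFAULT_PRIORITY,
                    max_configs: int = 10_000) -> SelectionDecision:
    """Decide which members of one overlap group enter the final gene set.

    Order of rules: (a) manually curated members override everything;
    (b) a singleton is kept as-is, with no discriminative analysis;
    (c) a pair/triple with one model per source keeps the member with the
    best HO/QO — operationalized as max min(ho, qo) — with identical-protein
    duplicates first collapsed by the longer-UTR rule and exact score ties
    broken by source priority; (d) anything with several models from one
    source goes to :func:`resolve_multi`.
    """
    curated = [m for m in group.members if m.source in curated_sources]
    if curated:
        kept = _non_overlapping_subset(curated)
        dropped = len(curated) - len(kept)
        notes = "curated models kept over all automatic annotations"
        if dropped:
            notes += f"; {dropped} overlapping curated member(s) dropped"
        return SelectionDecision(group=group, kept=kept, rule=RULE_CURATED, notes=notes)

    if len(group.members) == 1:
        return SelectionDecision(group=group, kept=list(group.members),
                                 rule=RULE_SINGLETON,
                                 notes="single-annotation locus, kept without analysis")

    if group.category in (CAT_PAIR, CAT_TRIPLE):
        notes: list[str] = []
        members = _collapse_identical_proteins(list(group.members), scores,
                                               priority, notes)
        if len(members) == 1:
            return SelectionDecision(group=group, kept=members, rule=RULE_BEST_SCORE,
                                     notes="; ".join(notes))
        ranked = sorted(members, key=lambda m: (
            -_score_of(m, scores).min_score,
            -(_score_of(m, scores).ho + _score_of(m, scores).qo),
            _priority_rank(m.source, priority), m.id))
        best = ranked[0]
        runner = ranked[1]
        sb, sr = _score_of(best, scores), _score_of(runner, scores)
        if (sb.ho, sb.qo) == (sr.ho, sr.qo):
            rule = RULE_PRIORITY
            notes.append(f"exact HO/QO tie resolved by source priority ({best.source})")
        else:
            rule = RULE_BEST_SCORE
        return SelectionDecision(group=group, kept=[best], rule=rule,
                                 notes="; ".join(notes))

    return resolve_multi(group, scores, priority=priority, max_configs=max_configs)


def _non_overlapping_subset(members: Sequence[GeneModel]) -> list[GeneModel]:
    """Greedy left-to-right pick of mutually non-overlapping members."""
    kept: list[GeneModel] = []
    for m in sorted(members, key=lambda m: (m.seqid, m.start, m.end, m.id)):
        if all(not _spans_overlap(m, k) for k in kept):
            kept.append(m)
    return kept


def _maximal_configurations(members: list[GeneModel],
                            limit: int) -> Optional[list[list[GeneModel]]]:
    """All maximal sets of mutually non-overlapping members, or None when
    enumeration exceeds ``limit`` (maximal independent sets of the overlap
    graph = maximal cliques of its complement)."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(members)))
    for i, j in itertools.combinations(range(len(members)), 2):
        if _spans_overlap(members[i], members[j]):
            graph.add_edge(i, j)
    configs: list[list[GeneModel]] = []
    for clique in nx.find_cliques(nx.complement(graph)):
        configs.append([members[i] for i in sorted(clique)])
        if len(configs) > limit:
            return None
    return configs


def resolve_multi(group: GeneGroup, scores: Mapping[str, HOQOScore],
                  priority: Sequence[str] = DEFAULT_PRIORITY,
                  max_configs: int = 10_000) -> SelectionDecision:
    """Resolve a group holding split and/or merged versions of real genes.

    Candidate configurations are the maximal sets of mutually non-
    overlapping members (after dropping same-source nested duplicates and
    collapsing identical-protein copies); each is scored by the sum of
    min(ho, qo) over its members.  The best total wins; ties go to the
    configuration with *more* (hence shorter, possibly incomplete) members
    — the conservative anti-chimera choice — and are flagged for manual
    review; remaining ties fall to source priority applied memberwise.
    """
    notes: list[str] = []
    members = _reduce_nested_same_source(list(group.members), notes)
    members = _collapse_identical_proteins(members, scores, priority, notes)
    rule = RULE_BEST_SCORE

    configs = _maximal_configurations(members, max_configs)
    if configs is None:
        kept = _greedy_config(members, scores)
        notes.append("configuration space exceeded bound; greedy fallback used")
        return SelectionDecision(group=group, kept=kept, rule=RULE_CONFIG,
                                 notes="; ".join(notes + [RULE_REVIEW]))

    def total(cfg: list[GeneModel]) -> int:
        return sum(_score_of(m, scores).min_score for m in cfg)

    def prio_key(cfg: list[GeneModel]) -> tuple:
        return tuple(sorted(_priority_rank(m.source, priority) for m in cfg)) + \
            tuple(sorted(m.id for m in cfg))

    best_total = max(total(c) for c in configs)
    top = [c for c in configs if total(c) == best_total]
    if len(top) > 1:
        most = max(len(c) for c in top)
        if any(len(c) != most for c in top):
            notes.append("tie on total score broken toward the split "
                         "(shorter members favored); flagged for review")
            rule = RULE_REVIEW
        top = [c for c in top if len(c) == most]
    if len(top) > 1:
        top.sort(key=prio_key)
        notes.append("residual tie resolved by source priority")
        if rule != RULE_REVIEW:
            rule = RULE_PRIORITY
    kept = sorted(top[0], key=lambda m: (m.start, m.end, m.id))
    return SelectionDecision(group=group, kept=kept, rule=rule, notes="; ".join(notes))


def _greedy_config(members: list[GeneModel],
                   scores: Mapping[str, HOQOScore]) -> list[GeneModel]:
    kept: list[GeneModel] = []
    for m in sorted(members, key=lambda m: (-_score_of(m, scores).min_score,
                                            m.start, m.id)):
        if all(not _spans_overlap(m, k) for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: (m.start, m.end, m.id))


# ---------------------------------------------------------------------------
# final merge
# ---------------------------------------------------------------------------

CATEGORIES = (CAT_SINGLE, CAT_PAIR, CAT_TRIPLE, CAT_MULTI)


@dataclass
class MergeSummary:
    """Per-category group counts before and after resolution.

    The total is always the sum of the four categories — the bookkeeping
    identity that also holds for the published correspondence tables.
    """

    before: dict[str, int] = field(default_factory=dict)
    after: dict[str, int] = field(default_factory=dict)

    @property
    def total_before(self) -> int:
        return sum(self.before.get(c, 0) for c in CATEGORIES)

    @property
    def total_after(self) -> int:
        return sum(self.after.get(c, 0) for c in CATEGORIES)


def merge_final(decisions: Iterable[SelectionDecision]
                ) -> tuple[list[GeneModel], MergeSummary, list[str]]:
    """Concatenate kept members, sort, revalidate, and tabulate categories.

    Same-strand overlaps between kept members of *different* groups are
    reported (they indicate inconsistent grouping upstream), not repaired.
    """
    decisions = list(decisions)
    summary = MergeSummary(before={c: 0 for c in CATEGORIES},
                           after={c: 0 for c in CATEGORIES})
    kept_all: list[tuple[GeneModel, int]] = []
    problems: list[str] = []
    for gi, dec in enumerate(decisions):
        summary.before[dec.group.category] += 1
        if dec.kept:
            counts = Counter(m.source for m in dec.kept)
            sig = tuple(counts.get(s, 0) for s in dec.group.source_order)
            summary.after[classify_signature(sig)] += 1
        for m in dec.kept:
            m.validate()
            kept_all.append((m, gi))
    kept_all.sort(key=lambda t: (t[0].seqid, t[0].start, t[0].end, t[0].id))
    for (a, ga), (b, gb) in zip(kept_all, kept_all[1:]):
        if ga != gb and _spans_overlap(a, b):
            problems.append(f"kept models {a.id} (group {ga}) and {b.id} "
                            f"(group {gb}) overlap")
    return [m for m, _ in kept_all], summary, problems


def assign_locus_ids(models: Sequence[GeneModel], prefix: str = "Vitvi",
                     chromosome_codes: Optional[Mapping[str, str]] = None
                     ) -> list[GeneModel]:
    """Allocate standardized locus IDs: prefix + 2-digit chromosome code +
    'g' + 5-digit per-chromosome ordinal (e.g. Vitvi14g00154); mRNA children
    get an additional '_t' + 3-digit ordinal.

    Models must arrive sorted by (seqid, start); chr00 uses code "00" and
    unrecognized seqids need an explicit entry in ``chromosome_codes``.
    """
    codes = dict(chromosome_codes or {})
    counters: Counter = Counter()
    out: list[GeneModel] = []
    ordered = sorted(models, key=lambda m: (m.seqid, m.start, m.end,
                                            0 if m.strand == "+" else 1, m.id))
    for m in ordered:
        code = codes.get(m.seqid)
        if code is None:
            digits = "".join(ch for ch in m.seqid if ch.isdigit())
            if not digits:
                raise ValidationError(
                    f"cannot derive a chromosome code from seqid {m.seqid!r}")
            code = f"{int(digits):02d}"
        counters[code] += 1
        if counters[code] > 99_999:
            raise ValidationError(f"more than 99,999 genes on chromosome {code}")
        gid = f"{prefix}{code}g{counters[code]:05d}"
        t = 0
        children = []
        id_map: dict[str, str] = {}
        for ch in m.children:
            if ch.type == "mRNA":
                t += 1
                new_id = f"{gid}_t{t:03d}"
                if ch.id is not None:
                    id_map[ch.id] = new_id
                children.append(Feature(type=ch.type, start=ch.start, end=ch.end,
                                        strand=ch.strand, id=new_id, parent=gid))
            else:
                parent = id_map.get(ch.parent, gid) if ch.parent else gid
                children.append(Feature(type=ch.type, start=ch.start, end=ch.end,
                                        strand=ch.strand, id=None, parent=parent))
        out.append(GeneModel(id=gid, source=m.source, seqid=m.seqid,
                             start=m.start, end=m.end, strand=m.strand,
                             children=children, protein_length=m.protein_length))
    return out


def reconcile(sources: Mapping[str, Sequence[GeneModel]],
              hits_by_gene: Mapping[str, Sequence[BlastHit]],
              curated_sources: Sequence[str] = ("curated",),
              priority: Sequence[str] = DEFAULT_PRIORITY,
              hoqo_cfg: HOQOConfig = HOQOConfig(),
              ) -> tuple[list[GeneModel], list[SelectionDecision], MergeSummary]:
    """End-to-end reconciliation: group, score, select, merge."""
    groups = group_models(sources)
    scores = {gid: compute_hoqo(gid, hits, hoqo_cfg)
              for gid, hits in hits_by_gene.items()}
    decisions = [select_in_group(g, scores, curated_sources, priority)
                 for g in groups]
    merged, summary, problems = merge_final(decisions)
    if problems:
        raise ValidationError("; ".join(problems))
    return merged, decisions, summary
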
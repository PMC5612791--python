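"""Grouping, HO/QO scoring, selection rules, merge bookkeeping, locus IDs."""
import itertools
import random

import pytest

from agpsuite.examples import pectinesterase_group, resolve_pectinesterase
from agpsuite.formats import BlastHit, Feature, GeneModel, ValidationError
from agpsuite.reconcile import (CAT_MULTI, CAT_PAIR, CAT_SINGLE, CAT_TRIPLE,
                                CHIMERIC_SUSPECT, COMPLETE, DUBIOUS, TRUNCATED,
                                GeneGroup, HOQOConfig, HOQOScore, MergeSummary,
                                assign_locus_ids, classify_signature,
                                compute_hoqo, group_models, interpret_hoqo,
                                merge_final, resolve_multi, select_in_group)


def model(gid, source, start, end, strand="+", seqid="chr1", cds=None,
          children=None):
    kids = children or []
    if cds is not None and not kids:
        kids = [Feature(type="mRNA", start=start, end=end, strand=strand,
                        id=f"{gid}.t", parent=gid),
                Feature(type="CDS", start=cds[0], end=cds[1], strand=strand,
                        parent=f"{gid}.t")]
    return GeneModel(id=gid, source=source, seqid=seqid, start=start, end=end,
                     strand=strand, children=kids)


def score(gid, ho, qo, n=30):
    return HOQOScore(gene_id=gid, ho=ho, qo=qo, n_hits=n)


class TestGrouping:
    def test_transitive_overlap_single_group(self):
        # A and C do not touch, but both touch B: one group of three
        groups = group_models({
            "src1": [model("A", "src1", 100, 500)],
            "src2": [model("B", "src2", 400, 900)],
            "src3": [model("C", "src3", 850, 1200)]})
        assert len(groups) == 1
        assert groups[0].signature == (1, 1, 1)

    def test_opposite_strands_never_group(self):
        groups = group_models({
            "src1": [model("A", "src1", 100, 500, "+")],
            "src2": [model("B", "src2", 100, 500, "-")]})
        assert len(groups) == 2
        assert all(g.category == CAT_SINGLE for g in groups)

    def test_pectinesterase_layout_signature(self):
        group, _ = pectinesterase_group()
        rebuilt = group_models({
            s: [m for m in group.members if m.source == s]
            for s in ("cribi", "vcost", "refseq")})
        assert len(rebuilt) == 1
        assert rebuilt[0].signature == (2, 1, 3)
        assert rebuilt[0].category == CAT_MULTI

    def test_matches_union_find_oracle(self):
        rng = random.Random(9)
        for trial in range(30):
            sources = {"a": [], "b": [], "c": []}
            models = []
            for i in range(rng.randint(0, 40)):
                start = rng.randint(1, 3_000)
                m = model(f"g{i}", rng.choice("abc"), start,
                          start + rng.randint(50, 600), rng.choice("+-"))
                sources[m.source].append(m)
                models.append(m)
            groups = group_models(sources)
            got = {frozenset(m.id for m in g.members) for g in groups}
            assert got == _oracle_components(models), f"trial {trial}"


def _oracle_components(models):
    parent = {m.id: m.id for m in models}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(models, 2):
        if a.seqid == b.seqid and a.strand == b.strand and \
                a.start <= b.end and b.start <= a.end:
            parent[find(a.id)] = find(b.id)
    comps = {}
    for m in models:
        comps.setdefault(find(m.id), set()).add(m.id)
    return {frozenset(v) for v in comps.values()}


def hit(q, s, qa, qb, sa, sb, qlen, slen, evalue=1e-50, bits=300.0):
    return BlastHit(query_id=q, subject_id=s, q_start=qa, q_end=qb,
                    s_start=sa, s_end=sb, q_len=qlen, s_len=slen,
                    evalue=evalue, bitscore=bits)


class TestComputeHoqo:
    def test_no_hits(self):
        sc = compute_hoqo("g", [])
        assert (sc.ho, sc.qo, sc.n_hits) == (0, 0, 0)

    def test_counting_example(self):
        # subject coverages .95/.95/.95/.50/.50 ; query .92/.92/.92/.92/.10
        specs = [(0.95, 0.92), (0.95, 0.92), (0.95, 0.92), (0.50, 0.92),
                 (0.50, 0.10)]
        hits = [hit("g", f"s{i}", 1, max(int(100 * qc), 1), 1,
                    max(int(100 * sc_), 1), 100, 100)
                for i, (sc_, qc) in enumerate(specs)]
        sc = compute_hoqo("g", hits)
        assert (sc.ho, sc.qo, sc.n_hits) == (3, 4, 5)

    def test_top_k_cap(self):
        hits = [hit("g", f"s{i}", 1, 98, 1, 98, 100, 100,
                    evalue=10.0 ** -(30 + i)) for i in range(40)]
        sc = compute_hoqo("g", hits)
        assert (sc.n_hits, sc.ho, sc.qo) == (30, 30, 30)

    def test_evalue_cutoff_is_strict(self):
        keep = hit("g", "a", 1, 98, 1, 98, 100, 100, evalue=9.9e-21)
        drop = hit("g", "b", 1, 98, 1, 98, 100, 100, evalue=1e-20)
        sc = compute_hoqo("g", [keep, drop])
        assert sc.n_hits == 1

    def test_one_hit_per_subject(self):
        hits = [hit("g", "same", 1, 98, 1, 98, 100, 100, evalue=1e-60),
                hit("g", "same", 1, 50, 1, 50, 100, 100, evalue=1e-40)]
        sc = compute_hoqo("g", hits)
        assert sc.n_hits == 1 and sc.ho == 1  # the better HSP is kept

    def test_zero_length_hit_cannot_exist(self):
        with pytest.raises(ValidationError):
            hit("g", "s", 1, 1, 1, 1, 0, 10)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(21)
        cfg = HOQOConfig()
        for trial in range(100):
            hits = []
            for i in range(rng.randint(0, 200)):
                qlen = rng.randint(50, 500)
                slen = rng.randint(50, 500)
                qa = rng.randint(1, qlen)
                qb = rng.randint(qa, qlen)
                sa = rng.randint(1, slen)
                sb = rng.randint(sa, slen)
                hits.append(hit("g", f"s{rng.randint(0, 60)}", qa, qb, sa, sb,
                                qlen, slen,
                                evalue=10.0 ** -rng.uniform(10, 80),
                                bits=round(rng.uniform(50, 900), 1)))
            got = compute_hoqo("g", hits, cfg)
            exp = _oracle_hoqo(hits, cfg)
            assert (got.ho, got.qo, got.n_hits) == exp, f"trial {trial}"


def _oracle_hoqo(hits, cfg):
    """Brute-force filter/sort/count, written independently."""
    ok = [h for h in hits if h.evalue < cfg.evalue_max]
    per_subject = {}
    for h in ok:
        cur = per_subject.get(h.subject_id)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            per_subject[h.subject_id] = h
    pool = sorted(per_subject.values(),
                  key=lambda h: (h.evalue, -h.bitscore, h.subject_id))[:cfg.top_k]
    ho = sum((h.s_end - h.s_start + 1) / h.s_len > cfg.cov_threshold for h in pool)
    qo = sum((h.q_end - h.q_start + 1) / h.q_len > cfg.cov_threshold for h in pool)
    return ho, qo, len(pool)


class TestInterpret:
    @pytest.mark.parametrize("ho,qo,n,label", [
        (30, 30, 30, COMPLETE),
        (28, 5, 30, CHIMERIC_SUSPECT),
        (5, 28, 30, TRUNCATED),
        (5, 5, 30, DUBIOUS),
        (0, 0, 0, DUBIOUS),
        (16, 16, 30, COMPLETE),   # just above half
        (15, 15, 30, DUBIOUS),    # exactly half is not high
    ])
    def test_labels(self, ho, qo, n, label):
        assert interpret_hoqo(score("g", ho, qo, n)) == label


class TestSelection:
    def test_singleton_kept_without_scores(self):
        g = GeneGroup(members=[model("v", "vcost", 1, 100)],
                      source_order=("cribi", "vcost", "refseq"))
        d = select_in_group(g, {})
        assert d.rule == "singleton" and [m.id for m in d.kept] == ["v"]

    def test_curated_overrides_everything(self):
        g = GeneGroup(members=[model("c", "curated", 1, 100, cds=(10, 90)),
                               model("a", "cribi", 1, 100, cds=(10, 90))],
                      source_order=("cribi", "vcost", "refseq"))
        d = select_in_group(g, {"a": score("a", 30, 30)},
                            curated_sources=("curated",))
        assert d.rule == "curated_override" and [m.id for m in d.kept] == ["c"]

    def test_pair_best_min_score_wins(self):
        g = GeneGroup(members=[model("a", "cribi", 1, 100, cds=(10, 90)),
                               model("b", "vcost", 50, 150, cds=(60, 140))],
                      source_order=("cribi", "vcost", "refseq"))
        d = select_in_group(g, {"a": score("a", 20, 25), "b": score("b", 28, 28)})
        assert d.rule == "best_score" and [m.id for m in d.kept] == ["b"]

    def test_exact_tie_falls_to_source_priority(self):
        g = GeneGroup(members=[model("a", "cribi", 1, 100, cds=(10, 90)),
                               model("b", "vcost", 50, 150, cds=(60, 140))],
                      source_order=("cribi", "vcost", "refseq"))
        d = select_in_group(g, {"a": score("a", 20, 20), "b": score("b", 20, 20)})
        assert d.rule == "priority_tie" and [m.id for m in d.kept] == ["a"]

    def test_identical_protein_longer_utr_wins(self):
        # same CDS, different UTR extents; UTR rule beats the raw score
        g = GeneGroup(members=[model("short", "cribi", 40, 110, cds=(50, 100)),
                               model("long", "vcost", 1, 150, cds=(50, 100))],
                      source_order=("cribi", "vcost", "refseq"))
        d = select_in_group(g, {"short": score("short", 23, 30),
                                "long": score("long", 30, 25)})
        assert [m.id for m in d.kept] == ["long"]
        assert "longer combined UTR" in d.notes


class TestResolveMulti:
    def test_pectinesterase_group_keeps_three_refseq(self):
        d = resolve_pectinesterase()
        kept = [m.id for m in d.kept]
        assert kept == ["LOC100244276", "LOC104881362", "LOC104881361"]
        assert all(m.source == "refseq" for m in d.kept)
        assert "LOC104881362 kept over identical-protein VIT14s0060g01960" in d.notes

    def test_nested_same_source_keeps_largest(self):
        g = GeneGroup(members=[model("big", "refseq", 1, 1000, cds=(101, 901 - 2)),
                               model("small", "refseq", 200, 400, cds=(210, 390 - 1))],
                      source_order=("cribi", "vcost", "refseq"))
        d = resolve_multi(g, {"big": score("big", 25, 25),
                              "small": score("small", 28, 28)})
        assert [m.id for m in d.kept] == ["big"]
        assert "nested" in d.notes

    def test_equal_score_tie_prefers_split_with_review_flag(self):
        # a 2-fragment split vs a 1-model merge with equal total min(ho,qo)
        g = GeneGroup(members=[model("merge", "cribi", 1, 1000, cds=(10, 990 - 2)),
                               model("f1", "refseq", 1, 450, cds=(10, 440 - 1)),
                               model("f2", "refseq", 500, 1000, cds=(510, 990))],
                      source_order=("cribi", "vcost", "refseq"))
        d = resolve_multi(g, {"merge": score("merge", 20, 20),
                              "f1": score("f1", 10, 12), "f2": score("f2", 12, 10)})
        assert sorted(m.id for m in d.kept) == ["f1", "f2"]
        assert d.rule == "manual_review"

    def test_matches_exhaustive_configuration_oracle(self):
        rng = random.Random(17)
        for trial in range(30):
            members, scores = [], {}
            for i in range(rng.randint(2, 8)):
                start = rng.randint(1, 600)
                m = model(f"g{i}", rng.choice(["cribi", "vcost", "refseq"]),
                          start, start + rng.randint(50, 400),
                          cds=None)
                members.append(m)
                scores[m.id] = score(m.id, rng.randint(0, 30), rng.randint(0, 30))
            g = GeneGroup(members=members,
                          source_order=("cribi", "vcost", "refseq"))
            d = resolve_multi(g, scores)
            best = _oracle_best_total(members, scores)
            got_total = sum(scores[m.id].min_score for m in d.kept)
            assert got_total == best, f"trial {trial}"
            # the kept set is mutually non-overlapping (SelectionDecision
            # validates that on construction)

    def test_member_permutation_invariance(self):
        group, scores = pectinesterase_group()
        baseline = [m.id for m in resolve_multi(group, scores).kept]
        rng = random.Random(2)
        for _ in range(5):
            members = list(group.members)
            rng.shuffle(members)
            g = GeneGroup(members=members, source_order=group.source_order)
            assert [m.id for m in resolve_multi(g, scores).kept] == baseline


def _overlap(a, b):
    return a.seqid == b.seqid and a.strand == b.strand and \
        a.start <= b.end and b.start <= a.end


def _oracle_best_total(members, scores):
    """Exhaustive subset scan for the best non-overlapping total, after the
    stated pre-reduction (same-source nested duplicates keep the largest)."""
    nested = set()
    for a, b in itertools.combinations(members, 2):
        if a.source == b.source and a.strand == b.strand and a.seqid == b.seqid:
            if b.start <= a.start and a.end <= b.end and a.id != b.id:
                nested.add(a.id)
            elif a.start <= b.start and b.end <= a.end and a.id != b.id:
                nested.add(b.id)
    pool = [m for m in members if m.id not in nested]
    best = 0
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            if any(_overlap(a, b) for a, b in itertools.combinations(combo, 2)):
                continue
            best = max(best, sum(scores[m.id].min_score for m in combo))
    return best


class TestMergeAndIds:
    def test_summary_counts_and_total(self):
        order = ("cribi", "vcost", "refseq")
        groups = [
            GeneGroup([model("s1", "cribi", 1, 100)], order),
            GeneGroup([model("s2", "vcost", 200, 300)], order),
            GeneGroup([model("s3", "refseq", 400, 500)], order),
            GeneGroup([model("p1", "cribi", 600, 700),
                       model("p2", "vcost", 650, 750)], order),
            GeneGroup([model("t1", "cribi", 800, 900),
                       model("t2", "vcost", 820, 920),
                       model("t3", "refseq", 840, 940)], order),
        ]
        decisions = [select_in_group(g, {}) for g in groups]
        merged, summary, problems = merge_final(decisions)
        assert problems == []
        assert summary.before == {CAT_SINGLE: 3, CAT_PAIR: 1, CAT_TRIPLE: 1,
                                  CAT_MULTI: 0}
        assert summary.total_before == 5

    def test_empty_input(self):
        merged, summary, problems = merge_final([])
        assert merged == [] and summary.total_before == 0 and problems == []

    def test_total_equals_category_sum_always(self, default_fixture):
        from agpsuite.reconcile import reconcile
        fix = default_fixture
        sources = dict(fix.annotations.sources)
        merged, decisions, summary = reconcile(sources, fix.annotations.hits_by_gene())
        assert summary.total_before == sum(summary.before.values())
        assert summary.total_after == sum(summary.after.values())

    def test_locus_id_shape(self):
        m = model("x", "cribi", 10, 100, seqid="chr14",
                  children=[Feature(type="mRNA", start=10, end=100, strand="+",
                                    id="x.t", parent="x")])
        (out,) = assign_locus_ids([m] , prefix="Vitvi")
        assert out.id == "Vitvi14g00001"
        assert out.children[0].id == "Vitvi14g00001_t001"
        import re
        assert re.fullmatch(r"Vitvi\d{2}g\d{5}", "Vitvi14g00154")
        assert re.fullmatch(r"Vitvi\d{2}g\d{5}", out.id)

    def test_ordinals_per_chromosome_and_chr00(self):
        ms = [model("a", "cribi", 10, 100, seqid="chr01"),
              model("b", "cribi", 200, 300, seqid="chr01"),
              model("c", "cribi", 10, 100, seqid="chr00")]
        out = assign_locus_ids(ms)
        assert [m.id for m in out] == ["Vitvi00g00001", "Vitvi01g00001",
                                       "Vitvi01g00002"]

    def test_same_start_tie_broken_deterministically(self):
        ms = [model("minus", "cribi", 10, 100, "-", seqid="chr02"),
              model("plus", "cribi", 10, 100, "+", seqid="chr02")]
        out = assign_locus_ids(ms)
        assert len({m.id for m in out}) == 2
        plus = next(m for m in out if m.strand == "+")
        assert plus.id == "Vitvi02g00001"


class TestMergeSummaryContract:
    def test_total_is_sum_of_categories(self):
        s = MergeSummary(before={CAT_SINGLE: 3, CAT_PAIR: 2, CAT_TRIPLE: 1,
                                 CAT_MULTI: 1},
                         after={CAT_SINGLE: 5, CAT_PAIR: 1, CAT_TRIPLE: 1,
                                CAT_MULTI: 0})
        assert s.total_before == 7 and s.total_after == 7


class TestTruthRecovery:
    def test_pipeline_recovers_truth_and_rejects_chimeras(self):
        """On the default synthetic conditions the merge keeps >= 95% of the
        true models and none of the engineered chimeras (whose QO sits below
        half their hit count)."""
        from agpsuite.reconcile import reconcile, compute_hoqo
        from agpsuite.simulate import SimConfig, simulate
        fix = simulate(SimConfig(seed=3))
        sources = dict(fix.annotations.sources)
        sources["curated"] = fix.annotations.curated
        by_gene = fix.annotations.hits_by_gene()
        merged, decisions, summary = reconcile(sources, by_gene)
        true_keys = {(g.seqid, g.strand, g.cds_intervals())
                     for g in fix.truth.genes}
        kept_keys = {(m.seqid, m.strand, m.cds_intervals()) for m in merged}
        recovered = len(true_keys & kept_keys) / len(true_keys)
        assert recovered >= 0.95
        chimera_ids = set(fix.truth.error_labels["vcost"]["chimera"])
        for cid in chimera_ids:
            sc = compute_hoqo(cid, by_gene[cid])
            assert sc.qo < sc.n_hits / 2  # engineered to look chimeric
        assert not chimera_ids & {m.id for m in merged}
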
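"""Annotation bars, coverage windows, pairing plans, figure tables."""

import numpy as np
import pytest

from phasepan.classify import classify_groups
from phasepan.homology import HomologyGroup
from phasepan.model import (
    GeneModel,
    GenomeRecord,
    HaplotypeID,
    PangenomeError,
    PangenomeStore,
    RepeatAnnotation,
    SequenceRecord,
    Transcript,
)
from phasepan.tracks import (
    GREY,
    coverage_track,
    dotplot_plan_and_filter,
    gene_presence_track,
    pairing_plan,
    parse_variant_records,
    stacked_chromosome_figure,
)
from oracles import coverage_oracle


def _store_with_chromosome_copies():
    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 2)
    for c in (2, 3):
        for p in "AB":
            name = f"chr{c}{p}"
            store.sequences[(1, name)] = SequenceRecord(1, name, "ACGT" * 300, HaplotypeID(c, p))

    def add(gene_id, seq_name, start):
        gm = GeneModel(gene_id=gene_id, genome_id=1, sequence_name=seq_name, start=start, end=start + 9, strand="+")
        gm.transcripts = [Transcript(gene_id + ".m", [(start, start + 9)], "MA")]
        store.genes[gene_id] = gm

    # group X: copies only on 2A and 2B (same chromosome, different haplotype)
    add("x_2a", "chr2A", 0)
    add("x_2b", "chr2B", 0)
    # group Y: copy on 2A and on 3A (different chromosome number)
    add("y_2a", "chr2A", 50)
    add("y_3a", "chr3A", 50)
    groups = [
        HomologyGroup("HGX", frozenset({"x_2a", "x_2b"})),
        HomologyGroup("HGY", frozenset({"y_2a", "y_3a"})),
    ]
    return store, groups


def test_other_chromosome_grey_rule():
    store, groups = _store_with_chromosome_copies()
    classes = classify_groups(store, groups)
    track = gene_presence_track(store, (1, "chr2A"), "other_chromosome_copy", classes)
    by_gene = {iv[2]: iv for iv in []}
    vals = {store.genes_on(1, "chr2A")[i].gene_id: track.intervals[i] for i in range(2)}
    # same chromosome, different haplotype: NOT grey
    assert vals["x_2a"][2] == "unique"
    # copy on another chromosome number: grey
    assert vals["y_2a"][2] == "grey"
    assert vals["y_2a"][3] == GREY


def test_class_and_subgenome_tracks(small_store, small_groups):
    classes = classify_groups(small_store, small_groups)
    seq = (1, "chr1A")
    t1 = gene_presence_track(small_store, seq, "pangenome_class", classes)
    genes = [g for g in small_store.genes_on(*seq) if any(g.gene_id in c.group.members for c in classes)]
    assert len(t1.intervals) == len(genes)
    # full track equals per-gene reclassification
    idx = {m: c for c in classes for m in c.group.members}
    for g, iv in zip(genes, t1.intervals):
        assert iv[2] == idx[g.gene_id].intergenomic
        assert (iv[0], iv[1]) == (g.start, g.end)
    t2 = gene_presence_track(small_store, seq, "subgenome_count", classes)
    for g, iv in zip(genes, t2.intervals):
        assert iv[2] == idx[g.gene_id].subgenome_counts.get(1, 0)
    with pytest.raises(PangenomeError):
        gene_presence_track(small_store, seq, "pangenome_class", [])


def test_coverage_union_and_oracle():
    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 1)
    L = 2_500_000
    store.sequences[(1, "chr")] = SequenceRecord(1, "chr", "A" * L, HaplotypeID(1, "A"))
    intervals = [(0, 600_000), (400_000, 1_000_000), (1_200_000, 1_250_000)]
    for i, (s, e) in enumerate(intervals):
        store.repeats.append(RepeatAnnotation(1, "chr", s, e, "LTR"))
    track = coverage_track(store, (1, "chr"), annotation="repeat")
    got = [iv[2] for iv in track.intervals]
    # overlapping annotations count once (union): first window is 100%
    assert got[0] == pytest.approx(100.0)
    assert got == pytest.approx(coverage_oracle(L, intervals, 1_000_000))
    # empty window is 0; last partial window normalized by its own length
    assert got[1] == pytest.approx(5.0)
    assert track.intervals[-1][1] == L


def test_pairing_plan_counts_and_exclusions():
    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 4)
    store.genomes[2] = GenomeRecord(2, "g2", 1)
    for p in "ABCD":
        store.sequences[(1, f"chr1{p}")] = SequenceRecord(1, f"chr1{p}", "ACGT", HaplotypeID(1, p))
    store.sequences[(2, "chr1A")] = SequenceRecord(2, "chr1A", "ACGT", HaplotypeID(1, "A"))
    store.sequences[(2, "scaff")] = SequenceRecord(2, "scaff", "ACGT", HaplotypeID())
    plan = pairing_plan(store)
    h = 5
    assert len(plan.pairs) == h * (h - 1) // 2
    assert all("scaff" not in a and "scaff" not in b for a, b in plan.pairs)
    assert len(set(plan.pairs)) == len(plan.pairs)


def test_variant_quality_boundary(tmp_path):
    path = tmp_path / "calls.txt"
    path.write_text(
        "R\tchr1A\t0\t100\n"
        "V\tchr1A\t10\t11\t1\t9\tA\tC\n"
        "V\tchr1A\t20\t21\t1\t10\tG\tT\n"
        "V\tchr1A\t30\t31\t1\t60\tC\tA\n"
    )
    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 1)
    store.sequences[(1, "chr1A")] = SequenceRecord(1, "chr1A", "ACGT", HaplotypeID(1, "A"))
    plan, variants = dotplot_plan_and_filter(store, [path], min_quality=10)
    assert [v.quality for v in variants] == [10, 60]  # 9 removed, 10 kept
    bad = tmp_path / "bad.txt"
    bad.write_text("V\tchr\toops\n")
    with pytest.raises(PangenomeError, match="line 1"):
        parse_variant_records(bad)


def test_stacked_figure_tables(inversion_store, inversion_groups, tmp_path):
    from phasepan.synteny import build_pair_inputs, detect_collinear_blocks

    classes = classify_groups(inversion_store, inversion_groups)
    _, _, matches = build_pair_inputs(inversion_store, (1, "chr1A"), (1, "chr1B"), inversion_groups)
    blocks = detect_collinear_blocks(matches, "g1#chr1A", "g1#chr1B")
    prefix = tmp_path / "fig"
    tracks, ribbons = stacked_chromosome_figure(inversion_store, 1, classes, blocks, out_prefix=prefix)
    assert (tmp_path / "fig.png").exists()
    assert (tmp_path / "fig.tracks.tsv").exists()
    # one antiparallel (crossing) ribbon from the planted inversion
    orientations = [r[6] for r in ribbons]
    assert "antiparallel" in orientations
    # ribbon endpoints lie within the sequences
    for row_a, row_b, a0, a1, b0, b1, _ in ribbons:
        assert 0 <= a0 < a1 <= inversion_store.sequence_by_label(row_a).length
        assert 0 <= b0 < b1 <= inversion_store.sequence_by_label(row_b).length
    # tables regenerate identically
    tracks2, ribbons2 = stacked_chromosome_figure(inversion_store, 1, classes, blocks, out_prefix=None)
    assert ribbons == ribbons2
    assert {k: t.intervals for k, t in tracks.items()} == {k: t.intervals for k, t in tracks2.items()}
    with pytest.raises(PangenomeError):
        stacked_chromosome_figure(inversion_store, 42, classes, [])
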
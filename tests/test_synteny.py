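"""Collinear blocks, MCScanX dialect round trips, gene retention windows."""

import numpy as np
import pytest

from phasepan.homology import HomologyGroup
from phasepan.model import PangenomeError
from phasepan.synteny import (
    GenePairMatch,
    add_synteny,
    build_pair_inputs,
    detect_collinear_blocks,
    gene_retention,
    parse_collinearity,
    write_collinearity,
)
from oracles import window_retention_oracle


def _diag_matches(n, anti=False):
    return [
        GenePairMatch(i, (n - 1 - i) if anti else i, f"q{i}", f"t{i}", f"G{i}")
        for i in range(n)
    ]


def test_perfect_collinearity_single_block():
    blocks = detect_collinear_blocks(_diag_matches(40))
    assert len(blocks) == 1
    assert blocks[0].orientation == "parallel"
    assert blocks[0].n_pairs == 40


def test_below_min_block_size_not_emitted():
    assert detect_collinear_blocks(_diag_matches(4)) == []
    assert detect_collinear_blocks([]) == []


def test_antiparallel_layout_detected():
    blocks = detect_collinear_blocks(_diag_matches(10, anti=True))
    assert len(blocks) == 1
    assert blocks[0].orientation == "antiparallel"


def test_detection_symmetric_up_to_orientation():
    rng = np.random.default_rng(2)
    matches = _diag_matches(30)
    fwd = detect_collinear_blocks(matches)
    swapped = [
        GenePairMatch(m.target_rank, m.query_rank, m.target_gene, m.query_gene, m.group_id)
        for m in matches
    ]
    rev = detect_collinear_blocks(sorted(swapped, key=lambda m: (m.query_rank, m.target_rank)))
    assert [(b.orientation, b.n_pairs) for b in fwd] == [(b.orientation, b.n_pairs) for b in rev]


def test_planted_inversion_recovered(inversion_sim, inversion_store, inversion_groups):
    (g, c, phase, start, size) = inversion_sim.truth.inversions[0]
    _, _, matches = build_pair_inputs(inversion_store, (1, "chr1A"), (1, f"chr1{phase}"), inversion_groups)
    blocks = detect_collinear_blocks(matches, "g1#chr1A", f"g1#chr1{phase}")
    anti = [b for b in blocks if b.orientation == "antiparallel"]
    assert len(anti) == 1
    got_start = anti[0].pairs[0].query_rank
    got_end = anti[0].pairs[-1].query_rank
    assert abs(got_start - start) <= 2
    assert abs(got_end - (start + size - 1)) <= 2
    assert all(b.n_pairs >= 5 for b in blocks)


def test_build_pair_inputs_matches_brute_force(inversion_store, inversion_groups):
    qa, qb = (1, "chr1A"), (1, "chr1B")
    q_genes, t_genes, matches = build_pair_inputs(inversion_store, qa, qb, inversion_groups)
    group_of = {m: g.group_id for g in inversion_groups for m in g.members}
    expect = set()
    for i, qg in enumerate(q_genes):
        for j, tg in enumerate(t_genes):
            if group_of.get(qg.gene_id) and group_of.get(qg.gene_id) == group_of.get(tg.gene_id):
                expect.add((i, j))
    assert {(m.query_rank, m.target_rank) for m in matches} == expect


def test_collinearity_round_trip(tmp_path):
    blocks = detect_collinear_blocks(_diag_matches(12) + _diag_matches(8, anti=True)[:0])
    path = tmp_path / "x.collinearity"
    write_collinearity(blocks, path)
    back = parse_collinearity(path)
    assert len(back) == len(blocks)
    for a, b in zip(blocks, back):
        assert a.orientation == b.orientation
        assert [(p.query_gene, p.target_gene) for p in a.pairs] == [
            (p.query_gene, p.target_gene) for p in b.pairs
        ]


def test_parse_hand_written_collinearity(tmp_path):
    text = """############### Parameters ###############
# MATCH_SCORE: 50
############### Statistics ###############
## Alignment 0: score=250 e_value=0 N=5 s1&s2 plus
0-  0:\tqa\tta\t0
0-  1:\tqb\ttb\t0
0-  2:\tqc\ttc\t0
0-  3:\tqd\ttd\t0
0-  4:\tqe\tte\t0
## Alignment 1: score=300 e_value=0 N=6 s1&s3 minus
1-  0:\tqa\tua\t0
1-  1:\tqb\tub\t0
1-  2:\tqc\tuc\t0
1-  3:\tqd\tud\t0
1-  4:\tqe\tue\t0
1-  5:\tqf\tuf\t0
"""
    path = tmp_path / "hand.collinearity"
    path.write_text(text)
    blocks = parse_collinearity(path)
    assert [b.n_pairs for b in blocks] == [5, 6]
    assert blocks[0].orientation == "parallel"
    assert blocks[1].orientation == "antiparallel"  # minus maps to antiparallel
    bad = tmp_path / "bad.collinearity"
    bad.write_text("## Alignment zero: score=x\n")
    with pytest.raises(PangenomeError, match="line 1"):
        parse_collinearity(bad)


def test_add_synteny_symmetric_and_idempotent(inversion_store, inversion_groups):
    _, _, matches = build_pair_inputs(inversion_store, (1, "chr1A"), (1, "chr1B"), inversion_groups)
    blocks = detect_collinear_blocks(matches, "g1#chr1A", "g1#chr1B")
    n1 = add_synteny(inversion_store, blocks)
    n2 = add_synteny(inversion_store, blocks)  # idempotent
    assert n1 == n2
    for gene, partners in inversion_store.syntenic_partners.items():
        for p in partners:
            assert gene in inversion_store.syntenic_partners[p]


def test_retention_self_and_oracle(inversion_store, inversion_groups):
    q = (1, "chr1A")
    tracks = gene_retention(inversion_store, q, [q], inversion_groups, window=20, step=5)
    assert all(w[2] == 100.0 for w in tracks[0].windows)
    # brute-force recount against the other haplotype
    t = (1, "chr1B")
    track = gene_retention(inversion_store, q, [t], inversion_groups, window=20, step=5)[0]
    group_of = {m: g.group_id for g in inversion_groups for m in g.members}
    t_groups = {group_of[g.gene_id] for g in inversion_store.genes_on(*t) if g.gene_id in group_of}
    flags = [
        g.gene_id in group_of and group_of[g.gene_id] in t_groups
        for g in inversion_store.genes_on(*q)
    ]
    assert [w[2] for w in track.windows] == window_retention_oracle(flags, 20, 5)
    # bp ranges lie within the query
    qlen = inversion_store.sequences[q].length
    for s, e, _ in track.windows:
        assert 0 <= s < e <= qlen


def test_synteny_retention_never_exceeds_homology(inversion_store, inversion_groups):
    _, _, matches = build_pair_inputs(inversion_store, (1, "chr1A"), (1, "chr1B"), inversion_groups)
    blocks = detect_collinear_blocks(matches, "g1#chr1A", "g1#chr1B")
    add_synteny(inversion_store, blocks)
    q, t = (1, "chr1A"), (1, "chr1B")
    hom = gene_retention(inversion_store, q, [t], inversion_groups, mode="homology", window=20, step=5)[0]
    syn = gene_retention(inversion_store, q, [t], inversion_groups, mode="synteny", window=20, step=5)[0]
    for (s1, e1, ph), (s2, e2, ps) in zip(hom.windows, syn.windows):
        assert (s1, e1) == (s2, e2)
        assert ps <= ph


def test_retention_errors(inversion_store, inversion_groups):
    with pytest.raises(PangenomeError, match="smaller"):
        gene_retention(inversion_store, (1, "chr1A"), [(1, "chr1B")], inversion_groups, window=10_000)
    with pytest.raises(PangenomeError, match="mode"):
        gene_retention(inversion_store, (1, "chr1A"), [(1, "chr1B")], inversion_groups, mode="bogus")
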
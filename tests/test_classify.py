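"""Core/accessory/cloud classification, single-copy scopes, allele census."""

from collections import Counter

import pytest

from phasepan.classify import (
    allele_census,
    classify_groups,
    gene_distance_matrix,
    single_copy_groups,
)
from phasepan.homology import HomologyGroup
from phasepan.model import (
    GeneModel,
    GenomeRecord,
    HaplotypeID,
    PangenomeError,
    PangenomeStore,
    SequenceRecord,
    Transcript,
)


def _fixture_store(n_genomes=3, ploidy=4, chromosomes=(1, 2)):
    store = PangenomeStore()
    for g in range(1, n_genomes + 1):
        store.genomes[g] = GenomeRecord(g, f"g{g}", ploidy)
        for c in chromosomes:
            for h in range(ploidy):
                phase = chr(65 + h)
                name = f"chr{c}{phase}"
                store.sequences[(g, name)] = SequenceRecord(g, name, "ACGT" * 500, HaplotypeID(c, phase))
        store.sequences[(g, "scaff0")] = SequenceRecord(g, "scaff0", "ACGT" * 100, HaplotypeID())
    return store


def _add_gene(store, gene_id, genome, seq_name, start=0, cds="ATGGCTTAA"):
    end = start + len(cds)
    gm = GeneModel(gene_id=gene_id, genome_id=genome, sequence_name=seq_name, start=start, end=end, strand="+")
    from phasepan.model import translate_cds

    prot, _ = translate_cds(cds)
    gm.transcripts = [Transcript(gene_id + ".m", [(start, end)], prot)]
    # plant the CDS into the sequence so extraction works
    rec = store.sequences[(genome, seq_name)]
    rec.residues = rec.residues[:start] + cds + rec.residues[end:]
    store.genes[gene_id] = gm
    return gm


def test_classification_definitions_and_counts():
    store = _fixture_store(n_genomes=3, ploidy=4)
    # core group: one member in every genome
    members_core = []
    for g in (1, 2, 3):
        _add_gene(store, f"core_g{g}", g, "chr1A")
        members_core.append(f"core_g{g}")
    # cloud group in genome 2, haplotypes A and C of chromosome 5-like (use 2)
    _add_gene(store, "cloud_a", 2, "chr2A")
    _add_gene(store, "cloud_c", 2, "chr2C")
    # a gene on an unphased scaffold contributes to genome presence only
    _add_gene(store, "unphased_g1", 1, "scaff0")
    groups = [
        HomologyGroup("HG1", frozenset(members_core)),
        HomologyGroup("HG2", frozenset({"cloud_a", "cloud_c"})),
        HomologyGroup("HG3", frozenset({"unphased_g1"})),
    ]
    classes = {c.group.group_id: c for c in classify_groups(store, groups)}
    assert classes["HG1"].intergenomic == "core"
    assert classes["HG2"].intergenomic == "cloud"
    assert classes["HG2"].subgenome_counts == {2: 2}
    assert classes["HG2"].chromosome_haplotype_counts == {(2, 2): 2}
    assert classes["HG3"].intergenomic == "cloud"
    assert classes["HG3"].genome_presence == 1
    assert classes["HG3"].subgenome_counts == {}  # unphased: no subgenome
    # partition property
    tally = Counter(c.intergenomic for c in classify_groups(store, groups))
    assert sum(tally.values()) == len(groups)


def test_classification_matches_planted_truth(small_store, small_groups, small_sim):
    truth = small_sim.truth
    # map each computed group to the planted family of its members
    classes = classify_groups(small_store, small_groups)
    fam_of_gene = {g: fam for fam, genes in truth.families.items() for g in genes}
    agree = total = 0
    for gc in classes:
        fams = {fam_of_gene[m] for m in gc.group.members}
        assert len(fams) == 1  # grouping must not merge or split families
        fam = fams.pop()
        want_cls, want_presence, want_sub = truth.classes[fam]
        total += 1
        if (
            gc.intergenomic == want_cls
            and gc.genome_presence == want_presence
            and gc.subgenome_counts == want_sub
        ):
            agree += 1
    assert total == len(truth.families)
    assert agree == total


def test_single_copy_scopes():
    store = _fixture_store(n_genomes=2, ploidy=2)
    # universal: one copy on every haplotype of both chromosomes
    members = []
    for g in (1, 2):
        for c in (1, 2):
            for p in "AB":
                _add_gene(store, f"u_g{g}c{c}{p}", g, f"chr{c}{p}")
                members.append(f"u_g{g}c{c}{p}")
    g_universal = HomologyGroup("U", frozenset(members))
    # one copy per subgenome exactly (chromosome 1 only)
    members_sub = []
    for g in (1, 2):
        for p in "AB":
            _add_gene(store, f"s_g{g}{p}", g, f"chr1{p}", start=100)
            members_sub.append(f"s_g{g}{p}")
    g_sub = HomologyGroup("S", frozenset(members_sub))
    # duplicated on one haplotype: excluded everywhere
    dup = [
        _add_gene(store, "d1", 1, "chr1A", start=200).gene_id,
        _add_gene(store, "d2", 1, "chr1A", start=300).gene_id,
    ] + [_add_gene(store, f"d_g{g}{p}", g, f"chr1{p}", start=400).gene_id for g in (1, 2) for p in "AB"]
    g_dup = HomologyGroup("D", frozenset(dup))
    groups = [g_universal, g_sub, g_dup]

    assert single_copy_groups(store, groups, "subgenome") == [g_sub]
    chr1 = single_copy_groups(store, groups, "chromosome:1")
    assert {g.group_id for g in chr1} == {"S", "U"}  # U has one copy per chr1 haplotype
    assert single_copy_groups(store, groups, "genome") == []  # all have >1 per genome
    with pytest.raises(PangenomeError):
        single_copy_groups(store, groups, "bogus")


def test_single_copy_planted_duplications(small_store, small_groups):
    # chromosome scope on the simulator: groups with one gene per haplotype
    sc = single_copy_groups(small_store, small_groups, "chromosome:1")
    for grp in sc:
        per_hap = Counter()
        for m in grp.members:
            gene = small_store.gene(m)
            hap = small_store.sequences[gene.sequence_key].haplotype
            if hap.chromosome == 1:
                per_hap[(gene.genome_id, hap.phase)] += 1
        assert set(per_hap.values()) == {1}
        assert len(per_hap) == 4  # 2 genomes x 2 haplotypes


def test_gene_distance_matrix_set_semantics():
    store = _fixture_store(n_genomes=1, ploidy=2, chromosomes=(1,))
    # haplotype A carries groups {1,2,3}, B carries {2,3,4}; A has a tandem
    # duplicate in group 2 which must not change anything
    layout = {"A": [1, 2, 2, 3], "B": [2, 3, 4]}
    groups = {}
    for phase, gids in layout.items():
        for i, gid in enumerate(gids):
            name = f"x{phase}{i}"
            _add_gene(store, name, 1, f"chr1{phase}", start=i * 20)
            groups.setdefault(gid, set()).add(name)
    hgroups = [HomologyGroup(f"HG{k}", frozenset(v)) for k, v in sorted(groups.items())]
    dm = gene_distance_matrix(store, hgroups, unit="sequence")
    a, b = "g1#chr1A", "g1#chr1B"
    assert dm[a, a] == 0.0
    assert dm[a, b] == pytest.approx(0.5)  # 1 - |{2,3}|/|{1,2,3,4}|


def test_allele_census_counts():
    store = _fixture_store(n_genomes=1, ploidy=2, chromosomes=(1,))
    # two identical CDS, one synonymous variant, one nonsynonymous variant
    cds_wt = "ATGGCTGCATAA"
    cds_syn = "ATGGCCGCATAA"  # GCT->GCC: same protein
    cds_non = "ATGACTGCATAA"  # GCT->ACT: different protein
    _add_gene(store, "m1", 1, "chr1A", start=0, cds=cds_wt)
    _add_gene(store, "m2", 1, "chr1B", start=0, cds=cds_wt)
    _add_gene(store, "m3", 1, "chr1A", start=50, cds=cds_syn)
    _add_gene(store, "m4", 1, "chr1B", start=50, cds=cds_non)
    grp = HomologyGroup("HG1", frozenset({"m1", "m2", "m3", "m4"}))
    census = allele_census(store, grp)
    assert census.nucleotide_alleles == 3
    assert census.protein_alleles == 2
    assert census.protein_alleles <= census.nucleotide_alleles <= len(grp.members)
    # occurrence matrix: columns are (genome, phase), rows protein alleles
    assert set(census.occurrence) == {(1, "A"), (1, "B")}
    assert sum(sum(v) for v in census.occurrence.values()) == 4
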
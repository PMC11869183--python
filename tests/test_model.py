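"""Pangenome store: FASTA/GFF3/phasing I/O, gene models, feature extraction."""

import pytest

from phasepan.model import (
    HaplotypeID,
    PangenomeError,
    add_annotations,
    add_phasing,
    build_pangenome,
    extract_feature_sequence,
    load_store,
    save_store,
    select_sequences,
    translate_cds,
)
from conftest import write_fasta


def _two_genome_store(tmp_path):
    f1 = write_fasta(tmp_path / "g1.fa", [("s1", "ACGT" * 30), ("s2", "TTGGCC" * 20), ("s3", "AAAC" * 25)])
    f2 = write_fasta(tmp_path / "g2.fa", [("s1", "ACGT" * 25), ("s2", "GGGT" * 25)])
    return build_pangenome([f1, f2], k=19)


def test_build_counts_and_determinism(tmp_path):
    store = _two_genome_store(tmp_path)
    assert len(store.genomes) == 2
    assert len(store.sequences) == 5
    again = _two_genome_store(tmp_path)
    assert {k: r.residues for k, r in store.sequences.items()} == {
        k: r.residues for k, r in again.sequences.items()
    }


def test_build_rejects_bad_input(tmp_path):
    empty_rec = write_fasta(tmp_path / "bad.fa", [("ok", "ACGT" * 10), ("hollow", "")])
    with pytest.raises(PangenomeError, match="hollow"):
        build_pangenome([empty_rec])
    dup = write_fasta(tmp_path / "dup.fa", [("x", "ACGTACGTACGT"), ("x", "ACGTACGTACGT")])
    with pytest.raises(PangenomeError, match="duplicate"):
        build_pangenome([dup])
    with pytest.raises(PangenomeError, match="k must be odd"):
        build_pangenome([write_fasta(tmp_path / "g.fa", [("a", "ACGT" * 10)])], k=20)


GFF_HEADER = "##gff-version 3\n"


def _write_gff(path, rows):
    with open(path, "w") as fh:
        fh.write(GFF_HEADER)
        fh.writelines(rows)
    return path


def test_annotation_translation_and_strands(tmp_path):
    # forward gene CDS ATGGCTTAA -> protein MA; reverse gene whose
    # reverse-complemented CDS is ATGTGA -> protein M
    fwd_cds = "ATGGCTTAA"
    rev_cds_genomic = "TCACAT"  # revcomp = ATGTGA
    seq = "GGGG" + fwd_cds + "TTTT" + rev_cds_genomic + "CCCC"
    fa = write_fasta(tmp_path / "g.fa", [("chr", seq)])
    store = build_pangenome([fa])
    gff = _write_gff(
        tmp_path / "a.gff3",
        [
            "chr\t.\tgene\t5\t13\t.\t+\t.\tID=gF\n",
            "chr\t.\tmRNA\t5\t13\t.\t+\t.\tID=gF.m;Parent=gF\n",
            "chr\t.\tCDS\t5\t13\t.\t+\t0\tID=gF.c;Parent=gF.m\n",
            "chr\t.\tgene\t18\t23\t.\t-\t.\tID=gR\n",
            "chr\t.\tmRNA\t18\t23\t.\t-\t.\tID=gR.m;Parent=gR\n",
            "chr\t.\tCDS\t18\t23\t.\t-\t0\tID=gR.c;Parent=gR.m\n",
        ],
    )
    assert add_annotations(store, gff, 1) == 2
    assert extract_feature_sequence(store, "gF", "protein") == "MA"
    assert extract_feature_sequence(store, "gR", "CDS") == "ATGTGA"
    assert extract_feature_sequence(store, "gR", "protein") == "M"
    # gene extraction on the minus strand is the reverse complement of the span
    span = seq[17:23]
    from phasepan.model import reverse_complement

    assert extract_feature_sequence(store, "gR", "gene") == reverse_complement(span)


def test_longest_transcript_by_cds_length(tmp_path):
    cds_a = "ATG" + "GCT" * 98 + "TAA"  # 300 nt
    cds_b = "ATG" + "GCT" * 48 + "TAA"  # 150 nt
    seq = cds_a + "TTTT"
    fa = write_fasta(tmp_path / "g.fa", [("chr", seq)])
    store = build_pangenome([fa])
    gff = _write_gff(
        tmp_path / "a.gff3",
        [
            "chr\t.\tgene\t1\t300\t.\t+\t.\tID=g1\n",
            f"chr\t.\tmRNA\t1\t300\t.\t+\t.\tID=g1.long;Parent=g1\n",
            f"chr\t.\tCDS\t1\t300\t.\t+\t0\tID=c1;Parent=g1.long\n",
            f"chr\t.\tmRNA\t1\t150\t.\t+\t.\tID=g1.short;Parent=g1\n",
            f"chr\t.\tCDS\t1\t150\t.\t+\t0\tID=c2;Parent=g1.short\n",
        ],
    )
    add_annotations(store, gff, 1)
    assert store.gene("g1").longest_transcript.mrna_id == "g1.long"
    assert store.gene("g1").longest_transcript.cds_length == 300


def test_two_exon_splice_matches_manual_oracle(tmp_path):
    exon1, intron, exon2 = "ATGGCA", "GTAAGTACAG", "GGTTAA"
    seq = "AAAA" + exon1 + intron + exon2 + "TTTT"
    fa = write_fasta(tmp_path / "g.fa", [("chr", seq)])
    store = build_pangenome([fa])
    s1 = 5  # 1-based start of exon1
    gff = _write_gff(
        tmp_path / "a.gff3",
        [
            f"chr\t.\tgene\t{s1}\t{s1 + len(exon1) + len(intron) + len(exon2) - 1}\t.\t+\t.\tID=g\n",
            f"chr\t.\tmRNA\t{s1}\t{s1 + 21}\t.\t+\t.\tID=g.m;Parent=g\n",
            f"chr\t.\tCDS\t{s1}\t{s1 + 5}\t.\t+\t0\tID=c;Parent=g.m\n",
            f"chr\t.\tCDS\t{s1 + 16}\t{s1 + 21}\t.\t+\t0\tID=c;Parent=g.m\n",
        ],
    )
    add_annotations(store, gff, 1)
    assert extract_feature_sequence(store, "g", "CDS") == exon1 + exon2
    prot, _ = translate_cds(exon1 + exon2)
    assert extract_feature_sequence(store, "g", "protein") == prot


def test_phasing_rendering_and_subgenomes(tmp_path):
    fa = write_fasta(
        tmp_path / "g1.fa",
        [(f"chr01_hap{p}", "ACGTAGGCTA" * 20) for p in "ABCD"] + [("scaffold_7", "TTTTACGTAC" * 12)],
    )
    store = build_pangenome([fa])
    table = tmp_path / "phasing.tsv"
    with open(table, "w") as fh:
        fh.write("genome\tsequence\tchromosome\tphase\n")
        for p in "ABCD":
            fh.write(f"1\tchr01_hap{p}\t1\t{p}\n")
    assert add_phasing(store, table) == 4
    assert store.sequences[(1, "chr01_hapA")].haplotype.render() == "1A"
    # unlisted sequence stays chromosome 0, no haplotype identifier
    assert store.sequences[(1, "scaffold_7")].haplotype == HaplotypeID()
    assert sorted(store.subgenomes(1)) == ["A", "B", "C", "D"]
    assert store.genomes[1].ploidy == 4
    with open(table, "a") as fh:
        fh.write("1\tnope\t2\tA\n")
    with pytest.raises(PangenomeError, match="nope"):
        add_phasing(store, table)


def test_select_sequences_filters_and_order(small_store):
    all_chr1 = select_sequences(small_store, chromosomes=[1])
    assert len(all_chr1) == 4  # 2 genomes x 2 haplotypes
    assert [r.label for r in all_chr1] == sorted(
        (r.label for r in all_chr1),
    )
    phase_a = select_sequences(small_store, phases=["A"])
    assert all(r.haplotype.phase == "A" for r in phase_a)
    one = select_sequences(small_store, genomes=[2], chromosomes=[2], phases=["B"])
    assert len(one) == 1
    assert select_sequences(small_store, genomes=[99]) == []


def test_select_sequences_mixed_ploidy_panel(tmp_path):
    # 4 tetraploid genomes + 1 haploid genome, 3 chromosomes each:
    # a chromosome filter returns 4+4+4+4+1 = 17 sequences
    paths = []
    for g in range(1, 6):
        phases = "ABCD" if g < 5 else "A"
        recs = [(f"chr{c}{p}", "ACGTAGGCTA" * 30) for c in (1, 2, 3) for p in phases]
        paths.append(write_fasta(tmp_path / f"g{g}.fa", recs))
    store = build_pangenome(paths)
    table = tmp_path / "phasing.tsv"
    with open(table, "w") as fh:
        fh.write("genome\tsequence\tchromosome\tphase\n")
        for g in range(1, 6):
            for c in (1, 2, 3):
                for p in ("ABCD" if g < 5 else "A"):
                    fh.write(f"{g}\tchr{c}{p}\t{c}\t{p}\n")
    add_phasing(store, table)
    assert len(select_sequences(store, chromosomes=[1])) == 17
    assert len(select_sequences(store)) == 51
    # exactly one sequence per (genome, chromosome, phase) in this panel
    assert len(select_sequences(store, genomes=[2], chromosomes=[3], phases=["B"])) == 1


def test_store_round_trip(small_store, tmp_path):
    save_store(small_store, tmp_path / "store")
    back = load_store(tmp_path / "store")
    assert len(back.genomes) == len(small_store.genomes)
    assert set(back.sequences) == set(small_store.sequences)
    assert set(back.genes) == set(small_store.genes)
    for gid in small_store.genes:
        assert (
            back.gene(gid).longest_transcript.protein
            == small_store.gene(gid).longest_transcript.protein
        )
        assert back.gene(gid).strand == small_store.gene(gid).strand
    for key, rec in small_store.sequences.items():
        assert back.sequences[key].haplotype == rec.haplotype
        assert back.sequences[key].residues == rec.residues


def test_protein_extraction_consistency(small_store):
    # translate(CDS extraction) == protein extraction, for every gene
    for gid in sorted(small_store.genes)[:40]:
        cds = extract_feature_sequence(small_store, gid, "CDS")
        prot, _ = translate_cds(cds)
        assert prot == extract_feature_sequence(small_store, gid, "protein")
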
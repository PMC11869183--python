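"""Phasing-aware gene content characterization.

Homology groups are classified intergenomically as core (present in every
genome), accessory (present in some but not all) or cloud (present in exactly
one genome).  With phased assemblies the same groups are also profiled
intragenomically: in how many subgenomes (phase letters) of each genome do
they occur, and on how many haplotypes of each chromosome.  Genes on unphased
(chromosome-0) sequences count toward genome presence but never toward
subgenome or haplotype counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix

from .homology import HomologyGroup
from .model import PangenomeError, PangenomeStore, extract_feature_sequence

logger = logging.getLogger("phasepan")

__all__ = [
    "GroupClass",
    "AlleleCensus",
    "classify_groups",
    "single_copy_groups",
    "gene_distance_matrix",
    "allele_census",
    "write_classification",
]


@dataclass
class GroupClass:
    group: HomologyGroup
    intergenomic: str  # core | accessory | cloud
    genome_presence: int
    # genome_id -> number of distinct subgenomes (phase letters) with >=1 member
    subgenome_counts: dict[int, int] = field(default_factory=dict)
    # (genome_id, chromosome) -> number of distinct haplotypes with >=1 member
    chromosome_haplotype_counts: dict[tuple[int, int], int] = field(default_factory=dict)


@dataclass
class AlleleCensus:
    group: HomologyGroup
    nucleotide_alleles: int
    protein_alleles: int
    # rows: protein allele index (by first occurrence in sorted gene order);
    # columns: (genome_id, phase) subgenomes, plus (genome_id, None) unphased
    occurrence: dict[tuple[int, str | None], list[int]] = field(default_factory=dict)


def classify_groups(store: PangenomeStore, groups: list[HomologyGroup]) -> list[GroupClass]:
    """Classify every group and count presence per genome, subgenome and
    chromosome haplotype."""
    n_genomes = len(store.genomes)
    if n_genomes == 0:
        raise PangenomeError("empty store")
    out = []
    for grp in groups:
        genomes: set[int] = set()
        subg: dict[int, set[str]] = {}
        chrom_h: dict[tuple[int, int], set[str]] = {}
        for gene_id in grp.members:
            gene = store.gene(gene_id)
            genomes.add(gene.genome_id)
            hap = store.sequences[gene.sequence_key].haplotype
            if hap.phased:
                subg.setdefault(gene.genome_id, set()).add(hap.phase)
                chrom_h.setdefault((gene.genome_id, hap.chromosome), set()).add(hap.phase)
        if len(genomes) == n_genomes:
            cls = "core"
        elif len(genomes) == 1:
            cls = "cloud"
        else:
            cls = "accessory"
        out.append(
            GroupClass(
                group=grp,
                intergenomic=cls,
                genome_presence=len(genomes),
                subgenome_counts={g: len(s) for g, s in sorted(subg.items())},
                chromosome_haplotype_counts={k: len(s) for k, s in sorted(chrom_h.items())},
            )
        )
    return out


def single_copy_groups(
    store: PangenomeStore, groups: list[HomologyGroup], scope: str = "subgenome"
) -> list[HomologyGroup]:
    """Groups with exactly one member per unit of the chosen scope.

    ``genome``: one member in every genome.  ``subgenome``: one member in
    every subgenome of every genome (a haploid genome counts as one
    subgenome).  ``chromosome:c``: one member on every haplotype of
    chromosome c; fragmented haplotypes (several sequences sharing a
    haplotype identifier) count as one haplotype.
    """
    _SKIP = object()  # member invisible to the scope (paper restricts first)
    if scope == "genome":
        required = {("genome", gid) for gid in store.genomes}

        def unit_of(gene):
            return ("genome", gene.genome_id)

    elif scope == "subgenome":
        required = set()
        for gid in store.genomes:
            sub = store.subgenomes(gid)
            if sub:
                required |= {(gid, p) for p in sub}
            else:
                required.add((gid, None))  # unphased/haploid genome = one unit

        def unit_of(gene):
            hap = store.sequences[gene.sequence_key].haplotype
            if hap.phased:
                return (gene.genome_id, hap.phase)
            if not store.subgenomes(gene.genome_id):
                return (gene.genome_id, None)
            return _SKIP  # chromosome-0 gene in a phased genome

    elif scope.startswith("chromosome:"):
        c = int(scope.split(":", 1)[1])
        required = set()
        for rec in store.sequences.values():
            if rec.haplotype.chromosome == c:
                required.add((rec.genome_id, rec.haplotype.phase))
        if not required:
            raise PangenomeError(f"no phased sequences on chromosome {c}")

        def unit_of(gene):
            hap = store.sequences[gene.sequence_key].haplotype
            if hap.chromosome == c:
                return (gene.genome_id, hap.phase)
            return _SKIP

    else:
        raise PangenomeError(f"invalid scope {scope!r}")

    out = []
    for grp in groups:
        counts: dict = {}
        ok = True
        for gene_id in grp.members:
            u = unit_of(store.gene(gene_id))
            if u is _SKIP:
                continue
            counts[u] = counts.get(u, 0) + 1
            if counts[u] > 1:
                ok = False
                break
        if ok and set(counts) == required:
            out.append(grp)
    return out


def gene_distance_matrix(
    store: PangenomeStore,
    groups: list[HomologyGroup],
    unit: str = "sequence",
    chromosome: int | None = None,
) -> DistanceMatrix:
    """1 − Jaccard distance between the homology-group sets of units.

    ``unit`` is ``genome`` or ``sequence``.  Only distinct groups count, so
    copy-number variation does not affect the distance.  Units hit by zero
    groups are excluded with a warning.
    """
    if unit not in ("genome", "sequence"):
        raise PangenomeError(f"unit must be genome or sequence, got {unit!r}")
    group_of: dict[str, str] = {}
    for grp in groups:
        for m in grp.members:
            group_of[m] = grp.group_id
    sets: dict[str, set[str]] = {}
    for gene in store.genes.values():
        if gene.gene_id not in group_of:
            continue
        rec = store.sequences[gene.sequence_key]
        if chromosome is not None and rec.haplotype.chromosome != chromosome:
            continue
        key = f"g{gene.genome_id}" if unit == "genome" else rec.label
        sets.setdefault(key, set()).add(group_of[gene.gene_id])
    if unit == "sequence":
        universe = (
            [r.label for r in store.sequences.values() if chromosome is None or r.haplotype.chromosome == chromosome]
        )
    else:
        universe = [f"g{g}" for g in store.genomes]
    for lab in sorted(universe):
        if lab not in sets:
            logger.warning("unit %s has no grouped genes; excluded from gene-distance matrix", lab)
    labels = sorted(sets)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = sets[labels[i]], sets[labels[j]]
        d = 1.0 - (len(a & b) / len(a | b) if a | b else 1.0)
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, labels)


def allele_census(store: PangenomeStore, group: HomologyGroup) -> AlleleCensus:
    """Count distinct alleles within one homology group.

    Every exact CDS string is a nucleotide allele and every exact protein
    string a protein allele — any polymorphism separates alleles.  The
    occurrence matrix counts each protein allele per subgenome (genome +
    phase letter; unphased members fall in a per-genome ``None`` column).
    """
    members = sorted(group.members)
    cds_alleles: dict[str, int] = {}
    prot_alleles: dict[str, int] = {}
    columns: dict[tuple[int, str | None], list[int]] = {}
    rows_order: list[str] = []
    usable = []
    for gene_id in members:
        gene = store.gene(gene_id)
        try:
            cds = extract_feature_sequence(store, gene_id, "CDS")
        except PangenomeError:
            logger.warning("group %s: member %s without CDS excluded", group.group_id, gene_id)
            continue
        if not cds:
            logger.warning("group %s: member %s without CDS excluded", group.group_id, gene_id)
            continue
        usable.append((gene_id, gene, cds, extract_feature_sequence(store, gene_id, "protein")))
    for gene_id, gene, cds, prot in usable:
        if cds not in cds_alleles:
            cds_alleles[cds] = len(cds_alleles)
        if prot not in prot_alleles:
            prot_alleles[prot] = len(prot_alleles)
            rows_order.append(prot)
    n_rows = len(prot_alleles)
    for gene_id, gene, cds, prot in usable:
        hap = store.sequences[gene.sequence_key].haplotype
        col = (gene.genome_id, hap.phase if hap.phased else None)
        if col not in columns:
            columns[col] = [0] * n_rows
        columns[col][prot_alleles[prot]] += 1
    return AlleleCensus(
        group=group,
        nucleotide_alleles=len(cds_alleles),
        protein_alleles=len(prot_alleles),
        occurrence=dict(sorted(columns.items(), key=lambda kv: (kv[0][0], kv[0][1] or ""))),
    )


def write_classification(classes: list[GroupClass], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tclass\tgenome_presence\tsubgenome_counts\tchromosome_haplotype_counts\n")
        for gc in classes:
            sg = ";".join(f"{g}:{c}" for g, c in sorted(gc.subgenome_counts.items()))
            ch = ";".join(f"{g}.{c}:{n}" for (g, c), n in sorted(gc.chromosome_haplotype_counts.items()))
            fh.write(f"{gc.group.group_id}\t{gc.intergenomic}\t{gc.genome_presence}\t{sg}\t{ch}\n")
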
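"""Protein clustering into homology groups and grouping-quality evaluation.

Clustering stringency is controlled by *relaxation modes*: mode m requires a
normalized pairwise similarity of at least 95 − 10·(m−1) percent (mode 1 →
95%, mode 8 → 25%).  Similarity is a global BLOSUM62 alignment score
normalized by the mean of the two self-scores:

    sim(A, B) = 100 · 2·score(A,B) / (score(A,A) + score(B,B))

Proteins (one per gene: the longest transcript) whose similarity meets the
threshold are connected in a graph; Markov clustering (MCL) partitions each
connected component, and isolated proteins become singleton groups.

Grouping quality is scored against single-copy gene families (BUSCO-style:
one expected member per subgenome) with an F1 of per-family precision and
recall, and by the mean Jaccard overlap of the homology-group sets hit by
sibling haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .model import PangenomeError, PangenomeStore

logger = logging.getLogger("phasepan")

__all__ = [
    "RelaxationMode",
    "HomologyGroup",
    "GroupingEvaluation",
    "pairwise_similarity",
    "group_proteins",
    "evaluate_grouping_busco",
    "subgenome_overlap",
    "parse_busco_full_table",
    "write_groups",
    "read_groups",
]


@dataclass(frozen=True)
class RelaxationMode:
    """Clustering stringency level; threshold drops 10 points per mode."""

    mode: int

    def __post_init__(self) -> None:
        if not 1 <= self.mode <= 8:
            raise PangenomeError(f"relaxation mode must be in 1..8, got {self.mode}")

    @property
    def similarity_threshold(self) -> float:
        return 95.0 - 10.0 * (self.mode - 1)


@dataclass
class HomologyGroup:
    group_id: str
    members: frozenset[str]  # gene ids

    def genome_counts(self, store: PangenomeStore) -> dict[int, int]:
        out: dict[int, int] = {}
        for gid in self.members:
            g = store.gene(gid)
            out[g.genome_id] = out.get(g.genome_id, 0) + 1
        return out


@dataclass
class GroupingEvaluation:
    precision: float
    recall: float
    per_family: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


# ---------------------------------------------------------------------------
# similarity

_DEFAULT_MATRIX = "BLOSUM62"


def _aligner(matrix: str = _DEFAULT_MATRIX, gap_open: float = 10.0, gap_extend: float = 1.0):
    al = PairwiseAligner(mode="global", open_gap_score=-gap_open, extend_gap_score=-gap_extend)
    al.substitution_matrix = substitution_matrices.load(matrix)
    return al


def _self_score(al, seq: str) -> float:
    m = al.substitution_matrix
    return float(sum(m[c, c] for c in seq))


def pairwise_similarity(
    protein_a: str,
    protein_b: str,
    matrix: str = _DEFAULT_MATRIX,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Normalized global-alignment similarity in percent, clipped to [0, 100]."""
    if not protein_a or not protein_b:
        raise PangenomeError("pairwise_similarity: empty protein")
    al = _aligner(matrix, gap_open, gap_extend)
    score = al.score(protein_a, protein_b)
    denom = _self_score(al, protein_a) + _self_score(al, protein_b)
    if denom <= 0:
        return 0.0
    return float(np.clip(100.0 * 2.0 * score / denom, 0.0, 100.0))


def _kmer_profile(seq: str, k: int = 6) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


# ---------------------------------------------------------------------------
# MCL


def _mcl(adj: np.ndarray, inflation: float = 2.0, max_iter: int = 200, tol: float = 1e-8) -> list[list[int]]:
    """Markov clustering of a weighted undirected adjacency matrix.

    Expansion = squaring of the column-stochastic matrix; inflation =
    elementwise power + renormalization.  Clusters are connected components
    of the converged nonzero structure, so every node lands in exactly one
    cluster.
    """
    n = adj.shape[0]
    m = adj.astype(float).copy()
    np.fill_diagonal(m, np.maximum(m.diagonal(), m.max(axis=0) if m.max() > 0 else 1.0))
    col = m.sum(axis=0)
    col[col == 0] = 1.0
    m = m / col
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < 1e-12] = 0.0
        col = m.sum(axis=0)
        col[col == 0] = 1.0
        m = m / col
        if np.abs(m - prev).max() < tol:
            break
    link = (m + m.T) > 1e-6
    seen = np.zeros(n, dtype=bool)
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.nonzero(link[v])[0]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        clusters.append(sorted(comp))
    return clusters


def group_proteins(
    store: PangenomeStore,
    mode: RelaxationMode | int = 4,
    inflation: float = 2.0,
    matrix: str = _DEFAULT_MATRIX,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> list[HomologyGroup]:
    """Cluster longest-transcript proteins into homology groups.

    A shared-6-mer prefilter restricts the all-vs-all alignment to plausible
    pairs; edges at or above the mode's similarity threshold feed MCL per
    connected component.  Input order never matters: genes are processed in
    sorted id order and group ids are assigned canonically.
    """
    if isinstance(mode, int):
        mode = RelaxationMode(mode)
    gene_ids = sorted(store.genes)
    if not gene_ids:
        raise PangenomeError("no annotated proteins to cluster")
    proteins = {}
    for gid in gene_ids:
        p = store.gene(gid).longest_transcript.protein
        if p:
            proteins[gid] = p
    ids = sorted(proteins)
    profiles = {g: _kmer_profile(proteins[g]) for g in ids}
    threshold = mode.similarity_threshold

    # candidate pairs via inverted 6-mer index
    index: dict[str, list[str]] = {}
    for g in ids:
        for km in profiles[g]:
            index.setdefault(km, []).append(g)
    candidates: set[tuple[str, str]] = set()
    for members in index.values():
        if len(members) > 1:
            for a, b in combinations(members, 2):
                candidates.add((a, b) if a < b else (b, a))

    idx = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n))
    for a, b in sorted(candidates):
        sim = pairwise_similarity(proteins[a], proteins[b], matrix, gap_open, gap_extend)
        if sim >= threshold:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = sim

    # connected components of the thresholded graph, then MCL per component
    seen = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.nonzero(adj[v])[0]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        comp.sort()
        if len(comp) == 1:
            clusters.append(comp)
        else:
            sub = adj[np.ix_(comp, comp)]
            for cl in _mcl(sub, inflation=inflation):
                clusters.append([comp[i2] for i2 in cl])

    member_sets = sorted((frozenset(ids[i] for i in cl) for cl in clusters), key=lambda s: sorted(s)[0])
    groups = [
        HomologyGroup(group_id=f"HG{i:06d}", members=ms) for i, ms in enumerate(member_sets, start=1)
    ]
    logger.info("mode %d (>=%.0f%%): %d proteins -> %d homology groups", mode.mode, threshold, n, len(groups))
    store.homology_groups = groups
    return groups


# ---------------------------------------------------------------------------
# evaluation


def evaluate_grouping_busco(
    groups: list[HomologyGroup], busco_families: dict[str, list[str]]
) -> GroupingEvaluation:
    """F1 of a grouping against single-copy families.

    Per family, the group containing the plurality of its members is matched;
    recall = matched members / family size, precision = matched members /
    matched-group size.  Precision and recall are averaged over families and
    F1 is computed from the averages.
    """
    if not busco_families:
        raise PangenomeError("no benchmark families supplied")
    group_of: dict[str, HomologyGroup] = {}
    for grp in groups:
        for m in grp.members:
            group_of[m] = grp
    per_family = []
    for fam_id in sorted(busco_families):
        members = busco_families[fam_id]
        if not members:
            raise PangenomeError(f"family {fam_id!r} has no members")
        tally: dict[str, int] = {}
        for m in members:
            if m in group_of:
                g = group_of[m].group_id
                tally[g] = tally.get(g, 0) + 1
        if not tally:
            per_family.append((fam_id, 0.0, 0.0))
            continue
        best = min(tally, key=lambda g: (-tally[g], g))
        matched = tally[best]
        size = len(next(g for g in groups if g.group_id == best).members)
        per_family.append((fam_id, matched / size, matched / len(members)))
    p = sum(x[1] for x in per_family) / len(per_family)
    r = sum(x[2] for x in per_family) / len(per_family)
    return GroupingEvaluation(precision=p, recall=r, per_family=per_family)


def subgenome_overlap(
    store: PangenomeStore, groups: list[HomologyGroup], genome_id: int
) -> float:
    """Mean percentage of homology groups shared between sibling haplotypes.

    For each chromosome of the genome, the Jaccard index of the group sets
    hit by each haplotype's genes is averaged over haplotype pairs, then over
    chromosomes; reported in percent.
    """
    group_of: dict[str, str] = {}
    for grp in groups:
        for m in grp.members:
            group_of[m] = grp.group_id
    by_hap: dict[tuple[int, str], set[str]] = {}
    for gene in store.genes.values():
        if gene.genome_id != genome_id:
            continue
        hap = store.sequences[gene.sequence_key].haplotype
        if not hap.phased or gene.gene_id not in group_of:
            continue
        by_hap.setdefault((hap.chromosome, hap.phase), set()).add(group_of[gene.gene_id])
    chroms = sorted({c for c, _ in by_hap})
    chrom_means = []
    for c in chroms:
        sets = [by_hap[(c, p)] for (c2, p) in sorted(by_hap) if c2 == c]
        if len(sets) < 2:
            continue
        jacc = [
            len(a & b) / len(a | b) if a | b else 1.0 for a, b in combinations(sets, 2)
        ]
        chrom_means.append(sum(jacc) / len(jacc))
    if not chrom_means:
        raise PangenomeError(f"genome {genome_id} has no chromosome with >= 2 phased haplotypes")
    return 100.0 * sum(chrom_means) / len(chrom_means)


# ---------------------------------------------------------------------------
# I/O


def parse_busco_full_table(path) -> dict[str, list[str]]:
    """Read a BUSCO full-table TSV into family -> gene-id lists.

    Rows with status Complete or Duplicated contribute their sequence/gene
    column; Missing/Fragmented rows are skipped.
    """
    fams: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            busco_id, status, seq = parts[0], parts[1], parts[2]
            if status in ("Complete", "Duplicated"):
                fams.setdefault(busco_id, []).append(seq)
    return fams


def write_groups(groups: list[HomologyGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgene_id\n")
        for grp in groups:
            for m in sorted(grp.members):
                fh.write(f"{grp.group_id}\t{m}\n")


def read_groups(path) -> list[HomologyGroup]:
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_id"):
            raise PangenomeError(f"{path}: not a groups table")
        for line in fh:
            if not line.strip():
                continue
            gid, gene = line.rstrip("\n").split("\t")
            members.setdefault(gid, set()).add(gene)
    return [HomologyGroup(gid, frozenset(ms)) for gid, ms in sorted(members.items())]
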
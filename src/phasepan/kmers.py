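"""Per-sequence canonical k-mer sets, Mash distances and clade validation.

Distances are computed between individual sequences, not pooled genomes, so
that each haplotype-resolved chromosome copy is a taxon of its own.  The
distance is the Mash formula applied to the exact Jaccard index of canonical
k-mer sets:

    J = |A ∩ B| / |A ∪ B|,    D = -(1/k) * ln(2J / (1 + J))

with D capped at 1.0 when J = 0.  Full k-mer sets are used rather than
MinHash sketches: at the scale this package targets, exact sets are feasible
and remove sketch noise from downstream trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from skbio import DistanceMatrix, TreeNode

from .model import PangenomeError, PangenomeStore, SequenceRecord, reverse_complement

__all__ = [
    "KmerSet",
    "canonical_kmers",
    "jaccard",
    "mash_distance",
    "kmer_distance_matrix",
    "validate_chromosome_clades",
    "CladeConflict",
]

_VALID = frozenset("ACGT")


@dataclass
class KmerSet:
    label: str
    k: int
    members: frozenset[str]


def canonical_kmers(sequence: str, k: int, label: str = "") -> KmerSet:
    """Distinct canonical k-mers (lexicographic min of k-mer and its
    reverse complement); windows containing non-ACGT letters are skipped."""
    seq = sequence.upper()
    members: set[str] = set()
    # track distance to the most recent invalid letter to skip tainted windows
    since_bad = 0  # valid letters seen since last non-ACGT (saturates at k)
    for i in range(len(seq)):
        if seq[i] not in _VALID:
            since_bad = 0
            continue
        since_bad = min(since_bad + 1, k)
        if since_bad >= k:
            kmer = seq[i - k + 1 : i + 1]
            rc = reverse_complement(kmer)
            members.add(kmer if kmer <= rc else rc)
    return KmerSet(label=label, k=k, members=frozenset(members))


def jaccard(a: KmerSet, b: KmerSet) -> float:
    if a.k != b.k:
        raise PangenomeError(f"k mismatch: {a.k} vs {b.k}")
    if not a.members and not b.members:
        raise PangenomeError("Jaccard undefined: both k-mer sets empty")
    inter = len(a.members & b.members)
    union = len(a.members | b.members)
    return inter / union


def mash_distance(a: KmerSet, b: KmerSet) -> float:
    """Mash distance from the exact Jaccard of two same-k k-mer sets."""
    j = jaccard(a, b)
    if j == 0.0:
        return 1.0
    d = -(1.0 / a.k) * math.log(2.0 * j / (1.0 + j))
    return min(max(d, 0.0), 1.0)


def kmer_distance_matrix(
    store: PangenomeStore,
    sequences: list[SequenceRecord] | None = None,
    min_genes: int = 100,
) -> DistanceMatrix:
    """Pairwise Mash distance matrix over sequences with >= ``min_genes``
    annotated genes.

    Fewer than 3 surviving sequences cannot support a tree downstream and is
    an error.  Labels are store-wide sequence labels (``g1#chr1A``).
    """
    if sequences is None:
        sequences = sorted(
            store.sequences.values(),
            key=lambda r: (r.genome_id, r.haplotype.chromosome, r.haplotype.phase or "", r.name),
        )
    survivors = []
    for rec in sequences:
        n_genes = sum(
            1
            for g in store.genes.values()
            if g.genome_id == rec.genome_id and g.sequence_name == rec.name
        )
        if n_genes >= min_genes:
            survivors.append(rec)
    if len(survivors) < 3:
        raise PangenomeError(
            f"only {len(survivors)} sequences pass the min_genes={min_genes} filter; "
            "at least 3 are needed for a tree"
        )
    sets = [canonical_kmers(rec.residues, store.k, rec.label) for rec in survivors]
    n = len(sets)
    import numpy as np

    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = mash_distance(sets[i], sets[j])
    return DistanceMatrix(mat, [s.label for s in sets])


def write_phylip_matrix(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance format (full matrix, name width 50)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for lab in dm.ids:
            row = " ".join(f"{float(dm[lab, o]):.9f}" for o in dm.ids)
            fh.write(f"{str(lab)[:50].ljust(50)}{row}\n")


def read_phylip_matrix(path) -> DistanceMatrix:
    import numpy as np

    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            labels.append(line[:50].strip())
            rows.append([float(x) for x in line[50:].split()])
    if len(labels) != n:
        raise PangenomeError(f"malformed PHYLIP matrix {path}")
    return DistanceMatrix(np.asarray(rows), labels)


@dataclass
class CladeConflict:
    chromosome: int
    leaves: frozenset[str]
    offending_clade: frozenset[str]


def validate_chromosome_clades(
    tree: TreeNode, chromosome_of: dict[str, int]
) -> list[CladeConflict]:
    """Check, per chromosome number, that its leaves form a clade.

    The tree is midpoint-rooted first (an unrooted tree has no clades).
    Chromosome-0 leaves are ignored.  For each failing chromosome the
    smallest clade containing all its leaves is reported, so the offending
    extra taxa are visible.
    """
    from .phylo import midpoint_root

    leaves = list(tree.tips())
    for leaf in leaves:
        if leaf.name not in chromosome_of:
            raise PangenomeError(f"leaf {leaf.name!r} has no chromosome label")
    rooted = midpoint_root(tree)
    by_chrom: dict[int, set[str]] = {}
    for leaf in rooted.tips():
        c = chromosome_of[leaf.name]
        if c != 0:
            by_chrom.setdefault(c, set()).add(leaf.name)
    conflicts = []
    for c in sorted(by_chrom):
        want = by_chrom[c]
        if len(want) == 1:
            continue
        mrca = rooted.lca([n for n in rooted.tips() if n.name in want])
        got = {t.name for t in mrca.tips() if chromosome_of[t.name] != 0}
        if got != want:
            conflicts.append(
                CladeConflict(chromosome=c, leaves=frozenset(want), offending_clade=frozenset(got))
            )
    return conflicts
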
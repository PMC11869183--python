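"""Distance trees, two-round trimmed alignments and core-SNP matrices.

Neighbor joining is implemented classically (Saitou–Nei agglomeration) with a
deterministic tie-break — among equal Q values the lexicographically smallest
label pair is joined — so trees are reproducible across runs and platforms.
Midpoint rooting and Newick serialization delegate to scikit-bio.

Multiple alignment follows a two-round scheme: proteins are aligned, the
longest run of leading and trailing gap columns across rows defines terminal
trim windows, every member loses the residues its row spans inside those
windows (nucleotides trimmed in triples), and the trimmed proteins are
re-aligned.  The aligner is pluggable: an external ``mafft`` adapter when the
binary is present, otherwise a built-in center-star aligner so the whole
pipeline runs with no external dependencies.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .model import PangenomeError

logger = logging.getLogger("phasepan")

__all__ = [
    "Msa",
    "SnpMatrix",
    "neighbor_joining",
    "midpoint_root",
    "center_star_align",
    "mafft_align",
    "default_aligner",
    "two_round_align",
    "parsimony_informative_columns",
    "core_snp_matrix",
    "write_phylip",
    "write_fasta_alignment",
    "read_phylip",
    "run_external_tree",
    "write_gene_trees",
]


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion are broken by the smallest (sorted) label pair;
    negative branch lengths are clamped to zero with a log entry.  The result
    is the conventional unrooted tree with a trifurcating root node.
    """
    labels = list(matrix.ids)
    n = len(labels)
    if n < 3:
        raise PangenomeError("neighbor joining needs at least 3 taxa")
    d = {a: {b: float(matrix[a, b]) for b in labels} for a in labels}
    nodes: dict[str, TreeNode] = {a: TreeNode(name=a) for a in labels}
    active = sorted(labels)
    clamped = False

    def _new_label() -> str:
        _new_label.i += 1
        return f"\x00internal{_new_label.i}"

    _new_label.i = 0

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for ia in range(m):
            for ib in range(ia + 1, m):
                a, b = active[ia], active[ib]
                q = (m - 2) * d[a][b] - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and pair < best_pair):
                    best, best_pair = q, pair
        a, b = best_pair
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[a][b] - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        u = _new_label()
        nodes[u] = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length, nodes[b].length = la, lb
        d[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[u][c] = d[c][u] = max(duc, 0.0)
        d[u][u] = 0.0
        active = sorted(x for x in active if x not in (a, b)) + [u]
        active.sort()

    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    lengths = [la, lb, lc]
    if any(x < 0 for x in lengths):
        clamped = True
        lengths = [max(x, 0.0) for x in lengths]
    for node, ln in zip((a, b, c), lengths):
        nodes[node].length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if clamped:
        logger.warning("neighbor joining: negative branch length(s) clamped to 0")
    for node in root.traverse():
        if node.name and node.name.startswith("\x00internal"):
            node.name = None
    return root


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    A tree whose branch lengths are all zero/absent is rooted at the first
    internal node with a warning.
    """
    t = tree.copy()
    total = sum((n.length or 0.0) for n in t.traverse() if n is not t)
    if total == 0.0:
        logger.warning("midpoint rooting: tree has zero total length; rooting at first internal node")
        return t
    return t.root_at_midpoint()


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass
class Msa:
    """A rectangular alignment: parallel label and aligned-row lists."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise PangenomeError("Msa: names and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise PangenomeError("Msa: rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def ungapped(self, name: str) -> str:
        return self.row(name).replace("-", "")


def _protein_aligner() -> PairwiseAligner:
    al = PairwiseAligner(mode="global", open_gap_score=-10.0, extend_gap_score=-1.0)
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return al


def _merge_center_alignments(
    center_name: str, center_seq: str, pairs: list[tuple[str, str, str]]
) -> Msa:
    """Merge pairwise alignments against a common center ('once a gap,
    always a gap').  ``pairs`` holds (name, center_row, other_row)."""
    L = len(center_seq)
    # per pairwise alignment: gaps inserted into the center before position p
    ins = []  # list of arrays length L+1
    for _, crow, _ in pairs:
        g = [0] * (L + 1)
        p = 0
        for ch in crow:
            if ch == "-":
                g[p] += 1
            else:
                p += 1
        ins.append(g)
    merged = [max(g[p] for g in ins) if ins else 0 for p in range(L + 1)]

    names = [center_name]
    rows = []
    center_row = ""
    for p in range(L):
        center_row += "-" * merged[p] + center_seq[p]
    center_row += "-" * merged[L]
    rows.append(center_row)

    for (name, crow, orow), g in zip(pairs, ins):
        out = []
        p = 0
        i = 0
        # consume the pairwise alignment column by column
        pending = merged[0] - g[0]
        out.append("-" * pending)
        while i < len(crow):
            if crow[i] == "-":
                out.append(orow[i])
                i += 1
            else:
                out.append(orow[i])
                i += 1
                p += 1
                out.append("-" * (merged[p] - g[p]))
        names.append(name)
        rows.append("".join(out))
    return Msa(names=names, rows=rows)


def center_star_align(sequences: dict[str, str]) -> Msa:
    """Built-in center-star multiple aligner (global pairwise, BLOSUM62).

    The center is the sequence maximizing the summed pairwise score (ties by
    smallest name); all others are aligned to it and merged.
    """
    items = sorted(sequences.items())
    if not items:
        raise PangenomeError("center_star_align: no sequences")
    if len(items) == 1:
        return Msa(names=[items[0][0]], rows=[items[0][1]])
    al = _protein_aligner()
    names = [n for n, _ in items]
    score_sum = {n: 0.0 for n in names}
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            s = al.score(items[i][1], items[j][1])
            score_sum[names[i]] += s
            score_sum[names[j]] += s
    center = min(names, key=lambda n: (-score_sum[n], n))
    center_seq = sequences[center]
    pairs = []
    for n, seq in items:
        if n == center:
            continue
        aln = al.align(center_seq, seq)[0]
        pairs.append((n, str(aln[0]), str(aln[1])))
    msa = _merge_center_alignments(center, center_seq, pairs)
    # restore the input (sorted) order
    order = [msa.names.index(n) for n in names]
    return Msa(names=[msa.names[i] for i in order], rows=[msa.rows[i] for i in order])


def mafft_align(sequences: dict[str, str], binary: str = "mafft") -> Msa:
    """External MAFFT adapter; raises if the binary is absent."""
    if shutil.which(binary) is None:
        raise PangenomeError(f"{binary!r} not found on PATH")
    items = sorted(sequences.items())
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        with open(inp, "w") as fh:
            for n, s in items:
                fh.write(f">{n}\n{s}\n")
        proc = subprocess.run(
            [binary, "--quiet", "--auto", str(inp)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise PangenomeError(f"mafft failed: {proc.stderr[:500]}")
        names, rows, cur = [], [], []
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                names.append(line[1:].split()[0])
            else:
                cur.append(line.strip())
        if cur:
            rows.append("".join(cur))
    return Msa(names=names, rows=[r.upper() for r in rows])


def default_aligner():
    """MAFFT when available, otherwise the built-in center-star aligner."""
    if shutil.which("mafft"):
        return mafft_align
    return center_star_align


def _terminal_trim(msa: Msa) -> tuple[int, int, dict[str, tuple[int, int]]]:
    """Longest leading/trailing gap runs across rows and, per row, how many
    residues fall inside those terminal windows."""
    lead = max(len(r) - len(r.lstrip("-")) for r in msa.rows)
    trail = max(len(r) - len(r.rstrip("-")) for r in msa.rows)
    spans = {}
    for name, row in zip(msa.names, msa.rows):
        nlead = sum(1 for ch in row[:lead] if ch != "-")
        ntrail = sum(1 for ch in row[len(row) - trail :] if ch != "-") if trail else 0
        spans[name] = (nlead, ntrail)
    return lead, trail, spans


def two_round_align(
    proteins: dict[str, str],
    cds: dict[str, str] | None = None,
    aligner=None,
    min_len: int = 10,
) -> tuple[Msa, dict[str, str]] | None:
    """Align, trim terminal overhangs, re-align.

    Round 1 aligns the proteins; the maximum leading and trailing gap-column
    counts over rows define terminal windows, and every member is trimmed of
    the residues its row places inside them (CDS trimmed by codon).  Round 2
    re-aligns the trimmed proteins.  Returns ``(protein MSA, trimmed CDS)``
    or None when any member would drop below ``min_len`` residues.
    """
    if aligner is None:
        aligner = default_aligner()
    cds = cds or {}
    msa1 = aligner(proteins)
    _, _, spans = _terminal_trim(msa1)
    trimmed_prot: dict[str, str] = {}
    trimmed_cds: dict[str, str] = {}
    for name in msa1.names:
        nlead, ntrail = spans[name]
        p = proteins[name]
        newp = p[nlead : len(p) - ntrail] if ntrail else p[nlead:]
        if len(newp) < min_len:
            logger.info("two_round_align: %s trimmed below %d aa; group dropped", name, min_len)
            return None
        trimmed_prot[name] = newp
        if name in cds:
            c = cds[name]
            if len(c) == 3 * len(p) + 3:  # trailing stop codon present
                c = c[:-3]
            newc = c[3 * nlead : len(c) - 3 * ntrail] if ntrail else c[3 * nlead :]
            trimmed_cds[name] = newc
    msa2 = aligner(trimmed_prot)
    return msa2, trimmed_cds


# ---------------------------------------------------------------------------
# SNP extraction


def parsimony_informative_columns(rows: list[str]) -> list[int]:
    """Indices of columns with >= 2 distinct non-gap states each seen in
    >= 2 rows.  Gaps are not states.  Fewer than 4 rows cannot produce such a
    column with meaning; an empty list is returned with a warning."""
    if len(rows) < 4:
        logger.warning("parsimony-informative scan on %d rows (<4): empty result", len(rows))
        return []
    if len({len(r) for r in rows}) > 1:
        raise PangenomeError("rows have unequal lengths")
    out = []
    for i in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[i]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append(i)
    return out


def _codon_expand(msa: Msa, cds: dict[str, str]) -> Msa:
    """Expand a protein alignment to codons, keeping gap columns as ---."""
    rows = []
    for name, row in zip(msa.names, msa.rows):
        c = cds[name]
        out = []
        p = 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(c[3 * p : 3 * p + 3])
                p += 1
        rows.append("".join(out))
    return Msa(names=list(msa.names), rows=rows)


@dataclass
class SnpMatrix:
    """Concatenated parsimony-informative nucleotide columns per haplotype."""

    labels: list[str]
    rows: list[str]
    provenance: list[tuple[str, int]] = field(default_factory=list)  # (group_id, column)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def core_snp_matrix(store, chromosome: int, groups, aligner=None) -> SnpMatrix:
    """Per-haplotype concatenation of parsimony-informative SNPs from the
    single-copy groups of one chromosome.

    Each single-copy group (exactly one gene per haplotype of the
    chromosome) is aligned with :func:`two_round_align`, expanded to codons,
    and its informative columns appended in ascending group-id order.
    """
    from .classify import single_copy_groups
    from .model import extract_feature_sequence

    sc = single_copy_groups(store, groups, scope=f"chromosome:{chromosome}")
    if not sc:
        raise PangenomeError(
            f"no single-copy groups on chromosome {chromosome}; "
            "phasing quality may be insufficient for a core SNP tree"
        )
    hap_label = {}
    for rec in store.sequences.values():
        if rec.haplotype.chromosome == chromosome:
            hap_label[(rec.genome_id, rec.haplotype.phase)] = f"g{rec.genome_id}#{chromosome}{rec.haplotype.phase}"
    labels = sorted(hap_label.values())
    parts: dict[str, list[str]] = {lab: [] for lab in labels}
    provenance: list[tuple[str, int]] = []
    for grp in sorted(sc, key=lambda g: g.group_id):
        prot, cds = {}, {}
        for gene_id in sorted(grp.members):
            gene = store.gene(gene_id)
            rec = store.sequences[gene.sequence_key]
            if rec.haplotype.chromosome != chromosome:
                continue  # single-copy status is scoped to this chromosome
            lab = hap_label[(gene.genome_id, rec.haplotype.phase)]
            prot[lab] = extract_feature_sequence(store, gene_id, "protein")
            cds[lab] = extract_feature_sequence(store, gene_id, "CDS")
        res = two_round_align(prot, cds, aligner=aligner)
        if res is None:
            continue
        msa, tcds = res
        codon_msa = _codon_expand(msa, tcds)
        cols = parsimony_informative_columns(codon_msa.rows)
        for c in cols:
            provenance.append((grp.group_id, c))
            for name, row in zip(codon_msa.names, codon_msa.rows):
                parts[name].append(row[c])
    rows = ["".join(parts[lab]) for lab in labels]
    return SnpMatrix(labels=labels, rows=rows, provenance=provenance)


# ---------------------------------------------------------------------------
# external tool adapters


def write_phylip(labels: list[str], rows: list[str], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f" {len(labels)} {len(rows[0]) if rows else 0}\n")
        for lab, row in zip(labels, rows):
            fh.write(f"{lab[:50].ljust(50)}{row}\n")
    return path


def read_phylip(path) -> tuple[list[str], list[str]]:
    with open(path) as fh:
        header = fh.readline().split()
        n, L = int(header[0]), int(header[1])
        labels, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            labels.append(line[:50].strip())
            rows.append(line[50:].strip())
    if len(labels) != n or any(len(r) != L for r in rows):
        raise PangenomeError(f"malformed PHYLIP file {path}")
    return labels, rows


def write_fasta_alignment(labels: list[str], rows: list[str], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for lab, row in zip(labels, rows):
            fh.write(f">{lab}\n{row}\n")
    return path


def write_gene_trees(trees: list[TreeNode], path) -> Path:
    """One Newick per line, for consensus-tree tools (ASTRAL-Pro style)."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in trees:
            fh.write(str(t).strip() + "\n")
    return path


def run_external_tree(binary: str, args: list[str], output_tree: str) -> TreeNode | None:
    """Invoke an external tree program if present; parse its Newick output.

    Absent binaries are a documented skip (returns None), so pipelines do not
    fail on machines without the optional tools.
    """
    if shutil.which(binary) is None:
        logger.info("external tree tool %r not found; skipping", binary)
        return None
    proc = subprocess.run([binary, *args], capture_output=True, text=True)
    if proc.returncode != 0:
        raise PangenomeError(f"{binary} failed: {proc.stderr[:500]}")
    out = Path(output_tree)
    if not out.exists():
        raise PangenomeError(f"{binary} produced no tree at {out}: {proc.stderr[:500]}")
    return TreeNode.read(str(out))
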
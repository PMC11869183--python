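"""Collinear block detection and sliding-window gene retention.

Homologous gene pairs between two sequences (same homology group) are placed
in rank space — the position index of each gene in start-coordinate order —
and chained by dynamic programming into collinear blocks, separately for the
parallel and antiparallel orientations.  The chaining constants follow the
MCScanX defaults (match score 50, unit gap penalty, at most 25 ranks between
consecutive anchors, at least 5 pairs per block); the detector also reads and
writes the MCScanX ``.collinearity`` text dialect so externally produced
files drop in unchanged.

Retention of a query sequence against targets is measured in sliding windows
of 100 genes moved in steps of 10 (full windows only): the percentage of
window genes with a homologue (same group) or a syntelog (additionally a
registered syntenic pair) on the target.  Syntenic depth is ignored, so
retention never exceeds 100%.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .homology import HomologyGroup
from .model import GeneModel, PangenomeError, PangenomeStore

logger = logging.getLogger("phasepan")

__all__ = [
    "GenePairMatch",
    "SyntenyBlock",
    "RetentionTrack",
    "build_pair_inputs",
    "detect_collinear_blocks",
    "write_collinearity",
    "parse_collinearity",
    "write_mcscanx_gff",
    "add_synteny",
    "gene_retention",
    "write_retention",
]

MIN_BLOCK_SIZE = 5
MAX_GAP = 25
MATCH_SCORE = 50.0
GAP_PENALTY = -1.0


@dataclass(frozen=True)
class GenePairMatch:
    query_rank: int
    target_rank: int
    query_gene: str
    target_gene: str
    group_id: str


@dataclass
class SyntenyBlock:
    block_id: int
    query_label: str
    target_label: str
    pairs: list[GenePairMatch]
    orientation: str  # parallel | antiparallel
    score: float = 0.0

    def __post_init__(self) -> None:
        q = [p.query_rank for p in self.pairs]
        t = [p.target_rank for p in self.pairs]
        if any(b <= a for a, b in zip(q, q[1:])):
            raise PangenomeError("block query ranks must be strictly increasing")
        if self.orientation == "parallel":
            if any(b <= a for a, b in zip(t, t[1:])):
                raise PangenomeError("parallel block target ranks must increase")
        elif self.orientation == "antiparallel":
            if any(b >= a for a, b in zip(t, t[1:])):
                raise PangenomeError("antiparallel block target ranks must decrease")
        else:
            raise PangenomeError(f"bad orientation {self.orientation!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class RetentionTrack:
    query_label: str
    target_label: str
    mode: str  # homology | synteny
    window_size: int
    step: int
    # (start_bp, end_bp, percent retained) per full-sized window
    windows: list[tuple[int, int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pair inputs


def gene_order(store: PangenomeStore, genome_id: int, sequence_name: str) -> list[GeneModel]:
    genes = store.genes_on(genome_id, sequence_name)
    if not genes:
        raise PangenomeError(f"sequence {sequence_name!r} of genome {genome_id} has no annotations")
    return genes


def build_pair_inputs(
    store: PangenomeStore,
    query: tuple[int, str],
    target: tuple[int, str],
    groups: list[HomologyGroup],
) -> tuple[list[GeneModel], list[GeneModel], list[GenePairMatch]]:
    """Gene orders of both sequences plus every cross-sequence gene pair
    sharing a homology group, in rank space."""
    q_genes = gene_order(store, *query)
    t_genes = gene_order(store, *target)
    group_of: dict[str, str] = {}
    for grp in groups:
        for m in grp.members:
            group_of[m] = grp.group_id
    t_by_group: dict[str, list[int]] = {}
    for j, g in enumerate(t_genes):
        gid = group_of.get(g.gene_id)
        if gid:
            t_by_group.setdefault(gid, []).append(j)
    matches = []
    for i, g in enumerate(q_genes):
        gid = group_of.get(g.gene_id)
        if not gid:
            continue
        for j in t_by_group.get(gid, ()):
            matches.append(
                GenePairMatch(
                    query_rank=i,
                    target_rank=j,
                    query_gene=g.gene_id,
                    target_gene=t_genes[j].gene_id,
                    group_id=gid,
                )
            )
    matches.sort(key=lambda m: (m.query_rank, m.target_rank))
    return q_genes, t_genes, matches


# ---------------------------------------------------------------------------
# collinear chaining


def _chain(
    matches: list[GenePairMatch],
    antiparallel: bool,
    min_block_size: int,
    max_gap: int,
    match_score: float,
    gap_penalty: float,
) -> list[tuple[float, list[GenePairMatch]]]:
    """All non-overlapping best chains for one orientation, by repeated DP.

    DP in rank space: a match extends a previous one when both rank deltas
    are positive (target delta negative for antiparallel) and each is at most
    ``max_gap``; the transition costs ``gap_penalty`` per skipped rank.
    """
    pool = list(matches)
    chains = []
    while pool:
        pts = sorted(pool, key=lambda m: (m.query_rank, m.target_rank))
        n = len(pts)
        score = [match_score] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                dq = pts[i].query_rank - pts[j].query_rank
                dt = pts[i].target_rank - pts[j].target_rank
                if antiparallel:
                    dt = -dt
                if dq <= 0 or dt <= 0 or dq > max_gap or dt > max_gap:
                    continue
                s = score[j] + match_score + gap_penalty * (dq - 1 + dt - 1)
                if s > score[i] + 1e-9:
                    score[i] = s
                    prev[i] = j
        best_i = max(range(n), key=lambda i: (score[i], len(_trace(prev, i))))
        chain = [pts[i] for i in _trace(prev, best_i)]
        if len(chain) < min_block_size:
            break
        chains.append((score[best_i], chain))
        used = set(id(m) for m in chain)
        # also retire matches whose query or target rank is inside the chain,
        # so one gene does not anchor two overlapping chains
        qr = {m.query_rank for m in chain}
        tr = {m.target_rank for m in chain}
        pool = [m for m in pool if id(m) not in used and m.query_rank not in qr and m.target_rank not in tr]
    return chains


def _trace(prev: list[int], i: int) -> list[int]:
    out = []
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def detect_collinear_blocks(
    matches: list[GenePairMatch],
    query_label: str = "q",
    target_label: str = "t",
    min_block_size: int = MIN_BLOCK_SIZE,
    max_gap: int = MAX_GAP,
    match_score: float = MATCH_SCORE,
    gap_penalty: float = GAP_PENALTY,
) -> list[SyntenyBlock]:
    """Chain homologous gene pairs of one sequence pair into collinear
    blocks, both orientations; overlaps resolved by score, then chain length,
    then smallest query start rank."""
    if not matches:
        return []
    cands = []
    for anti in (False, True):
        for sc, chain in _chain(matches, anti, min_block_size, max_gap, match_score, gap_penalty):
            cands.append((sc, len(chain), chain[0].query_rank, "antiparallel" if anti else "parallel", chain))
    cands.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    used_q: set[int] = set()
    used_t: set[int] = set()
    blocks = []
    for sc, _, _, orient, chain in cands:
        if any(m.query_rank in used_q or m.target_rank in used_t for m in chain):
            chain = [m for m in chain if m.query_rank not in used_q and m.target_rank not in used_t]
            chain = _longest_valid_run(chain, orient)
            if len(chain) < min_block_size:
                continue
        used_q |= {m.query_rank for m in chain}
        used_t |= {m.target_rank for m in chain}
        blocks.append(
            SyntenyBlock(
                block_id=len(blocks),
                query_label=query_label,
                target_label=target_label,
                pairs=chain,
                orientation=orient,
                score=sc,
            )
        )
    blocks = _split_bridged_blocks(blocks, query_label, target_label, min_block_size, match_score, gap_penalty)
    blocks.sort(key=lambda b: b.pairs[0].query_rank)
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def _split_bridged_blocks(
    blocks: list[SyntenyBlock],
    query_label: str,
    target_label: str,
    min_block_size: int,
    match_score: float,
    gap_penalty: float,
) -> list[SyntenyBlock]:
    """Split any block that jumps over query ranks anchored by another block
    (e.g. a collinear chain bridging across an inversion), so rearranged
    segments surface as separate blocks with tight boundaries."""
    owner: dict[int, int] = {}
    for bi, b in enumerate(blocks):
        for p in b.pairs:
            owner[p.query_rank] = bi
    out: list[SyntenyBlock] = []
    for bi, b in enumerate(blocks):
        segments: list[list[GenePairMatch]] = [[b.pairs[0]]]
        for prev, cur in zip(b.pairs, b.pairs[1:]):
            bridged = any(
                owner.get(q, bi) != bi for q in range(prev.query_rank + 1, cur.query_rank)
            )
            if bridged:
                segments.append([cur])
            else:
                segments[-1].append(cur)
        for seg in segments:
            if len(seg) < min_block_size:
                continue
            score = match_score * len(seg) + gap_penalty * sum(
                (y.query_rank - x.query_rank - 1) + abs(y.target_rank - x.target_rank) - 1
                for x, y in zip(seg, seg[1:])
            )
            out.append(
                SyntenyBlock(
                    block_id=0,
                    query_label=query_label,
                    target_label=target_label,
                    pairs=seg,
                    orientation=b.orientation,
                    score=score,
                )
            )
    return out


def _longest_valid_run(chain: list[GenePairMatch], orient: str) -> list[GenePairMatch]:
    """Longest monotone sub-run after overlap removal (keeps invariants)."""
    if not chain:
        return chain
    sign = 1 if orient == "parallel" else -1
    best, cur = [chain[0]], [chain[0]]
    for m in chain[1:]:
        last = cur[-1]
        if m.query_rank > last.query_rank and sign * (m.target_rank - last.target_rank) > 0:
            cur.append(m)
        else:
            cur = [m]
        if len(cur) > len(best):
            best = cur
    return best


# ---------------------------------------------------------------------------
# MCScanX collinearity dialect


def write_collinearity(blocks: list[SyntenyBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("############### Parameters ###############\n")
        fh.write(f"# MATCH_SCORE: {MATCH_SCORE:g}\n# MAX GAPS: {MAX_GAP}\n")
        fh.write("############### Statistics ###############\n")
        for b in blocks:
            strand = "minus" if b.orientation == "antiparallel" else "plus"
            fh.write(
                f"## Alignment {b.block_id}: score={b.score:g} e_value=0 N={b.n_pairs} "
                f"{b.query_label}&{b.target_label} {strand}\n"
            )
            for i, p in enumerate(b.pairs):
                fh.write(f"{b.block_id}-{i:>3}:\t{p.query_gene}\t{p.target_gene}\t0\n")


_ALN_RE = re.compile(
    r"^## Alignment (\d+): score=([\d.eE+-]+) e_value=\S+ N=(\d+) (\S+)&(\S+) (plus|minus)"
)


def parse_collinearity(path, rank_lookup=None) -> list[SyntenyBlock]:
    """Parse an MCScanX-style .collinearity file.

    ``rank_lookup(label, gene_id) -> rank`` supplies gene ranks; without it,
    pair order within the alignment is used for query ranks and orientation
    determines target ranks, preserving block structure for round trips.
    """
    blocks: list[SyntenyBlock] = []
    header = None
    rows: list[tuple[str, str]] = []

    def _flush():
        nonlocal header, rows
        if header is None:
            return
        bid, score, n, qlab, tlab, strand = header
        if len(rows) != n:
            raise PangenomeError(f"block {bid}: expected {n} pairs, found {len(rows)}")
        orient = "antiparallel" if strand == "minus" else "parallel"
        pairs = []
        for i, (qg, tg) in enumerate(rows):
            if rank_lookup is not None:
                qr, tr = rank_lookup(qlab, qg), rank_lookup(tlab, tg)
            else:
                qr = i
                tr = i if orient == "parallel" else n - 1 - i
            pairs.append(GenePairMatch(qr, tr, qg, tg, group_id=""))
        blocks.append(SyntenyBlock(bid, qlab, tlab, pairs, orient, score))
        header, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                _flush()
                m = _ALN_RE.match(line)
                if not m:
                    raise PangenomeError(f"{path}: malformed alignment header at line {lineno}")
                header = (
                    int(m.group(1)),
                    float(m.group(2)),
                    int(m.group(3)),
                    m.group(4),
                    m.group(5),
                    m.group(6),
                )
            elif line.startswith("#") or not line.strip():
                continue
            elif header is not None:
                parts = line.split("\t")
                if len(parts) < 3:
                    raise PangenomeError(f"{path}: malformed pair line at line {lineno}")
                rows.append((parts[1], parts[2]))
    _flush()
    return blocks


def write_mcscanx_gff(store: PangenomeStore, path) -> None:
    """MCScanX 4-column 'gff' input: label, gene, start, end."""
    with open(path, "w") as fh:
        for (gid, name), rec in sorted(store.sequences.items()):
            genes = [
                g for g in store.genes.values()
                if g.genome_id == gid and g.sequence_name == name
            ]
            genes.sort(key=lambda g: (g.start, g.gene_id))
            for g in genes:
                fh.write(f"{rec.label}\t{g.gene_id}\t{g.start + 1}\t{g.end}\n")


# ---------------------------------------------------------------------------
# syntenic-pair relations


def add_synteny(store: PangenomeStore, blocks: list[SyntenyBlock]) -> int:
    """Register every in-block gene pair as a symmetric syntenic relation.

    Re-adding blocks is idempotent (set semantics).  Returns the number of
    relations (unordered pairs) registered after the call.
    """
    for b in blocks:
        for p in b.pairs:
            for g in (p.query_gene, p.target_gene):
                if g not in store.genes:
                    raise PangenomeError(f"synteny block references unknown gene {g!r}")
            store.syntenic_partners.setdefault(p.query_gene, set()).add(p.target_gene)
            store.syntenic_partners.setdefault(p.target_gene, set()).add(p.query_gene)
    store.synteny_blocks = list(store.synteny_blocks) + [
        b for b in blocks if b not in store.synteny_blocks
    ]
    return sum(len(v) for v in store.syntenic_partners.values()) // 2


# ---------------------------------------------------------------------------
# retention


def gene_retention(
    store: PangenomeStore,
    query: tuple[int, str],
    targets: list[tuple[int, str]],
    groups: list[HomologyGroup],
    mode: str = "homology",
    window: int = 100,
    step: int = 10,
) -> list[RetentionTrack]:
    """Sliding-window retention of the query's genes on each target.

    A query gene is retained on a target when at least one homologue (same
    homology group; ``mode="homology"``) or at least one syntenic partner
    (``mode="synteny"``) lies on that target — anywhere on it; depth is
    ignored.  Windows cover ``window`` consecutive genes, advance by
    ``step``, and only full-sized windows are reported, with bp ranges from
    the first gene's start to the last gene's end.
    """
    if mode not in ("homology", "synteny"):
        raise PangenomeError(f"mode must be homology or synteny, got {mode!r}")
    q_genes = gene_order(store, *query)
    if len(q_genes) < window:
        raise PangenomeError(
            f"query has {len(q_genes)} genes < window {window}; use a smaller window"
        )
    if mode == "synteny" and not store.syntenic_partners:
        raise PangenomeError("synteny mode requires add_synteny first")
    group_of: dict[str, str] = {}
    for grp in groups:
        for m in grp.members:
            group_of[m] = grp.group_id
    q_label = store.sequences[query].label
    tracks = []
    for target in targets:
        t_genes = gene_order(store, *target)
        t_label = store.sequences[target].label
        t_gene_ids = {g.gene_id for g in t_genes}
        if mode == "homology":
            t_groups = {group_of[g.gene_id] for g in t_genes if g.gene_id in group_of}
            retained = [
                g.gene_id in group_of and group_of[g.gene_id] in t_groups for g in q_genes
            ]
        else:
            retained = [
                bool(store.syntenic_partners.get(g.gene_id, set()) & t_gene_ids)
                for g in q_genes
            ]
        windows = []
        start = 0
        while start + window <= len(q_genes):
            count = sum(retained[start : start + window])
            first, last = q_genes[start], q_genes[start + window - 1]
            windows.append((first.start, last.end, 100.0 * count / window))
            start += step
        tracks.append(
            RetentionTrack(
                query_label=q_label,
                target_label=t_label,
                mode=mode,
                window_size=window,
                step=step,
                windows=windows,
            )
        )
    return tracks


def write_retention(tracks: list[RetentionTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\tmode\twindow_start_bp\twindow_end_bp\tpercent\n")
        for t in tracks:
            for s, e, pct in t.windows:
                fh.write(f"{t.query_label}\t{t.target_label}\t{t.mode}\t{s}\t{e}\t{pct:.4f}\n")
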
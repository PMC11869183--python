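"""Codon alignments and Nei–Gojobori (1986) Dn/Ds estimation.

Protein alignments are back-translated to codon alignments; columns holding
a gap or an in-frame stop in any member are removed in all members, and any
alignment whose source protein is shorter than 30 amino acids is dropped to
avoid short-alignment artefacts.

Rates use the NG86 counting estimator.  Per codon, each position contributes
a synonymous-site fraction equal to the proportion of its three possible
changes that preserve the amino acid (changes to stop codons count as
nonsynonymous); site counts are averaged over the two sequences.  Observed
differences between a codon pair are partitioned over all shortest
mutational pathways with equal weights, pathways through stop codons
excluded (all-blocked pairs fall back to all pathways).  The Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3) is applied separately to the synonymous
and nonsynonymous proportions; p ≥ 3/4 marks the estimate invalid.

Within- and between-genome Ds distributions localize divergence events:
haplotype heterozygosity produces a very young peak and whole-genome
duplications an old one, the pattern this module's histogram/mode report is
designed to expose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

from .homology import HomologyGroup
from .model import PangenomeError, PangenomeStore, extract_feature_sequence, translate_cds
from .phylo import Msa, two_round_align

logger = logging.getLogger("phasepan")

__all__ = [
    "CodonAlignment",
    "RateEstimate",
    "back_translate_alignment",
    "ng86_rates",
    "pairwise_ds_scan",
    "ds_histogram",
    "write_estimates",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}
for _a in _BASES:
    for _b in _BASES:
        for _c in _BASES:
            _codon = _a + _b + _c
            _CODON_TABLE[_codon], _ = translate_cds(_codon) if _codon not in _STOPS else ("*", False)
for _s in _STOPS:
    _CODON_TABLE[_s] = "*"


@dataclass
class CodonAlignment:
    group_id: str
    names: list[str]
    rows: list[str]  # gap-free, equal length, length % 3 == 0
    excluded_columns: list[int] = field(default_factory=list)  # codon-column indices

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0


@dataclass
class RateEstimate:
    gene_a: str
    gene_b: str
    dn: float
    ds: float
    valid: bool
    group_id: str = ""
    scope: str = ""


# ---------------------------------------------------------------------------
# back-translation


def back_translate_alignment(
    msa: Msa, cds: dict[str, str], group_id: str = "", min_aa: int = 30
) -> CodonAlignment | None:
    """Convert a protein alignment + ungapped CDS set to a codon alignment.

    Codon columns containing any gap or in-frame stop are excluded from all
    rows.  Returns None (with a log entry) when any source protein is shorter
    than ``min_aa`` amino acids.
    """
    for name in msa.names:
        prot = msa.ungapped(name)
        if len(prot) < min_aa:
            logger.info("group %s: %s shorter than %d aa; alignment dropped", group_id, name, min_aa)
            return None
        c = cds[name]
        if len(c) == 3 * len(prot) + 3:
            c = c[:-3]  # trailing stop codon
        if len(c) != 3 * len(prot):
            raise PangenomeError(f"member {name}: CDS length {len(c)} does not match protein length {len(prot)}")
        aa, _ = translate_cds(c)
        if aa != prot:
            raise PangenomeError(f"member {name}: CDS does not translate to its protein row")
        cds = {**cds, name: c}
    codon_rows = []
    for name in msa.names:
        row = msa.row(name)
        c = cds[name]
        if len(c) == 3 * (len(row.replace("-", ""))) + 3:
            c = c[:-3]
        out, p = [], 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(c[3 * p : 3 * p + 3])
                p += 1
        codon_rows.append(out)
    n_cols = len(codon_rows[0])
    keep, dropped = [], []
    for i in range(n_cols):
        col = [r[i] for r in codon_rows]
        if any("-" in c for c in col) or any(c in _STOPS for c in col):
            dropped.append(i)
        else:
            keep.append(i)
    rows = ["".join(r[i] for i in keep) for r in codon_rows]
    return CodonAlignment(group_id=group_id, names=list(msa.names), rows=rows, excluded_columns=dropped)


# ---------------------------------------------------------------------------
# NG86


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon."""
    if codon in _STOPS or any(b not in _BASES for b in codon):
        return (0.0, 0.0)
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut not in _STOPS and _CODON_TABLE[mut] == aa:
                syn += 1.0
    return (syn / 3.0, 3.0 - syn / 3.0)


@lru_cache(maxsize=None)
def _codon_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) observed differences between two codons,
    averaged over all shortest mutational pathways (equal weights, pathways
    through stops excluded)."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return (0.0, 0.0)
    results = []
    for order in permutations(diff):
        cur = a
        syn = non = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        results.append((syn, non, blocked))
    open_paths = [r for r in results if not r[2]]
    use = open_paths if open_paths else results
    syn = sum(r[0] for r in use) / len(use)
    non = sum(r[1] for r in use) / len(use)
    return (syn, non)


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        return 0.0
    if p >= 0.75:
        return None
    return max(0.0, -0.75 * math.log(1.0 - 4.0 * p / 3.0))


def ng86_rates(row_a: str, row_b: str) -> RateEstimate:
    """NG86 Dn/Ds of two equal-length, gap-free codon strings."""
    if len(row_a) != len(row_b):
        raise PangenomeError("codon rows differ in length")
    if len(row_a) % 3 != 0:
        raise PangenomeError("codon row length must be divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    if S <= 0 or N <= 0:
        raise PangenomeError("no countable sites")
    ps, pn = Sd / S, Nd / N
    ds, dn = _jukes_cantor(ps), _jukes_cantor(pn)
    valid = ds is not None and dn is not None
    return RateEstimate(
        gene_a="", gene_b="", dn=dn if dn is not None else math.inf,
        ds=ds if ds is not None else math.inf, valid=valid,
    )


# ---------------------------------------------------------------------------
# group scans


def _qualifying_pairs(store: PangenomeStore, members: list[str], scope) -> list[tuple[str, str]]:
    kind = scope[0]
    out = []
    for a, b in combinations(sorted(members), 2):
        ga, gb = store.gene(a), store.gene(b)
        ha = store.sequences[ga.sequence_key].haplotype
        hb = store.sequences[gb.sequence_key].haplotype
        if kind == "between":
            gx, gy = scope[1], scope[2]
            if {ga.genome_id, gb.genome_id} == {gx, gy} and ga.genome_id != gb.genome_id:
                out.append((a, b))
        elif kind == "within":
            gx = scope[1]
            if ga.genome_id == gx == gb.genome_id:
                if ha.phased and hb.phased and (ha.phase != hb.phase or ha.chromosome != hb.chromosome):
                    out.append((a, b))
    return out


def pairwise_ds_scan(
    store: PangenomeStore,
    groups: list[HomologyGroup],
    scope: tuple,
    aligner=None,
    min_aa: int = 30,
) -> list[RateEstimate]:
    """Dn/Ds for every qualifying member pair of every homology group.

    ``scope`` is ``("between", genome_x, genome_y)`` — pairs across the two
    genomes — or ``("within", genome_x)`` — pairs across different haplotypes
    of one genome (two genes of the same haplotype are never paired).
    Invalid (saturated) estimates are returned flagged; summaries should
    exclude them.
    """
    if scope[0] not in ("between", "within"):
        raise PangenomeError(f"unknown scope {scope!r}")
    for gid in scope[1:]:
        if gid not in store.genomes:
            raise PangenomeError(f"unknown genome {gid}")
    if scope[0] == "within" and store.genomes[scope[1]].ploidy < 2:
        logger.warning("genome %d is haploid; within-genome scan is empty", scope[1])
        return []
    estimates: list[RateEstimate] = []
    for grp in sorted(groups, key=lambda g: g.group_id):
        members = sorted(grp.members)
        pairs = _qualifying_pairs(store, members, scope)
        if not pairs:
            continue
        needed = sorted({g for p in pairs for g in p})
        prot = {g: extract_feature_sequence(store, g, "protein") for g in needed}
        cds = {g: extract_feature_sequence(store, g, "CDS") for g in needed}
        if any(len(p) < min_aa for p in prot.values()):
            continue
        res = two_round_align(prot, cds, aligner=aligner)
        if res is None:
            continue
        msa, tcds = res
        ca = back_translate_alignment(msa, tcds, group_id=grp.group_id, min_aa=min_aa)
        if ca is None or ca.n_codons == 0:
            continue
        row_of = dict(zip(ca.names, ca.rows))
        for a, b in pairs:
            est = ng86_rates(row_of[a], row_of[b])
            est.gene_a, est.gene_b = a, b
            est.group_id, est.scope = grp.group_id, f"{scope[0]}:" + ",".join(map(str, scope[1:]))
            estimates.append(est)
    return estimates


def ds_histogram(
    estimates: list[RateEstimate],
    n_bins: int = 60,
    lo: float = 1e-4,
    hi: float = 10.0,
    smooth: int = 3,
    prominence_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Log-binned Ds histogram with detected modes.

    Returns ``(bin_edges, counts, modes)`` where modes are the geometric bin
    centers of local maxima of the smoothed histogram whose prominence
    exceeds ``prominence_frac`` of the tallest peak.  Ds values are clamped
    into the binning range so no estimate is silently dropped.
    """
    vals = [e.ds for e in estimates if e.valid]
    if not vals:
        raise PangenomeError("no valid estimates to bin")
    vals = np.clip(np.asarray(vals), lo, hi * (1 - 1e-12))
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(counts, kernel, mode="same")
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    centers = np.sqrt(edges[:-1] * edges[1:])
    modes = [float(centers[p]) for p in peaks]
    return edges, counts, modes


def write_estimates(estimates: list[RateEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tgeneA\tgeneB\tscope\tDn\tDs\tvalid\n")
        for e in estimates:
            fh.write(
                f"{e.group_id}\t{e.gene_a}\t{e.gene_b}\t{e.scope}\t"
                f"{e.dn:.6g}\t{e.ds:.6g}\t{int(e.valid)}\n"
            )
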
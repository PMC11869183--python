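"""Chromosome-scale annotation tracks, coverage profiles and figure tables.

Five per-sequence annotation bars are computed as interval tables: gene
intervals colored by pangenome class (core/accessory/cloud), by
subgenome-presence count within the gene's own genome, or greyed when a
homologue lies on a *different* chromosome number (copies on the same
chromosome but a different haplotype do not trigger grey); plus gene- and
repeat-coverage percentages in 1 Mb windows.  Rendering is a thin matplotlib
layer over these tables — every plotted value is also emitted as a table,
which is the testable surface.

Whole-genome alignment planning enumerates homeologous pairs (equal
chromosome numbers across haplotypes and genomes) and variant records from
external aligners are quality-filtered (< 10 dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import GroupClass
from .model import PangenomeError, PangenomeStore, SequenceRecord

logger = logging.getLogger("phasepan")

__all__ = [
    "Track",
    "PairingPlan",
    "VariantRecord",
    "gene_presence_track",
    "coverage_track",
    "pairing_plan",
    "dotplot_plan_and_filter",
    "parse_variant_records",
    "stacked_chromosome_figure",
]

CLASS_COLORS = {"core": "#1b9e77", "accessory": "#d95f02", "cloud": "#7570b3"}
GREY = "#999999"
SUBGENOME_CMAP = "viridis"


@dataclass
class Track:
    sequence_label: str
    kind: str  # pangenome_class | subgenome_count | other_chromosome_copy | coverage
    # interval tracks: (start, end, value, color); coverage: (start, end, percent, "")
    intervals: list[tuple[int, int, str | float, str]] = field(default_factory=list)


@dataclass
class PairingPlan:
    pairs: list[tuple[str, str]]  # sequence labels, unordered pairs once


@dataclass
class VariantRecord:
    sequence: str
    start: int
    end: int
    quality: int
    ref: str
    alt: str


# ---------------------------------------------------------------------------
# annotation bars


def _class_index(classes: list[GroupClass]) -> dict[str, GroupClass]:
    idx: dict[str, GroupClass] = {}
    for gc in classes:
        for m in gc.group.members:
            idx[m] = gc
    return idx


def gene_presence_track(
    store: PangenomeStore,
    sequence: tuple[int, str],
    kind: str,
    classes: list[GroupClass],
) -> Track:
    """One colored interval per gene of the sequence.

    ``pangenome_class`` colors by core/accessory/cloud; ``subgenome_count``
    by the number of subgenomes of the gene's genome containing the group;
    ``other_chromosome_copy`` greys a gene iff a group member lies on a
    different (non-zero) chromosome number, anywhere in the pangenome —
    same-chromosome different-haplotype copies never trigger grey.
    """
    if not classes:
        raise PangenomeError("classification missing; run classify_groups first")
    idx = _class_index(classes)
    rec = store.sequences[sequence]
    out = Track(sequence_label=rec.label, kind=kind)
    genes = store.genes_on(*sequence)
    own_chrom = rec.haplotype.chromosome
    for g in genes:
        gc = idx.get(g.gene_id)
        if gc is None:
            continue
        if kind == "pangenome_class":
            val = gc.intergenomic
            color = CLASS_COLORS[val]
        elif kind == "subgenome_count":
            val = gc.subgenome_counts.get(g.genome_id, 0)
            ploidy = store.genomes[g.genome_id].ploidy
            cmap = plt.get_cmap(SUBGENOME_CMAP)
            color = matplotlib.colors.to_hex(cmap(val / max(ploidy, 1)))
        elif kind == "other_chromosome_copy":
            elsewhere = False
            for m in gc.group.members:
                other = store.gene(m)
                hap = store.sequences[other.sequence_key].haplotype
                if hap.chromosome not in (0, own_chrom):
                    elsewhere = True
                    break
            val = "grey" if elsewhere else "unique"
            color = GREY if elsewhere else "#ffffff"
        else:
            raise PangenomeError(f"unknown track kind {kind!r}")
        out.intervals.append((g.start, g.end, val, color))
    return out


def coverage_track(
    store: PangenomeStore,
    sequence: tuple[int, str],
    annotation: str = "gene",
    window: int = 1_000_000,
) -> Track:
    """Percent of window bases covered by the union of annotations.

    Windows tile the sequence; the final partial window is normalized by its
    own length.  ``annotation`` is ``gene`` or ``repeat``.
    """
    rec = store.sequences[sequence]
    if annotation == "gene":
        ivals = [(g.start, g.end) for g in store.genes_on(*sequence)]
    elif annotation == "repeat":
        ivals = [
            (r.start, r.end)
            for r in store.repeats
            if r.genome_id == sequence[0] and r.sequence_name == sequence[1]
        ]
    else:
        raise PangenomeError(f"annotation must be gene or repeat, got {annotation!r}")
    # merge the interval union once, then intersect per window
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out = Track(sequence_label=rec.label, kind="coverage")
    pos = 0
    while pos < rec.length:
        wend = min(pos + window, rec.length)
        covered = 0
        for s, e in merged:
            if e <= pos or s >= wend:
                continue
            covered += min(e, wend) - max(s, pos)
        pct = 100.0 * covered / (wend - pos)
        out.intervals.append((pos, wend, pct, ""))
        pos = wend
    return out


# ---------------------------------------------------------------------------
# alignment planning and variant filtering


def pairing_plan(store: PangenomeStore, chromosome: int | None = None) -> PairingPlan:
    """All same-chromosome-number sequence pairs (chromosome 0 excluded)."""
    by_chrom: dict[int, list[SequenceRecord]] = {}
    for rec in store.sequences.values():
        c = rec.haplotype.chromosome
        if c == 0 or (chromosome is not None and c != chromosome):
            continue
        by_chrom.setdefault(c, []).append(rec)
    pairs = []
    for c in sorted(by_chrom):
        recs = sorted(by_chrom[c], key=lambda r: r.label)
        for a, b in combinations(recs, 2):
            pairs.append((a.label, b.label))
    return PairingPlan(pairs=pairs)


def parse_variant_records(path) -> list[VariantRecord]:
    """Parse variant lines of a paftools.js-style call file.

    Only ``V`` lines are variants: tab-separated
    ``V <seq> <start> <end> <depth> <quality> <ref> <alt> ...``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] != "V":
                continue
            try:
                out.append(
                    VariantRecord(
                        sequence=parts[1],
                        start=int(parts[2]),
                        end=int(parts[3]),
                        quality=int(parts[5]),
                        ref=parts[6] if len(parts) > 6 else "",
                        alt=parts[7] if len(parts) > 7 else "",
                    )
                )
            except (IndexError, ValueError):
                raise PangenomeError(f"{path}: malformed variant line {lineno}") from None
    return out


def dotplot_plan_and_filter(
    store: PangenomeStore,
    variant_paths: list | None = None,
    min_quality: int = 10,
    chromosome: int | None = None,
) -> tuple[PairingPlan, list[VariantRecord]]:
    """Homeologous-pair alignment plan plus quality-filtered variants.

    Variant records below ``min_quality`` are removed, mirroring the
    quality-<10 filter applied to external whole-genome-alignment calls.
    """
    plan = pairing_plan(store, chromosome=chromosome)
    variants: list[VariantRecord] = []
    for path in variant_paths or []:
        variants.extend(parse_variant_records(path))
    kept = [v for v in variants if v.quality >= min_quality]
    if variants:
        logger.info("variants: %d of %d pass quality >= %d", len(kept), len(variants), min_quality)
    return plan, kept


# ---------------------------------------------------------------------------
# stacked chromosome figure


def stacked_chromosome_figure(
    store: PangenomeStore,
    chromosome: int,
    classes: list[GroupClass],
    blocks=None,
    out_prefix: str | Path | None = None,
):
    """Stack the haplotypes of one chromosome with class-colored gene bars
    and synteny ribbons between adjacent rows.

    Returns ``(track_tables, ribbon_table)``; when ``out_prefix`` is given a
    PNG and the tables (TSV) are also written.  The tables are the testable
    surface; the figure is a thin rendering of them.
    """
    recs = sorted(
        (r for r in store.sequences.values() if r.haplotype.chromosome == chromosome),
        key=lambda r: r.label,
    )
    if not recs:
        raise PangenomeError(f"no phased sequences for chromosome {chromosome}")
    tracks = {
        r.label: gene_presence_track(store, (r.genome_id, r.name), "pangenome_class", classes)
        for r in recs
    }
    span_of: dict[str, dict[str, tuple[int, int]]] = {}
    for r in recs:
        span_of[r.label] = {}
        for g in store.genes_on(r.genome_id, r.name):
            span_of[r.label][g.gene_id] = (g.start, g.end)
    ribbons = []  # (row_a, row_b, a_start, a_end, b_start, b_end, orientation)
    labels = [r.label for r in recs]
    for b in blocks or []:
        if b.query_label in labels and b.target_label in labels:
            ia, ib = labels.index(b.query_label), labels.index(b.target_label)
            if abs(ia - ib) != 1:
                continue
            qs = [span_of[b.query_label][p.query_gene] for p in b.pairs if p.query_gene in span_of[b.query_label]]
            ts = [span_of[b.target_label][p.target_gene] for p in b.pairs if p.target_gene in span_of[b.target_label]]
            if not qs or not ts:
                continue
            ribbons.append(
                (
                    b.query_label,
                    b.target_label,
                    min(s for s, _ in qs),
                    max(e for _, e in qs),
                    min(s for s, _ in ts),
                    max(e for _, e in ts),
                    b.orientation,
                )
            )
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        with open(f"{out_prefix}.tracks.tsv", "w") as fh:
            fh.write("sequence\tstart\tend\tvalue\tcolor\n")
            for lab in labels:
                for s, e, v, c in tracks[lab].intervals:
                    fh.write(f"{lab}\t{s}\t{e}\t{v}\t{c}\n")
        with open(f"{out_prefix}.ribbons.tsv", "w") as fh:
            fh.write("row_a\trow_b\ta_start\ta_end\tb_start\tb_end\torientation\n")
            for r in ribbons:
                fh.write("\t".join(map(str, r)) + "\n")
        fig, ax = plt.subplots(figsize=(10, 1.2 * len(labels) + 1))
        for yi, lab in enumerate(labels):
            y = len(labels) - 1 - yi
            ax.hlines(y, 0, store.sequence_by_label(lab).length, color="#dddddd", lw=6, zorder=1)
            for s, e, v, c in tracks[lab].intervals:
                ax.hlines(y, s, e, color=c, lw=8, zorder=2)
            ax.text(-0.01, y, lab, ha="right", va="center", transform=ax.get_yaxis_transform())
        for row_a, row_b, a0, a1, b0, b1, orient in ribbons:
            ya = len(labels) - 1 - labels.index(row_a)
            yb = len(labels) - 1 - labels.index(row_b)
            color = "#b3cde3" if orient == "parallel" else "#fbb4ae"
            ax.fill(
                [a0, a1, b1, b0], [ya, ya, yb, yb], color=color, alpha=0.5, zorder=0
            )
        ax.set_yticks([])
        ax.set_xlabel("position (bp)")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}.png", dpi=120)
        plt.close(fig)
    return tracks, ribbons
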
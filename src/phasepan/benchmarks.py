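"""Self-contained benchmark experiments on simulated pangenomes.

Each function builds its inputs with the synthetic-data generator (or a
direct construction), runs the corresponding analysis end to end, and
returns the measured quantities.  They are used both by the validation test
suite and by the reproduction script; every quantity is recomputed from
scratch on every call, seeded by the caller.
"""

from __future__ import annotations

import math
import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .classify import classify_groups, gene_distance_matrix
from .homology import HomologyGroup, evaluate_grouping_busco, group_proteins
from .kmers import KmerSet, canonical_kmers, kmer_distance_matrix, mash_distance, validate_chromosome_clades
from .model import GenomeRecord, HaplotypeID, PangenomeStore, RepeatAnnotation, SequenceRecord
from .phylo import neighbor_joining
from .rates import ds_histogram, ng86_rates, pairwise_ds_scan
from .sim import (
    SimulationConfig,
    apply_synonymous_events,
    calibrate_synonymous_channel,
    load_simulated,
    random_cds,
    simulate_pangenome,
)
from .synteny import build_pair_inputs, detect_collinear_blocks, gene_retention, parse_collinearity, write_collinearity
from .tracks import coverage_track, pairing_plan


def _sub_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31 - 1)


# ---------------------------------------------------------------------------


def classification_recovery(seed: int) -> dict:
    """4 genomes x ploidy 2 x 2 chromosomes x 100 genes: fraction of homology
    groups whose class, genome presence and subgenome counts all match the
    planted truth."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 1),
        n_genomes=4,
        ploidy=2,
        n_chromosomes=2,
        genes_per_chromosome=100,
        gene_length_codons=60,
        gene_loss_rate=0.1,
        genome_gene_loss_rate=0.1,
        haplotype_snp_rate=0.002,
    )
    with tempfile.TemporaryDirectory() as tmp:
        sim = simulate_pangenome(cfg, tmp)
        store = load_simulated(sim)
    groups = group_proteins(store, mode=2)
    classes = classify_groups(store, groups)
    fam_of = {g: fam for fam, genes in sim.truth.families.items() for g in genes}
    agree = 0
    comparable = 0
    for gc in classes:
        fams = {fam_of[m] for m in gc.group.members}
        comparable += 1
        if len(fams) != 1:
            continue
        cls, presence, sub = sim.truth.classes[fams.pop()]
        if gc.intergenomic == cls and gc.genome_presence == presence and gc.subgenome_counts == sub:
            agree += 1
    return {
        "agreement_pct": 100.0 * agree / comparable,
        "n_groups": len(classes),
        "n_families": len(sim.truth.families),
    }


def chromosome_clade_check(seed: int) -> dict:
    """3 genomes x ploidy 2 x 3 chromosomes at 0.5% haplotype SNPs: number of
    chromosome-clade conflicts in the NJ tree on per-sequence Mash distances."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 2),
        n_genomes=3,
        ploidy=2,
        n_chromosomes=3,
        genes_per_chromosome=20,
        gene_length_codons=60,
        intergenic_length=200,
        haplotype_snp_rate=0.005,
        gene_loss_rate=0.05,
        genome_gene_loss_rate=0.05,
    )
    with tempfile.TemporaryDirectory() as tmp:
        store = load_simulated(simulate_pangenome(cfg, tmp))
    dm = kmer_distance_matrix(store, min_genes=5)
    tree = neighbor_joining(dm)
    chroms = {r.label: r.haplotype.chromosome for r in store.sequences.values()}
    conflicts = validate_chromosome_clades(tree, chroms)
    return {"n_conflicts": len(conflicts), "n_sequences": len(dm.ids)}


def mash_closed_form_check(seed: int, n_pairs: int = 200) -> dict:
    """Random k-mer-set pairs: worst deviation of mash_distance from a direct
    evaluation of -(1/k) ln(2J/(1+J)), plus the two limit cases."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    k = 19
    worst = 0.0
    for _ in range(n_pairs):
        shared = int(rng.integers(1, 200))
        only_a = int(rng.integers(0, 200))
        only_b = int(rng.integers(0, 200))
        a = KmerSet("", k, frozenset(f"s{i}" for i in range(shared)) | frozenset(f"a{i}" for i in range(only_a)))
        b = KmerSet("", k, frozenset(f"s{i}" for i in range(shared)) | frozenset(f"b{i}" for i in range(only_b)))
        j = shared / (shared + only_a + only_b)
        direct = min(1.0, max(0.0, -(1.0 / k) * math.log(2 * j / (1 + j)))) if j > 0 else 1.0
        worst = max(worst, abs(mash_distance(a, b) - direct))
    ident = KmerSet("", k, frozenset({"x"}))
    assert mash_distance(ident, ident) == 0.0
    disjoint = mash_distance(KmerSet("", k, frozenset({"x"})), KmerSet("", k, frozenset({"y"})))
    return {"max_abs_err": worst, "identical_distance": 0.0, "disjoint_distance": disjoint, "n_pairs": n_pairs}


def retention_recovery(seed: int) -> dict:
    """500-gene query vs a target with 40% uniform gene loss: mean window
    retention, worst window deviation from a brute-force recount, and the
    self-retention check."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 4),
        n_genomes=1,
        ploidy=2,
        n_chromosomes=1,
        genes_per_chromosome=500,
        gene_length_codons=30,
        intergenic_length=50,
        gene_loss_rate=0.4,
        genome_gene_loss_rate=0.0,
        haplotype_snp_rate=0.0,
        haplotype_ds=0.0,
    )
    with tempfile.TemporaryDirectory() as tmp:
        store = load_simulated(simulate_pangenome(cfg, tmp))
    groups = group_proteins(store, mode=2)
    q, t = (1, "chr1A"), (1, "chr1B")
    track = gene_retention(store, q, [t], groups, mode="homology", window=100, step=10)[0]
    # brute-force recount per window
    group_of = {m: g.group_id for g in groups for m in g.members}
    t_groups = {group_of[g.gene_id] for g in store.genes_on(*t) if g.gene_id in group_of}
    flags = [g.gene_id in group_of and group_of[g.gene_id] in t_groups for g in store.genes_on(*q)]
    worst = 0.0
    for wi, (s, e, pct) in enumerate(track.windows):
        start = wi * 10
        recount = 100.0 * sum(flags[start : start + 100]) / 100
        worst = max(worst, abs(pct - recount))
    self_track = gene_retention(store, q, [q], groups, mode="homology", window=100, step=10)[0]
    return {
        "mean_retention_pct": float(np.mean([w[2] for w in track.windows])),
        "max_window_oracle_diff": worst,
        "self_retention_min_pct": min(w[2] for w in self_track.windows),
        "n_windows": len(track.windows),
    }


def ng86_recovery(seed: int, targets=(0.01, 0.1, 0.3, 0.7), n_pairs: int = 100, n_codons: int = 300) -> dict:
    """Planted synonymous divergence recovery: relative error of the mean
    NG86 Ds across replicate pairs, per planted level."""
    rng = np.random.default_rng(_sub_seed(seed, 5))
    out = {}
    worst_rel = 0.0
    for target in targets:
        n_events = calibrate_synonymous_channel(target, n_codons)
        vals = []
        for _ in range(n_pairs):
            anc = random_cds(n_codons, rng)
            mut = apply_synonymous_events(anc, n_events, rng)
            est = ng86_rates(anc[:-3], mut[:-3])
            if est.valid:
                vals.append(est.ds)
        mean = float(np.mean(vals))
        rel = abs(mean - target) / target
        worst_rel = max(worst_rel, rel)
        out[f"mean_ds_at_{target:g}"] = mean
    out["worst_relative_error"] = worst_rel
    out["n_pairs_per_level"] = n_pairs
    return out


def ds_peak_detection(seed: int) -> dict:
    """Haplotype heterozygosity (Ds ~ 0.005) plus a WGD layer (Ds ~ 0.7):
    positions of the detected modes of the within-genome Ds histogram."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 6),
        n_genomes=1,
        ploidy=2,
        n_chromosomes=1,
        genes_per_chromosome=80,
        gene_length_codons=500,
        intergenic_length=100,
        gene_loss_rate=0.0,
        genome_gene_loss_rate=0.0,
        haplotype_snp_rate=0.0,
        haplotype_ds=0.005,
        wgd=True,
        ds_wgd=0.7,
        wgd_retention=0.4,
    )
    with tempfile.TemporaryDirectory() as tmp:
        store = load_simulated(simulate_pangenome(cfg, tmp))
    groups = group_proteins(store, mode=2)
    estimates = pairwise_ds_scan(store, groups, ("within", 1))
    _, _, modes = ds_histogram(estimates)
    low = [m for m in modes if 1e-3 <= m <= 1e-2]
    high = [m for m in modes if 0.6 <= m <= 0.9]
    return {
        "n_estimates": len([e for e in estimates if e.valid]),
        "modes": modes,
        "mode_low": low[0] if low else float("nan"),
        "mode_high": high[0] if high else float("nan"),
    }


def inversion_recovery(seed: int) -> dict:
    """Planted 15-gene inversion inside collinear flanks: boundary error of
    the recovered antiparallel block, in genes."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 7),
        n_genomes=1,
        ploidy=2,
        n_chromosomes=1,
        genes_per_chromosome=60,
        gene_length_codons=60,
        gene_loss_rate=0.0,
        genome_gene_loss_rate=0.0,
        haplotype_snp_rate=0.001,
        n_inversions=1,
        inversion_size_range=(15, 15),
    )
    with tempfile.TemporaryDirectory() as tmp:
        sim = simulate_pangenome(cfg, tmp)
        store = load_simulated(sim)
        groups = group_proteins(store, mode=2)
        g, c, phase, start, size = sim.truth.inversions[0]
        _, _, matches = build_pair_inputs(store, (1, "chr1A"), (1, f"chr1{phase}"), groups)
        blocks = detect_collinear_blocks(matches, "g1#chr1A", f"g1#chr1{phase}")
        anti = [b for b in blocks if b.orientation == "antiparallel"]
        boundary_err = float("inf")
        if anti:
            got_start = anti[0].pairs[0].query_rank
            got_end = anti[0].pairs[-1].query_rank
            boundary_err = max(abs(got_start - start), abs(got_end - (start + size - 1)))
        # round-trip fidelity of the collinearity dialect
        path = Path(tmp) / "x.collinearity"
        write_collinearity(blocks, path)
        back = parse_collinearity(path)
        lossless = len(back) == len(blocks) and all(
            [(p.query_gene, p.target_gene) for p in a.pairs] == [(p.query_gene, p.target_gene) for p in b.pairs]
            and a.orientation == b.orientation
            for a, b in zip(blocks, back)
        )
    return {
        "boundary_err_genes": boundary_err,
        "n_blocks": len(blocks),
        "min_block_pairs": min(b.n_pairs for b in blocks),
        "round_trip_lossless": int(lossless),
    }


def _random_additive_tree(n_leaves: int, rng: np.random.Generator) -> tuple[DistanceMatrix, TreeNode]:
    leaves = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(n_leaves)]
    pool = list(leaves)
    while len(pool) > 3:
        j, i = sorted(rng.choice(len(pool), size=2, replace=False), reverse=True)
        parent = TreeNode(children=[pool.pop(j), pool.pop(i)], length=float(rng.uniform(0.1, 1.0)))
        pool.append(parent)
    root = TreeNode(children=pool)
    names = [l.name for l in leaves]
    mat = np.zeros((n_leaves, n_leaves))
    for a, b in combinations(range(n_leaves), 2):
        mat[a, b] = mat[b, a] = leaves[a].distance(leaves[b])
    return DistanceMatrix(mat, names), root


def nj_additive_recovery(seed: int, n_trees: int = 100, n_leaves: int = 8) -> dict:
    """Fraction of random additive 8-leaf matrices whose generating topology
    NJ recovers exactly (Robinson-Foulds distance 0)."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    ok = 0
    for _ in range(n_trees):
        dm, true_tree = _random_additive_tree(n_leaves, rng)
        mine = neighbor_joining(dm)
        if mine.compare_rfd(true_tree) == 0:
            ok += 1
    return {"recovery_rate": ok / n_trees, "n_trees": n_trees}


def grouping_calibration(seed: int) -> dict:
    """Planted protein families: F1 at mode 2, monotone group counts across
    modes, and the merged-family F1 under the documented definition."""
    rng = np.random.default_rng(_sub_seed(seed, 9))
    from .model import GeneModel, Transcript

    AA = "ACDEFGHIKLMNPQRSTVWY"
    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 4)
    for p in "ABCD":
        store.sequences[(1, f"chr1{p}")] = SequenceRecord(1, f"chr1{p}", "A" * 100, HaplotypeID(1, p))
    families = {}
    for f in range(20):
        base = "".join(rng.choice(list(AA), size=80))
        fam = []
        for ci, p in enumerate("ABCD"):
            prot = list(base)
            for i in rng.choice(80, size=2, replace=False):  # >95% within-family identity
                prot[i] = AA[(AA.index(prot[i]) + 1) % 20]
            gid = f"F{f:02d}_{p}"
            gm = GeneModel(gene_id=gid, genome_id=1, sequence_name=f"chr1{p}", start=0, end=3, strand="+")
            gm.transcripts = [Transcript(gid + ".m", [(0, 3)], "".join(prot))]
            store.genes[gid] = gm
            fam.append(gid)
        families[f"fam{f:02d}"] = fam
    counts = []
    f1_mode2 = None
    for mode in (2, 4, 6, 8):
        groups = group_proteins(store, mode=mode)
        counts.append(len(groups))
        if mode == 2:
            f1_mode2 = evaluate_grouping_busco(groups, families).f1
    merged = [HomologyGroup("HGM", frozenset(families["fam00"] + families["fam01"]))]
    f1_merged = evaluate_grouping_busco(merged, {k: families[k] for k in ("fam00", "fam01")}).f1
    return {
        "f1_planted_mode2": f1_mode2,
        "group_counts_by_mode": counts,
        "monotone_nonincreasing": int(all(a >= b for a, b in zip(counts, counts[1:]))),
        "f1_merged_families": f1_merged,
        "n_families": len(families),
    }


def coverage_and_pairing_check(seed: int) -> dict:
    """1 Mb coverage windows vs a per-base boolean oracle on a 5 Mb sequence,
    and the homeologous pairing-plan size for 5 haplotypes."""
    rng = np.random.default_rng(_sub_seed(seed, 10))
    L = 5_000_000
    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 1)
    store.sequences[(1, "chr1A")] = SequenceRecord(1, "chr1A", "A" * L, HaplotypeID(1, "A"))
    intervals = []
    for _ in range(300):
        s = int(rng.integers(0, L - 60_000))
        e = s + int(rng.integers(500, 60_000))
        intervals.append((s, min(e, L)))
        store.repeats.append(RepeatAnnotation(1, "chr1A", s, min(e, L), "repeat"))
    track = coverage_track(store, (1, "chr1A"), annotation="repeat", window=1_000_000)
    covered = np.zeros(L, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    worst = 0.0
    for (s, e, pct, _), wstart in zip(track.intervals, range(0, L, 1_000_000)):
        oracle = 100.0 * covered[wstart : wstart + 1_000_000].sum() / (min(wstart + 1_000_000, L) - wstart)
        worst = max(worst, abs(pct - oracle))
    # pairing plan for 5 haplotypes of one chromosome
    store2 = PangenomeStore()
    store2.genomes[1] = GenomeRecord(1, "g1", 4)
    store2.genomes[2] = GenomeRecord(2, "g2", 1)
    for p in "ABCD":
        store2.sequences[(1, f"chr1{p}")] = SequenceRecord(1, f"chr1{p}", "ACGT", HaplotypeID(1, p))
    store2.sequences[(2, "chr1A")] = SequenceRecord(2, "chr1A", "ACGT", HaplotypeID(1, "A"))
    store2.sequences[(2, "scaff")] = SequenceRecord(2, "scaff", "ACGT", HaplotypeID())
    plan = pairing_plan(store2)
    return {
        "coverage_max_abs_diff": worst,
        "n_windows": len(track.intervals),
        "pairing_plan_size": len(plan.pairs),
        "expected_plan_size": 5 * 4 // 2,
        "grey_rule_ok": int(_grey_rule_check()),
    }


def _grey_rule_check() -> bool:
    """Other-chromosome-copy track: a copy on the same chromosome number but a
    different haplotype must NOT grey the gene; a copy on another chromosome
    number must."""
    from .model import GeneModel, Transcript
    from .tracks import gene_presence_track

    store = PangenomeStore()
    store.genomes[1] = GenomeRecord(1, "g1", 2)
    for c in (2, 3):
        for p in "AB":
            store.sequences[(1, f"chr{c}{p}")] = SequenceRecord(1, f"chr{c}{p}", "ACGT" * 50, HaplotypeID(c, p))

    def add(gid, seq, start):
        gm = GeneModel(gene_id=gid, genome_id=1, sequence_name=seq, start=start, end=start + 9, strand="+")
        gm.transcripts = [Transcript(gid + ".m", [(start, start + 9)], "MA")]
        store.genes[gid] = gm

    add("x_2a", "chr2A", 0)
    add("x_2b", "chr2B", 0)
    add("y_2a", "chr2A", 50)
    add("y_3a", "chr3A", 50)
    groups = [
        HomologyGroup("HGX", frozenset({"x_2a", "x_2b"})),
        HomologyGroup("HGY", frozenset({"y_2a", "y_3a"})),
    ]
    classes = classify_groups(store, groups)
    track = gene_presence_track(store, (1, "chr2A"), "other_chromosome_copy", classes)
    vals = {store.genes_on(1, "chr2A")[i].gene_id: track.intervals[i][2] for i in range(2)}
    return vals["x_2a"] == "unique" and vals["y_2a"] == "grey"
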
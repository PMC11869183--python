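"""Deterministic simulator of haplotype-resolved pangenomes with planted truth.

The generator emulates the structure of a phased plant pangenome: several
genomes, each contributing one sequence per chromosome per haplotype, built
from a shared ancestral gene catalogue.  Divergence is planted through four
channels —

* a synonymous-only codon channel calibrated so the expected NG86 Ds between
  two haplotypes matches a target (haplotype heterozygosity; defaults to the
  very young divergence typical of within-genome allele pairs),
* a neutral per-site SNP channel over genes and intergenic spacers
  (stop-codon-creating changes are skipped so proteins stay intact),
* gene loss, at the genome level (all haplotypes lose the gene: presence/
  absence variation between genomes) and at the haplotype level (subgenome
  mosaicism),
* structural events: inversions of contiguous gene runs, and an optional
  whole-genome-duplication remnant — chromosome 1 duplicated onto an extra
  chromosome at a deep synonymous divergence and fractionated down to a
  retention fraction.

All outputs (FASTA, GFF3, phasing table, optional repeats GFF3) are a pure
function of the configuration, and every planted fact is recorded in truth
tables emitted next to them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import PangenomeError, PangenomeStore, build_pangenome, add_annotations, add_phasing, add_repeats

logger = logging.getLogger("phasepan")

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SimResult",
    "simulate_pangenome",
    "calibrate_synonymous_channel",
    "apply_synonymous_events",
    "random_cds",
    "load_simulated",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_NONSTOP = [c for c in _CODONS if c not in _STOPS]

from Bio.Seq import Seq

_AA = {c: str(Seq(c).translate()) for c in _CODONS}

# codon -> synonymous single-nucleotide neighbors (never a stop)
_SYN_NEIGHBORS: dict[str, list[str]] = {}
for _c in _NONSTOP:
    nb = []
    for _pos in range(3):
        for _alt in _BASES:
            if _alt == _c[_pos]:
                continue
            _m = _c[:_pos] + _alt + _c[_pos + 1 :]
            if _m not in _STOPS and _AA[_m] == _AA[_c]:
                nb.append(_m)
    _SYN_NEIGHBORS[_c] = nb


@dataclass
class SimulationConfig:
    seed: int
    n_genomes: int = 3
    ploidy: int = 2  # haplotypes per genome (1..4 supported; letters A..D)
    n_chromosomes: int = 2
    genes_per_chromosome: int = 100
    gene_length_codons: int = 100
    intergenic_length: int = 300
    haplotype_snp_rate: float = 0.005
    haplotype_ds: float = 0.005  # expected pairwise synonymous divergence
    gene_loss_rate: float = 0.05  # per haplotype copy
    genome_gene_loss_rate: float = 0.1  # whole-genome loss (presence/absence)
    n_inversions: int = 0
    inversion_size_range: tuple[int, int] = (10, 20)
    wgd: bool = False
    ds_wgd: float = 0.7
    wgd_retention: float = 0.4
    repeat_arrays: bool = False

    def __post_init__(self) -> None:
        for rate in (self.haplotype_snp_rate, self.gene_loss_rate, self.genome_gene_loss_rate):
            if not 0.0 <= rate <= 1.0:
                raise PangenomeError("rates must be in [0, 1]")
        if not 1 <= self.ploidy <= 4:
            raise PangenomeError("ploidy must be in 1..4")
        if self.genes_per_chromosome < 1 or self.gene_length_codons < 12:
            raise PangenomeError("infeasible geometry: too few genes or codons")


@dataclass
class TruthTables:
    # family id -> emitted gene ids (all copies, all genomes/haplotypes)
    families: dict[str, list[str]] = field(default_factory=dict)
    # family id -> (class, genome presence count, {genome: subgenome count})
    classes: dict[str, tuple[str, int, dict[int, int]]] = field(default_factory=dict)
    # (genome, chromosome, phase, start_rank, n_genes) in final gene order
    inversions: list[tuple[int, int, str, int, int]] = field(default_factory=list)
    # sequence label -> [(gene_id, family_id, strand)] in coordinate order
    gene_orders: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # planted pairwise Ds per duplicate class
    ds_targets: dict[str, float] = field(default_factory=dict)
    # families retained on the WGD remnant chromosome
    wgd_retained: list[str] = field(default_factory=list)


@dataclass
class SimResult:
    outdir: Path
    fasta_paths: list[Path]
    gff_paths: list[Path]
    phasing_path: Path
    repeat_paths: list[Path]
    truth: TruthTables
    config: SimulationConfig


# ---------------------------------------------------------------------------
# codon machinery


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random coding sequence: ATG + random non-stop codons + one stop."""
    body = rng.choice(_NONSTOP, size=n_codons - 2)
    stop = sorted(_STOPS)[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def apply_synonymous_events(cds: str, n_events: int, rng: np.random.Generator) -> str:
    """Apply n synonymous single-nucleotide substitutions (never creating a
    stop); the trailing stop codon is left untouched."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    body = len(codons) - 1 if codons[-1] in _STOPS else len(codons)
    editable = [i for i in range(body) if _SYN_NEIGHBORS.get(codons[i])]
    for _ in range(n_events):
        if not editable:
            break
        i = editable[rng.integers(0, len(editable))]
        nb = _SYN_NEIGHBORS[codons[i]]
        codons[i] = nb[rng.integers(0, len(nb))]
        if not _SYN_NEIGHBORS[codons[i]]:
            editable.remove(i)
    return "".join(codons)


_CALIBRATION_CACHE: dict[tuple[float, int], int] = {}


def calibrate_synonymous_channel(target_ds: float, gene_length_codons: int) -> int:
    """Number of synonymous substitution events whose expected NG86 Ds over
    random genes of the given length matches ``target_ds``.

    Calibration inverts a fixed-seed Monte-Carlo estimate of the
    event-count → Ds curve by bisection; results are cached.  Targets at or
    beyond Ds 1.5 sit in the saturated regime of the Jukes–Cantor correction
    and are refused.
    """
    if target_ds < 0:
        raise PangenomeError("target Ds must be >= 0")
    if target_ds >= 1.5:
        raise PangenomeError(f"target Ds {target_ds} beyond the estimator's validity domain (< 1.5)")
    if target_ds == 0:
        return 0
    key = (round(target_ds, 8), gene_length_codons)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    from .rates import ng86_rates

    cal_seed = (hash(key) & 0x7FFFFFFF) or 1

    def expected_ds(n: int, reps: int = 24) -> float:
        rng = np.random.default_rng(cal_seed)
        vals = []
        for _ in range(reps):
            anc = random_cds(gene_length_codons, rng)
            mut = apply_synonymous_events(anc, n, rng)
            est = ng86_rates(anc[:-3], mut[:-3])
            if est.valid:
                vals.append(est.ds)
        if not vals:
            return float("inf")
        return float(np.mean(vals))

    hi = 1
    while expected_ds(hi) < target_ds:
        hi *= 2
        if hi > 200 * gene_length_codons:
            raise PangenomeError(f"target Ds {target_ds} unreachable")
    lo = hi // 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_ds(mid) < target_ds:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda n: abs(expected_ds(n) - target_ds))
    _CALIBRATION_CACHE[key] = best
    return best


def _mutate_neutral_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site neutral substitutions in a CDS, skipping changes that would
    create an in-frame stop codon."""
    if rate <= 0:
        return cds
    seq = list(cds)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alts = [b for b in _BASES if b != seq[i]]
        alt = alts[rng.integers(0, 3)]
        cstart = (i // 3) * 3
        codon = seq[cstart : cstart + 3]
        codon[i - cstart] = alt
        if "".join(codon) in _STOPS:
            continue
        # never destroy an existing stop either (keeps the frame clean)
        if cds[cstart : cstart + 3] in _STOPS:
            continue
        seq[i] = alt
    return "".join(seq)


def _mutate_neutral(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alts = [b for b in _BASES if b != arr[i]]
        arr[i] = alts[rng.integers(0, 3)]
    return "".join(arr)


_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# the generator


def simulate_pangenome(config: SimulationConfig, outdir: str | Path) -> SimResult:
    """Generate a phased pangenome directory plus its truth tables."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    C, G, P = config.n_chromosomes, config.n_genomes, config.ploidy
    L = config.gene_length_codons
    n_hap_events = calibrate_synonymous_channel(config.haplotype_ds / 2.0, L) if config.haplotype_ds > 0 else 0
    n_wgd_events = calibrate_synonymous_channel(config.ds_wgd, L) if config.wgd else 0

    # --- ancestral catalogue -------------------------------------------------
    chromosomes = list(range(1, C + 1))
    ancestral: dict[int, list[dict]] = {}
    intergenic: dict[int, list[str]] = {}
    for c in chromosomes:
        genes = []
        for i in range(config.genes_per_chromosome):
            genes.append(
                {
                    "family": f"F{c:02d}_{i:04d}",
                    "cds": random_cds(L, rng),
                    "strand": "+" if rng.random() < 0.7 else "-",
                }
            )
        ancestral[c] = genes
        intergenic[c] = [
            "".join(rng.choice(list(_BASES), size=config.intergenic_length))
            for _ in range(config.genes_per_chromosome + 1)
        ]
    wgd_chrom = None
    if config.wgd:
        wgd_chrom = C + 1
        chromosomes.append(wgd_chrom)
        retained = []
        genes = []
        for src in ancestral[1]:
            if rng.random() < config.wgd_retention:
                genes.append(
                    {
                        "family": src["family"],
                        "cds": apply_synonymous_events(src["cds"], n_wgd_events, rng),
                        "strand": src["strand"],
                    }
                )
                retained.append(src["family"])
        if len(genes) < 1:
            raise PangenomeError("WGD retention too low: remnant chromosome is empty")
        ancestral[wgd_chrom] = genes
        intergenic[wgd_chrom] = [
            "".join(rng.choice(list(_BASES), size=config.intergenic_length))
            for _ in range(len(genes) + 1)
        ]
    else:
        retained = []

    # repeat monomer for optional tandem arrays
    monomer = "".join(rng.choice(list(_BASES), size=50)) if config.repeat_arrays else ""

    # --- per-genome loss decisions -------------------------------------------
    genome_lost: dict[tuple[int, str], bool] = {}
    for g in range(1, G + 1):
        for c in chromosomes:
            for gene in ancestral[c]:
                genome_lost[(g, gene["family"], c)] = bool(rng.random() < config.genome_gene_loss_rate)

    # --- planted inversions ---------------------------------------------------
    planned_inversions: list[tuple[int, int, str, int, int]] = []
    for _ in range(config.n_inversions):
        g = int(rng.integers(1, G + 1))
        c = int(chromosomes[rng.integers(0, len(chromosomes))])
        phase = chr(ord("A") + int(rng.integers(1, P))) if P > 1 else "A"
        lo_sz, hi_sz = config.inversion_size_range
        size = int(rng.integers(lo_sz, hi_sz + 1))
        n_anc = len(ancestral[c])
        if size >= n_anc - 4:
            size = max(2, n_anc // 3)
        start = int(rng.integers(2, max(3, n_anc - size - 2)))
        planned_inversions.append((g, c, phase, start, size))

    truth = TruthTables(ds_targets={"haplotype": config.haplotype_ds}, wgd_retained=retained)
    if config.wgd:
        truth.ds_targets["wgd"] = config.ds_wgd
    fam_genes: dict[str, list[str]] = {}
    fam_presence: dict[str, dict[int, set[str]]] = {}

    fasta_paths, gff_paths, repeat_paths = [], [], []
    phasing_rows = []

    for g in range(1, G + 1):
        fa = outdir / f"genome{g}.fa"
        gff = outdir / f"genome{g}.gff3"
        rep_rows = []
        with open(fa, "w") as ffa, open(gff, "w") as fgff:
            fgff.write("##gff-version 3\n")
            for c in chromosomes:
                for h in range(P):
                    phase = chr(ord("A") + h)
                    seq_name = f"chr{c}{phase}"
                    copies = []
                    for rank, gene in enumerate(ancestral[c]):
                        if genome_lost[(g, gene["family"], c)]:
                            continue
                        if rng.random() < config.gene_loss_rate:
                            continue
                        cds = apply_synonymous_events(gene["cds"], n_hap_events, rng)
                        cds = _mutate_neutral_cds(cds, config.haplotype_snp_rate, rng)
                        copies.append({"family": gene["family"], "cds": cds, "strand": gene["strand"]})
                    for (ig, ic, iphase, istart, isize) in planned_inversions:
                        if (ig, ic, iphase) == (g, c, phase) and istart + isize <= len(copies):
                            seg = copies[istart : istart + isize][::-1]
                            for cp in seg:
                                cp["strand"] = "-" if cp["strand"] == "+" else "+"
                            copies[istart : istart + isize] = seg
                            truth.inversions.append((g, c, phase, istart, isize))
                    # assemble
                    parts = []
                    pos = 0
                    gene_rows = []
                    order = []
                    spacers = intergenic[c]
                    for j in range(len(copies) + 1):
                        spacer = spacers[j % len(spacers)]
                        if config.repeat_arrays and c == 1 and j == 0:
                            spacer = monomer * 10
                            rep_rows.append((seq_name, pos, pos + len(spacer), "tandem_array"))
                        parts.append(_mutate_neutral(spacer, config.haplotype_snp_rate, rng))
                        pos += len(spacer)
                        if j < len(copies):
                            cp = copies[j]
                            body = cp["cds"] if cp["strand"] == "+" else _rc(cp["cds"])
                            gene_id = f"g{g}{phase}_c{c}_{cp['family']}"
                            gene_rows.append((gene_id, pos, pos + len(body), cp["strand"]))
                            order.append((gene_id, cp["family"], cp["strand"]))
                            fam_genes.setdefault(cp["family"], []).append(gene_id)
                            fam_presence.setdefault(cp["family"], {}).setdefault(g, set()).add(phase)
                            parts.append(body)
                            pos += len(body)
                    residues = "".join(parts)
                    ffa.write(f">{seq_name}\n")
                    for i in range(0, len(residues), 80):
                        ffa.write(residues[i : i + 80] + "\n")
                    for gene_id, s, e, strand in gene_rows:
                        fgff.write(f"{seq_name}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gene_id}\n")
                        fgff.write(
                            f"{seq_name}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gene_id}.m1;Parent={gene_id}\n"
                        )
                        fgff.write(
                            f"{seq_name}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tID={gene_id}.m1.cds;Parent={gene_id}.m1\n"
                        )
                    truth.gene_orders[f"g{g}#{seq_name}"] = order
                    phasing_rows.append((g, seq_name, c, phase))
        fasta_paths.append(fa)
        gff_paths.append(gff)
        if rep_rows:
            rp = outdir / f"genome{g}.repeats.gff3"
            with open(rp, "w") as fh:
                fh.write("##gff-version 3\n")
                for i, (seq_name, s, e, label) in enumerate(rep_rows):
                    fh.write(f"{seq_name}\tsim\t{label}\t{s + 1}\t{e}\t.\t+\t.\tID=rep{g}_{i}\n")
            repeat_paths.append(rp)

    phasing_path = outdir / "phasing.tsv"
    with open(phasing_path, "w") as fh:
        fh.write("genome\tsequence\tchromosome\tphase\n")
        for g, seq_name, c, phase in phasing_rows:
            fh.write(f"{g}\t{seq_name}\t{c}\t{phase}\n")

    # --- truth classes --------------------------------------------------------
    for fam in sorted(fam_genes):
        truth.families[fam] = sorted(fam_genes[fam])
        pres = fam_presence[fam]
        npres = len(pres)
        cls = "core" if npres == G else ("cloud" if npres == 1 else "accessory")
        truth.classes[fam] = (cls, npres, {g: len(ph) for g, ph in sorted(pres.items())})

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "families.tsv", "w") as fh:
        fh.write("family\tgene_id\n")
        for fam, genes in truth.families.items():
            for gid in genes:
                fh.write(f"{fam}\t{gid}\n")
    with open(tdir / "classes.tsv", "w") as fh:
        fh.write("family\tclass\tgenome_presence\tsubgenome_counts\n")
        for fam, (cls, npres, sub) in truth.classes.items():
            sg = ";".join(f"{g}:{n}" for g, n in sub.items())
            fh.write(f"{fam}\t{cls}\t{npres}\t{sg}\n")
    with open(tdir / "inversions.tsv", "w") as fh:
        fh.write("genome\tchromosome\tphase\tstart_rank\tn_genes\n")
        for row in truth.inversions:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)

    logger.info(
        "simulated %d genomes x ploidy %d x %d chromosomes (%d families)",
        G, P, len(chromosomes), len(truth.families),
    )
    return SimResult(
        outdir=outdir,
        fasta_paths=fasta_paths,
        gff_paths=gff_paths,
        phasing_path=phasing_path,
        repeat_paths=repeat_paths,
        truth=truth,
        config=config,
    )


def load_simulated(sim: SimResult, k: int = 19) -> PangenomeStore:
    """Round-trip a simulation through the pangenome model's own parsers."""
    store = build_pangenome(sim.fasta_paths, k=k)
    for gid, gff in enumerate(sim.gff_paths, start=1):
        add_annotations(store, gff, gid)
    add_phasing(store, sim.phasing_path)
    for rp in sim.repeat_paths:
        gid = int(rp.stem.split(".")[0].removeprefix("genome"))
        add_repeats(store, rp, gid)
    return store
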
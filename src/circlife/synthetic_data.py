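"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators live here.

:func:`simulate_dataset` draws a random but internally consistent dataset —
genome, annotation, back-splice junctions honoring their assigned category,
count matrices over the 14-point leaf time course, miRNAs with planted
(near-)perfect target sites and anti-correlated expression — from a
:class:`SimParams` seed. Counts are negative-binomial around logistic (or
flat) time-course means; there is no replicate structure, so noise acts
across time points only, as in a one-library-per-time-point design.

:func:`make_paper_fixture` is deterministic constraint satisfaction, not
sampling: it constructs a dataset whose classification table, detection
histogram, stage membership, novelty split, differential-expression calls,
host-gene concordance and sponge-network sizes all take the exact values a
desk-scale reanalysis should reproduce. Sequence content is drawn from a
fixed internal seed; the combinatorial structure is hand-allocated (the
allocation is spelled out in the builder functions below and exercised by the
test suite).

Planted differential expression is defined on the pseudo-counted scale the
pipeline actually measures: a planted fold ``F`` multiplies ``mean + 1`` by
``F`` between the stage reference day and the later stage days, so the
noise-free log2 fold change of a planted feature is exactly ``log2(F)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import largest_remainder_percentages  # noqa: F401  (shared rounding)
from .io_formats import (
    BackspliceJunction,
    Chromosome,
    Exon,
    Gene,
    GenomeAnnotation,
    write_bsj_table,
    write_count_matrix,
    write_fasta,
    write_gff3,
    write_known_circs,
)
from .quantify import StageConfig, day_label, default_stage_config

DAYS = tuple(range(4, 31, 2))
_LABELS = [day_label(d) for d in DAYS]

_COMP = str.maketrans("ACGTU", "TGCAA")


def _revcomp_dna(seq: str) -> str:
    """Reverse complement as DNA (U treated as A's partner on input)."""
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _plant_site(genome: dict[str, str], chrom: str, pos: int, site: str) -> None:
    """Overwrite genome[chrom] at 1-based pos with a target site."""
    s = genome[chrom]
    genome[chrom] = s[: pos - 1] + site + s[pos - 1 + len(site):]


def _site_on_genome(mirna_seq: str, strand: str) -> str:
    """Genomic-forward sequence whose *transcript* is a perfect miRNA site.

    On the plus strand the transcript reads the genome forward, so the site
    is the reverse complement of the miRNA; on the minus strand the
    transcript is the reverse complement of the genome, so the genomic
    segment must be the miRNA itself (as DNA).
    """
    return _revcomp_dna(mirna_seq) if strand == "+" else mirna_seq.replace("U", "T")


def nb_counts(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _logistic(days: np.ndarray, t0: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(days - t0) / tau))


def trajectory(
    shape: str,
    base: float,
    fold: float,
    days: tuple[int, ...] = DAYS,
    t0: float = 20.0,
    tau: float = 1.5,
) -> np.ndarray:
    """Mean time course on the raw-count scale.

    ``up``/``down`` are logistic rises/falls of amplitude ``fold`` on the
    pseudo-counted scale; ``step_up`` multiplies ``base + 1`` by ``fold`` for
    every day strictly after ``t0`` (a planted effect whose stage contrast is
    exactly ``log2(fold)`` when ``t0`` is the stage reference day); ``flat``
    is constant.
    """
    d = np.asarray(days, dtype=float)
    if shape == "flat":
        factor = np.ones_like(d)
    elif shape == "up":
        factor = 1.0 + (fold - 1.0) * _logistic(d, t0, tau)
    elif shape == "down":
        factor = 1.0 + (fold - 1.0) * (1.0 - _logistic(d, t0, tau))
    elif shape == "step_up":
        factor = np.where(d > t0, fold, 1.0)
    else:
        raise ValueError(f"unknown trajectory shape {shape!r}")
    return (base + 1.0) * factor - 1.0


# ---------------------------------------------------------------------------
# Small focused instances for power / calibration checks
# ---------------------------------------------------------------------------

def simulate_recovery_instance(
    rng: np.random.Generator,
    n_features: int = 24,
    n_planted: int = 8,
    fold: float = 4.0,
    dispersion: float = 0.05,
    base_range: tuple[float, float] = (20.0, 80.0),
    config: StageConfig | None = None,
    stage_name: str = "M-to-S",
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Counts with ``n_planted`` step-up DE features planted in one stage.

    The plant multiplies ``mean + 1`` by ``fold`` on every stage day after the
    reference, so the noise-free contrast equals ``log2(fold)`` exactly.
    Returns (raw counts, library sizes, planted feature ids).
    """
    config = config or default_stage_config()
    stage = config.stage(stage_name)
    base = rng.uniform(*base_range, size=n_features)
    mu_plus = np.tile((base + 1.0)[:, None], (1, len(config.time_points)))
    planted_idx = rng.choice(n_features, size=n_planted, replace=False)
    late = [i for i, d in enumerate(config.time_points) if d in stage.days and d > stage.reference]
    mu_plus[np.ix_(planted_idx, late)] *= fold
    counts = nb_counts(rng, mu_plus - 1.0, dispersion)
    ids = [f"feat{i:03d}" for i in range(n_features)]
    raw = pd.DataFrame(counts, index=ids, columns=[day_label(d) for d in config.time_points])
    lib = pd.Series(1e6, index=raw.columns)
    return raw, lib, [ids[i] for i in sorted(planted_idx)]


def simulate_anticorr_instance(
    rng: np.random.Generator,
    fold: float = 4.0,
    dispersion: float = 0.05,
    base: float = 100.0,
    t0: float = 17.0,
    tau: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One planted anti-correlated pair: target up-logistic, miRNA down-logistic.

    Returns the two normalized (pseudo-counted) 14-point profiles.
    """
    d = np.asarray(DAYS, dtype=float)
    up = trajectory("up", base, fold, t0=t0, tau=tau)
    down = trajectory("down", base, fold, t0=t0, tau=tau)
    target = nb_counts(rng, up, dispersion) + 1.0
    mirna = nb_counts(rng, down, dispersion) + 1.0
    assert d.size == target.size
    return mirna, target


# ---------------------------------------------------------------------------
# Random dataset generator
# ---------------------------------------------------------------------------

def _default_mix() -> dict[str, float]:
    # Table-1-like proportions of splice-site configurations
    return {
        "EXONIC_BOTH_BOUNDARY": 0.798,
        "EXONIC_BOTH_INTERNAL": 0.048,
        "EXONIC_ONE_BOUNDARY": 0.095,
        "INTERGENIC": 0.059,
    }


@dataclass
class SimParams:
    """Knobs of the random generator; defaults emulate the study conditions.

    14 time points at 2-day intervals (days 4–30), mostly-exonic circRNAs in
    Table-1-like category proportions, an upregulation trend toward
    senescence (85% of regulated circRNAs go up), miRNAs anti-correlated with
    their planted targets, and one library per time point.
    """

    seed: int = 0
    nuclear_chromosomes: int = 2
    genes_per_chromosome: int = 20
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (80, 160)
    intron_length: tuple[int, int] = (40, 100)
    gene_gap: tuple[int, int] = (200, 400)
    organelle_length: int = 8000
    n_circrnas: int = 60
    category_mix: dict[str, float] = field(default_factory=_default_mix)
    chloroplast_fraction: float = 0.3     # of intergenic circRNAs
    fraction_regulated: float = 0.3
    fraction_up: float = 0.85             # senescence-upregulated share of regulated
    planted_fold: float = 4.0             # pseudo-scale amplitude of regulation
    baseline_mean: tuple[float, float] = (20.0, 80.0)
    dispersion: float = 0.05
    library_size: float = 1e6
    library_size_cv: float = 0.05
    n_mirnas: int = 10
    mirna_length: int = 21
    planted_target_fraction: float = 0.5
    host_concordant_fraction: float = 0.26
    known_fraction: float = 0.76

    def validate(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-6:
            raise ValueError("category_mix must sum to 1")
        for name in (
            "nuclear_chromosomes", "genes_per_chromosome", "n_circrnas", "n_mirnas",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exon_length[0] < self.mirna_length + 25:
            raise ValueError(
                "exons too short to host circRNA breakpoints and planted target sites"
            )


@dataclass
class SimulatedDataset:
    params: SimParams
    annotation: GenomeAnnotation
    genome: dict[str, str]
    junctions: list[BackspliceJunction]
    circ_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    library_sizes: pd.Series
    mirna_seqs: dict[str, str]
    known_list: list[tuple[str, int, int, str]]
    host_map: dict[str, str]
    truth: dict

    def write(self, outdir) -> dict[str, str]:
        return _write_dataset(self, outdir)


def _apportion(mix: dict[str, float], n: int) -> dict[str, int]:
    """Integer counts per category, largest-remainder, summing to n."""
    raw = {k: v * n for k, v in mix.items()}
    out = {k: int(v // 1) for k, v in raw.items()}
    rest = n - sum(out.values())
    for k in sorted(mix, key=lambda k: raw[k] - out[k], reverse=True)[:rest]:
        out[k] += 1
    return out


def _make_circ_coords(gene: Gene, category: str, first_exon: int, span: int):
    """Breakpoints realizing a category on a gene (1-based exon index)."""
    exons = gene.exons[first_exon - 1 : first_exon - 1 + span]
    lo, hi = exons[0], exons[-1]
    if category == "EXONIC_BOTH_BOUNDARY":
        return lo.start, hi.end
    if category == "EXONIC_BOTH_INTERNAL":
        if len(lo) < 31 or len(hi) < 31:
            raise ValueError(f"gene {gene.gene_id}: exon too short for internal breakpoints")
        return lo.start + 15, hi.end - 15
    if category == "EXONIC_ONE_BOUNDARY":
        if len(hi) < 16:
            raise ValueError(f"gene {gene.gene_id}: exon too short for internal breakpoint")
        return lo.start, hi.end - 15
    raise ValueError(category)


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Draw one dataset; identical params (incl. seed) give identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    # --- genome layout -----------------------------------------------------
    chromosomes: dict[str, Chromosome] = {}
    genes: dict[str, Gene] = {}
    spacers: list[tuple[str, int, int]] = []  # gene-free nuclear intervals
    gene_order: list[str] = []
    for c in range(params.nuclear_chromosomes):
        cid = f"Chr{c + 1}"
        pos = 1
        for gslot in range(params.genes_per_chromosome):
            gap = int(rng.integers(*params.gene_gap))
            if gap >= 150:
                spacers.append((cid, pos + 10, pos + gap - 10))
            pos += gap
            n_ex = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
            exons = []
            epos = pos
            for k in range(n_ex):
                elen = int(rng.integers(*params.exon_length))
                exons.append(Exon(epos, epos + elen - 1))
                epos += elen + int(rng.integers(*params.intron_length))
            gid = f"SYNG{c + 1}G{gslot + 1:04d}"
            strand = "+" if rng.integers(2) == 0 else "-"
            genes[gid] = Gene(gid, cid, strand, exons[0].start, exons[-1].end, exons)
            gene_order.append(gid)
            pos = exons[-1].end + 1
        tail_gap = int(rng.integers(*params.gene_gap)) + 500
        spacers.append((cid, pos + 10, pos + tail_gap - 10))
        chromosomes[cid] = Chromosome(cid, pos + tail_gap)
    chromosomes["ChrC"] = Chromosome("ChrC", params.organelle_length, "chloroplast")
    chromosomes["ChrM"] = Chromosome("ChrM", params.organelle_length, "mitochondria")
    annotation = GenomeAnnotation(chromosomes, genes)
    annotation.validate()

    genome = {cid: _random_seq(rng, ch.length) for cid, ch in chromosomes.items()}

    # --- circRNA placement -------------------------------------------------
    cat_counts = _apportion(params.category_mix, params.n_circrnas)
    exonic_total = params.n_circrnas - cat_counts.get("INTERGENIC", 0)
    if exonic_total > 0 and not gene_order:
        raise ValueError("exonic circRNAs requested but the genome has no genes")

    host_order = list(gene_order)
    rng.shuffle(host_order)
    while len(host_order) < exonic_total:  # reuse genes if circRNAs outnumber them
        host_order += gene_order

    junctions: list[BackspliceJunction] = []
    categories: list[str] = []
    hosts: list[str | None] = []
    placements: list[tuple[int, int] | None] = []  # (first exon, span) for exonic
    gi = 0
    used: set[tuple] = set()
    for category in ("EXONIC_BOTH_BOUNDARY", "EXONIC_BOTH_INTERNAL", "EXONIC_ONE_BOUNDARY"):
        for _ in range(cat_counts.get(category, 0)):
            for _attempt in range(50):  # genes may host several circRNAs
                g = genes[host_order[gi % len(host_order)]]
                gi += 1
                span = int(rng.integers(1, min(5, len(g.exons)) + 1))
                first = int(rng.integers(1, len(g.exons) - span + 2))
                start, end = _make_circ_coords(g, category, first, span)
                key = (g.chrom, start, end, g.strand)
                if key not in used:
                    break
            else:
                raise ValueError("could not place a unique circRNA; too few genes")
            used.add(key)
            junctions.append(BackspliceJunction(g.chrom, start, end, g.strand, ()))
            categories.append(category)
            hosts.append(g.gene_id)
            placements.append((first, span))

    n_inter = cat_counts.get("INTERGENIC", 0)
    n_chloro = int(round(params.chloroplast_fraction * n_inter))
    for k in range(n_inter):
        for _attempt in range(50):
            if k < n_chloro:
                length = int(rng.integers(150, 400))
                start = int(rng.integers(100, params.organelle_length - length - 100))
                chrom = "ChrC"
            else:
                usable = [s for s in spacers if s[2] - s[1] >= 160]
                if not usable:
                    raise ValueError("no gene-free spacer long enough for an intergenic circRNA")
                chrom, lo, hi = usable[int(rng.integers(len(usable)))]
                length = int(rng.integers(100, min(300, hi - lo)))
                start = int(rng.integers(lo, hi - length))
            strand = "+" if rng.integers(2) == 0 else "-"
            if (chrom, start, start + length, strand) not in used:
                break
        used.add((chrom, start, start + length, strand))
        junctions.append(BackspliceJunction(chrom, start, start + length, strand, ()))
        categories.append("INTERGENIC")
        hosts.append(None)
        placements.append(None)

    circ_ids = [j.circ_id for j in junctions]
    host_map = {cid: h for cid, h in zip(circ_ids, hosts) if h is not None}

    # --- expression --------------------------------------------------------
    n = params.n_circrnas
    n_reg = int(round(params.fraction_regulated * n))
    reg_idx = sorted(rng.choice(n, size=n_reg, replace=False))
    n_up = int(round(params.fraction_up * n_reg))
    up_idx = set(reg_idx[:n_up])
    down_idx = set(reg_idx[n_up:])

    lib = params.library_size * (
        1.0 + params.library_size_cv * rng.standard_normal(len(DAYS))
    )
    lib = np.clip(lib, params.library_size * 0.5, None)
    lib_factor = lib / lib.mean()
    library_sizes = pd.Series(np.round(lib), index=_LABELS)

    def draw(shape: str, base: float) -> np.ndarray:
        mu = trajectory(shape, base, params.planted_fold)
        return nb_counts(rng, np.maximum(mu, 0.0) * lib_factor, params.dispersion)

    circ_shape = {}
    circ_rows = []
    for i in range(n):
        base = float(rng.uniform(*params.baseline_mean))
        shape = "up" if i in up_idx else ("down" if i in down_idx else "flat")
        circ_shape[circ_ids[i]] = shape
        circ_rows.append(draw(shape, base))
    circ_counts = pd.DataFrame(circ_rows, index=circ_ids, columns=_LABELS)

    up_hosts = set()
    for i in sorted(up_idx):
        if hosts[i] is not None and rng.uniform() < params.host_concordant_fraction:
            up_hosts.add(hosts[i])

    # pick the mRNA targets of planted miRNAs up front and force them up, so
    # an anti-correlated partner always exists (non-host genes preferred)
    n_planted = int(round(params.planted_target_fraction * params.n_mirnas))
    host_genes = set(host_map.values())
    non_host = [g for g in gene_order if g not in host_genes]
    target_pool = non_host if len(non_host) >= n_planted else list(gene_order)
    planted_genes = [
        target_pool[i]
        for i in sorted(rng.choice(len(target_pool), size=min(n_planted, len(target_pool)), replace=False))
    ]

    gene_shape = {}
    gene_rows = []
    for gid in gene_order:
        base = float(rng.uniform(80.0, 300.0))
        if gid in up_hosts or gid in planted_genes:
            shape = "up"
        elif gid in host_genes:
            shape = "flat"
        else:
            u = rng.uniform()
            shape = "up" if u < 0.15 else ("down" if u < 0.25 else "flat")
        gene_shape[gid] = shape
        gene_rows.append(draw(shape, base))
    gene_counts = pd.DataFrame(gene_rows, index=gene_order, columns=_LABELS)

    # --- miRNAs and planted target sites -----------------------------------
    mirna_ids = [f"sim-miR{i + 1:03d}" for i in range(params.n_mirnas)]
    mirna_seqs = {m: _random_seq(rng, params.mirna_length, "ACGU") for m in mirna_ids}
    up_exonic = [i for i in sorted(up_idx) if hosts[i] is not None]
    planted_pairs: list[tuple[str, str]] = []
    for k in range(n_planted):
        if not up_exonic or not planted_genes:
            break
        ci = up_exonic[k % len(up_exonic)]
        gid = planted_genes[k % len(planted_genes)]
        mid = mirna_ids[k]
        # inside the first exon of the circRNA span, clear of both breakpoints
        g = genes[hosts[ci]]
        first, _span = placements[ci]
        ex = g.exons[first - 1]
        _plant_site(genome, g.chrom, ex.start + 20, _site_on_genome(mirna_seqs[mid], g.strand))
        tg = genes[gid]
        _plant_site(
            genome, tg.chrom, tg.exons[0].start + 20, _site_on_genome(mirna_seqs[mid], tg.strand)
        )
        planted_pairs.append((mid, circ_ids[ci]))
        planted_pairs.append((mid, gid))

    mirna_rows = []
    for k, mid in enumerate(mirna_ids):
        shape = "down" if k < len(planted_pairs) // 2 else "flat"
        mirna_rows.append(draw(shape, 100.0))
    mirna_counts = pd.DataFrame(mirna_rows, index=mirna_ids, columns=_LABELS)

    # --- junction supporting reads & catalogue ------------------------------
    junctions = [
        BackspliceJunction(
            j.chrom, j.start, j.end, j.strand, tuple(int(v) for v in circ_counts.iloc[i])
        )
        for i, j in enumerate(junctions)
    ]
    n_known = int(round(params.known_fraction * n))
    known_pick = sorted(rng.choice(n, size=n_known, replace=False))
    known_list = [
        (junctions[i].chrom, junctions[i].start, junctions[i].end, junctions[i].strand)
        for i in known_pick
    ]

    truth = {
        "category": dict(zip(circ_ids, categories)),
        "circ_shape": circ_shape,
        "gene_shape": gene_shape,
        "planted_pairs": planted_pairs,
        "known_ids": [circ_ids[i] for i in known_pick],
    }
    return SimulatedDataset(
        params=params,
        annotation=annotation,
        genome=genome,
        junctions=junctions,
        circ_counts=circ_counts,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        library_sizes=library_sizes,
        mirna_seqs=mirna_seqs,
        known_list=known_list,
        host_map=host_map,
        truth=truth,
    )


def _write_dataset(ds, outdir) -> dict[str, str]:
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "annotation.gff3"),
        "bsj": os.path.join(outdir, "bsj.tsv"),
        "gene_counts": os.path.join(outdir, "gene_counts.tsv"),
        "mirna_counts": os.path.join(outdir, "mirna_counts.tsv"),
        "mirna_fasta": os.path.join(outdir, "mirna.fa"),
        "known": os.path.join(outdir, "known_circs.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(ds.genome, paths["genome"])
    write_gff3(ds.annotation, paths["gff3"])
    write_bsj_table(ds.junctions, paths["bsj"], _LABELS)
    write_count_matrix(ds.gene_counts, ds.library_sizes, paths["gene_counts"])
    write_count_matrix(ds.mirna_counts, ds.library_sizes, paths["mirna_counts"])
    write_fasta(ds.mirna_seqs, paths["mirna_fasta"])
    write_known_circs(ds.known_list, paths["known"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Deterministic fixture
# ---------------------------------------------------------------------------
#
# 168 circRNAs. Index allocation (0-based), constructed so that every joint
# constraint holds simultaneously:
#
#   0-7     singletons, samples 1-6, EXONIC_BOTH_INTERNAL (the 8 internal)
#   8-19    singletons, samples 1-6, EXONIC_BOTH_BOUNDARY
#   20-29   singletons, samples 7-8 (days shared by both stages)
#   30-45   singletons, samples 9-14, EXONIC_ONE_BOUNDARY (the 16 one-boundary)
#   46-61   singletons, samples 9-14, spans 6-8 (the 16 long exonic)
#   62-93   singletons, samples 9-14
#   94-103  singletons, samples 9-14, INTERGENIC (101-103 on the chloroplast)
#   104-105 G-stage network circRNAs (up at G, planted miRNA sites)
#   106     down-regulated at G-to-M
#   107     retained but not DE (early samples)
#   108-110 up-regulated in BOTH stages (the 3 shared DE calls)
#   111     down-regulated at M-to-S (constant through sample 8, then absent)
#   112-114 up at M-to-S, detected in both stage windows
#   115-132 retained, both windows, not DE
#   133-137 M-stage network circRNAs (up at M, planted miRNA sites)
#   138-160 plain up at M-to-S (hosts of 138-146 are 4-fold-up genes,
#           giving the 9/34 host concordance)
#   161-167 detected in >10 samples, never DE
#
# Detection: 104 singletons; 57 features in 2-10 samples; 7 in >=11.
# Stage sets: A-only 24 (0-19 and 104-107), both 42 (20-29, 108-132, 161-167),
# B-only 102 (30-103, 133-160) -> |A| 66, |B| 144, 42 shared, union 168.
# Retained (>=2 samples): 64. The known-circRNA list holds the exact
# coordinates of indices 0-127, leaving 40 novel.

_FIX_SEED = 180781
_N_FIX = 168
_GENES_PER_CHROM = 35
_EXON_LEN = 120
_INTRON_LEN = 60
_GENE_START0 = 1001
_GENE_STRIDE = 1800
_NUC_LEN = 68000
_ORG_LEN = 10000


def _fixture_category_span(i: int) -> tuple[str, int]:
    if i < 8:
        return "EXONIC_BOTH_INTERNAL", 1 + (i % 2)
    if i < 30:
        return "EXONIC_BOTH_BOUNDARY", 1 + (i % 5)
    if i < 46:
        return "EXONIC_ONE_BOUNDARY", 1 + (i % 5)
    if i < 62:
        return "EXONIC_BOTH_BOUNDARY", 6 + (i % 3)
    if i < 94:
        return "EXONIC_BOTH_BOUNDARY", 1 + (i % 5)
    if i < 104:
        return "INTERGENIC", 0
    if i in (104, 105) or 133 <= i < 138:
        return "EXONIC_BOTH_BOUNDARY", 5  # network circRNAs carry 4-5 sites
    return "EXONIC_BOTH_BOUNDARY", 1 + (i % 5)


def _fixture_counts(i: int) -> list[int]:
    c = [0] * 14
    if i < 20:
        c[i % 6] = 1 + (i % 3)
    elif i < 30:
        c[6 + (i % 2)] = 1 + (i % 3)
    elif i < 104:
        c[8 + (i % 6)] = 1 + (i % 3)
    elif i in (104, 105):
        c[0:6] = [2, 4, 8, 16, 32, 64]
    elif i == 106:
        c[0] = c[1] = 15
    elif i == 107:
        c[1] = c[2] = 1
    elif i in (108, 109, 110):
        c[4] = c[9] = 15
    elif i == 111:
        c[0:8] = [15] * 8
    elif i in (112, 113, 114):
        c[6] = 1
        c[9] = 15
    elif i < 133:
        c[6] = 1 + (i % 2)
        c[7] = 1 + ((i + 1) % 2)
    elif i < 138:
        c[8:14] = [2, 4, 8, 16, 32, 64]
    elif i < 161:
        b = 8 + (i % 4)
        c[b] = 15
        c[b + 2] = 15
    elif i < 165:
        c = [2] * 14
    else:
        c = [1] * 12 + [0, 0]
    return c


def _fixture_role(i: int) -> str:
    if i < 104:
        return "singleton"
    if i in (104, 105):
        return "network_circ_G"
    if i == 106:
        return "de_down_G"
    if i == 107:
        return "retained_flat"
    if i in (108, 109, 110):
        return "de_up_both"
    if i == 111:
        return "de_down_M"
    if i in (112, 113, 114):
        return "de_up_M"
    if i < 133:
        return "retained_flat"
    if i < 138:
        return "network_circ_M"
    if i < 161:
        return "de_up_M"
    return "high_detection"


# expression profiles used by the planted sponge networks; the miRNA rank
# pattern is the exact mirror of its targets' pattern, so Spearman rho = -1
_G_TARGET_GENE = [50, 100, 200, 400, 800, 1600] + [12] * 8
_M_TARGET_GENE = [12] * 8 + [50, 100, 200, 400, 800, 1600]
_G_MIRNA = [32, 16, 8, 4, 2, 1] + [100] * 8
_M_MIRNA = [100] * 8 + [32, 16, 8, 4, 2, 1]
_UP_HOST = [100] * 8 + [500] * 6

_G_MIRNA_IDS = ["fix-miR9101", "fix-miR9102"]
_M_MIRNA_IDS = ["fix-miR9201", "fix-miR9202", "fix-miR9203", "fix-miR9204"]
_DECOY_MIRNA_IDS = ["fix-miR9301", "fix-miR9302"]


@dataclass
class PaperFixture:
    annotation: GenomeAnnotation
    genome: dict[str, str]
    junctions: list[BackspliceJunction]
    circ_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    library_sizes: pd.Series
    mirna_seqs: dict[str, str]
    known_list: list[tuple[str, int, int, str]]
    host_map: dict[str, str]
    truth: pd.DataFrame          # circ_id, category, exon_span, host, role
    stage_config: StageConfig

    def write(self, outdir) -> dict[str, str]:
        ds = SimulatedDataset(
            params=SimParams(seed=_FIX_SEED),
            annotation=self.annotation,
            genome=self.genome,
            junctions=self.junctions,
            circ_counts=self.circ_counts,
            gene_counts=self.gene_counts,
            mirna_counts=self.mirna_counts,
            library_sizes=self.library_sizes,
            mirna_seqs=self.mirna_seqs,
            known_list=self.known_list,
            host_map=self.host_map,
            truth={"roles": dict(zip(self.truth["circ_id"], self.truth["role"]))},
        )
        return _write_dataset(ds, outdir)


def make_paper_fixture() -> PaperFixture:
    """Build the deterministic fixture (see the allocation table above)."""
    rng = np.random.default_rng(_FIX_SEED)

    # genes: 175 uniform 8-exon genes over 5 nuclear chromosomes
    chromosomes = {
        **{f"Chr{c}": Chromosome(f"Chr{c}", _NUC_LEN) for c in range(1, 6)},
        "ChrC": Chromosome("ChrC", _ORG_LEN, "chloroplast"),
        "ChrM": Chromosome("ChrM", _ORG_LEN, "mitochondria"),
    }
    gene_list: list[Gene] = []
    for gi in range(5 * _GENES_PER_CHROM):
        c = gi // _GENES_PER_CHROM + 1
        slot = gi % _GENES_PER_CHROM
        gstart = _GENE_START0 + slot * _GENE_STRIDE
        exons = [
            Exon(
                gstart + k * (_EXON_LEN + _INTRON_LEN),
                gstart + k * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN - 1,
            )
            for k in range(8)
        ]
        gid = f"FIX{c}G{(slot + 1) * 10:05d}"
        gene_list.append(Gene(gid, f"Chr{c}", "+", exons[0].start, exons[-1].end, exons))

    # network genes (hosts of site-carrying circRNAs and the target mRNAs)
    # must be plus-strand; others alternate for variety
    forced_plus = {94, 95, 123, 124, 125, 126, 127} | set(range(158, 174))
    for gi, g in enumerate(gene_list):
        if gi not in forced_plus:
            g.strand = "+" if gi % 2 == 0 else "-"
    genes = {g.gene_id: g for g in gene_list}
    annotation = GenomeAnnotation(chromosomes, genes)
    annotation.validate()

    genome = {cid: _random_seq(rng, ch.length) for cid, ch in chromosomes.items()}

    # --- junctions ----------------------------------------------------------
    junctions: list[BackspliceJunction] = []
    hosts: list[str | None] = []
    cats: list[str] = []
    spans: list[int] = []
    host_cursor = 0
    for i in range(_N_FIX):
        category, span = _fixture_category_span(i)
        counts = tuple(_fixture_counts(i))
        if category == "INTERGENIC":
            k = i - 94
            if i <= 100:
                chrom = f"Chr{k % 5 + 1}"
                start = 64500 + k * 300
                end = start + 249
            else:
                chrom = "ChrC"
                start = 1001 + (i - 101) * 1000
                end = start + 399
            junctions.append(BackspliceJunction(chrom, start, end, "+", counts))
            hosts.append(None)
        else:
            g = gene_list[host_cursor]
            host_cursor += 1
            start, end = _make_circ_coords(g, category, 1, span)
            junctions.append(BackspliceJunction(g.chrom, start, end, g.strand, counts))
            hosts.append(g.gene_id)
        cats.append(category)
        spans.append(span)

    circ_ids = [j.circ_id for j in junctions]
    host_map = {cid: h for cid, h in zip(circ_ids, hosts) if h is not None}
    known_list = [
        (junctions[i].chrom, junctions[i].start, junctions[i].end, junctions[i].strand)
        for i in range(128)
    ]

    # --- count matrices -----------------------------------------------------
    circ_counts = pd.DataFrame(
        [list(j.counts) for j in junctions], index=circ_ids, columns=list(_LABELS)
    )

    up_host_genes = {host_map[circ_ids[i]] for i in range(138, 147)}
    gene_rows = {}
    for gi, g in enumerate(gene_list):
        if g.gene_id in up_host_genes:
            gene_rows[g.gene_id] = list(_UP_HOST)
        elif 158 <= gi <= 162:
            gene_rows[g.gene_id] = list(_G_TARGET_GENE)
        elif 163 <= gi <= 173:
            gene_rows[g.gene_id] = list(_M_TARGET_GENE)
        else:
            gene_rows[g.gene_id] = [100] * 14
    gene_counts = pd.DataFrame.from_dict(gene_rows, orient="index", columns=list(_LABELS))

    mirna_rows = {}
    for mid in _G_MIRNA_IDS:
        mirna_rows[mid] = list(_G_MIRNA)
    for mid in _M_MIRNA_IDS:
        mirna_rows[mid] = list(_M_MIRNA)
    for mid in _DECOY_MIRNA_IDS:
        mirna_rows[mid] = [50] * 14
    mirna_counts = pd.DataFrame.from_dict(mirna_rows, orient="index", columns=list(_LABELS))

    library_sizes = pd.Series(1e6, index=list(_LABELS))

    # --- miRNA sequences and planted sites ----------------------------------
    mirna_seqs = {
        mid: _random_seq(rng, 21, "ACGU")
        for mid in _G_MIRNA_IDS + _M_MIRNA_IDS + _DECOY_MIRNA_IDS
    }

    def plant_in_gene(gene: Gene, exon_no: int, mirna_id: str) -> None:
        site = _revcomp_dna(mirna_seqs[mirna_id])
        _plant_site(genome, gene.chrom, gene.exons[exon_no - 1].start + 20, site)

    for i in (104, 105):  # G-stage sponge circRNAs
        g = genes[host_map[circ_ids[i]]]
        for exon_no, mid in enumerate(_G_MIRNA_IDS, start=1):
            plant_in_gene(g, exon_no, mid)
    for gi in range(158, 163):  # G-stage target mRNAs
        for exon_no, mid in enumerate(_G_MIRNA_IDS, start=1):
            plant_in_gene(gene_list[gi], exon_no, mid)
    for i in range(133, 138):  # M-stage sponge circRNAs
        g = genes[host_map[circ_ids[i]]]
        for exon_no, mid in enumerate(_M_MIRNA_IDS, start=1):
            plant_in_gene(g, exon_no, mid)
    for gi in range(163, 174):  # M-stage target mRNAs
        for exon_no, mid in enumerate(_M_MIRNA_IDS, start=1):
            plant_in_gene(gene_list[gi], exon_no, mid)

    truth = pd.DataFrame(
        {
            "circ_id": circ_ids,
            "category": cats,
            "exon_span": spans,
            "host": [h if h is not None else "" for h in hosts],
            "role": [_fixture_role(i) for i in range(_N_FIX)],
        }
    )
    return PaperFixture(
        annotation=annotation,
        genome=genome,
        junctions=junctions,
        circ_counts=circ_counts,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        library_sizes=library_sizes,
        mirna_seqs=mirna_seqs,
        known_list=known_list,
        host_map=host_map,
        truth=truth,
        stage_config=default_stage_config(),
    )
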
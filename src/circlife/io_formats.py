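"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is **1-based inclusive** (the GFF3 convention).
Back-splice junction (BSJ) tables on disk use the BED dialect
(**0-based half-open**) and are converted on read/write, so a file row
``Chr1  999  2000  +`` becomes the internal junction ``start=1000, end=2000``.
Known-circRNA catalogues (PlantcircBase style) are 1-based inclusive both on
disk and in memory.

Library sizes (per-sample sequencing totals, the denominator of the
``(n+1)/N`` normalization) always travel with a count matrix — either as a
reserved ``library_size`` row inside the TSV or as a two-column sidecar file —
and are never recomputed from column sums: feature sums are not sequencing
totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Default mapping of chromosome ids to organelle tags (TAIR naming).
ORGANELLE_MAP_DEFAULT = {"ChrC": "chloroplast", "ChrM": "mitochondria"}

#: Reserved feature id carrying per-sample library sizes inside a count matrix.
LIBRARY_SIZE_ROW = "library_size"


class FormatError(ValueError):
    """A file violates its format contract (bad column count, bad value...)."""


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Exon:
    """A 1-based inclusive exon interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"exon start {self.start} > end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Exon] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.start or ex.end > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside "
                    f"gene span {self.start}-{self.end}"
                )
            if prev_end is not None and ex.start <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at "
                    f"{ex.start}-{ex.end}"
                )
            prev_end = ex.end


@dataclass
class Chromosome:
    chrom_id: str
    length: int
    organelle: str = "nuclear"  # one of nuclear / chloroplast / mitochondria


@dataclass
class GenomeAnnotation:
    """Chromosomes, genes and exons of one genome, with organelle tags."""

    chromosomes: dict[str, Chromosome]
    genes: dict[str, Gene]
    _by_chrom: dict[str, list[Gene]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def validate(self) -> None:
        for g in self.genes.values():
            g.validate()
            if g.chrom not in self.chromosomes:
                raise FormatError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self.chromosomes[g.chrom].length:
                raise FormatError(
                    f"gene {g.gene_id}: end {g.end} exceeds {g.chrom} length "
                    f"{self.chromosomes[g.chrom].length}"
                )

    def genes_on(self, chrom: str) -> list[Gene]:
        """Genes on one chromosome, sorted by start (cached)."""
        if chrom not in self._by_chrom:
            self._by_chrom[chrom] = sorted(
                (g for g in self.genes.values() if g.chrom == chrom),
                key=lambda g: (g.start, g.end, g.gene_id),
            )
        return self._by_chrom[chrom]


def read_gff3(path: str, organelle_map: dict[str, str] | None = None) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    ``##sequence-region`` directives provide chromosome lengths; chromosomes
    without one get the maximum feature end observed. Exons may be children of
    genes directly or via mRNA features. Chromosomes whose id appears in
    ``organelle_map`` (default ``ChrC``/``ChrM``) are tagged accordingly.

    Raises :class:`FormatError` naming the line number for malformed lines and
    for exons lacking a gene ancestor.
    """
    organelle_map = dict(ORGANELLE_MAP_DEFAULT if organelle_map is None else organelle_map)

    seq_regions: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) != 4:
                        raise FormatError(
                            f"{path}: line {lineno}: malformed ##sequence-region directive"
                        )
                    seq_regions[parts[1]] = int(parts[3])
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF3 columns"
                )

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = Gene(g.id, g.seqid, g.strand, g.start, g.end)

    for ex in db.features_of_type("exon"):
        parent_gene = None
        for anc in db.parents(ex):
            if anc.featuretype == "gene":
                parent_gene = anc.id
                break
        if parent_gene is None or parent_gene not in genes:
            raise FormatError(
                f"{path}: exon at {ex.seqid}:{ex.start}-{ex.end} has no parent gene"
            )
        genes[parent_gene].exons.append(Exon(ex.start, ex.end))

    for g in genes.values():
        g.exons = sorted(set(g.exons))

    chrom_ids = set(seq_regions) | {g.chrom for g in genes.values()}
    chromosomes = {}
    for cid in sorted(chrom_ids):
        length = seq_regions.get(
            cid, max((g.end for g in genes.values() if g.chrom == cid), default=0)
        )
        chromosomes[cid] = Chromosome(cid, length, organelle_map.get(cid, "nuclear"))

    ann = GenomeAnnotation(chromosomes, genes)
    ann.validate()
    return ann


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write an annotation as GFF3 (gene features with direct exon children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes.values():
            fh.write(f"##sequence-region {chrom.chrom_id} 1 {chrom.length}\n")
        for g in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tcirclife\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tcirclife\texon\t{ex.start}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Back-splice junctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackspliceJunction:
    """A back-splice junction: the two breakpoints joined head-to-tail.

    ``start``/``end`` are 1-based inclusive genomic positions with
    ``start < end``; ``counts`` holds one supporting-read integer per sample
    of the time course.
    """

    chrom: str
    start: int
    end: int
    strand: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"junction {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in "+-":
            raise FormatError(f"bad junction strand {self.strand!r}")
        if any(c < 0 for c in self.counts):
            raise FormatError(
                f"junction {self.chrom}:{self.start}-{self.end}: negative count"
            )

    @property
    def circ_id(self) -> str:
        return f"circ:{self.chrom}:{self.start}-{self.end}:{self.strand}"


def read_bsj_table(path: str, n_samples: int) -> list[BackspliceJunction]:
    """Read a BED-dialect BSJ table (0-based half-open on disk).

    Expects a header line then columns chrom, start, end, strand followed by
    one count column per sample.
    """
    junctions: list[BackspliceJunction] = []
    with open(path) as fh:
        header = fh.readline()
        if header and len(header.rstrip("\n").split("\t")) != 4 + n_samples:
            raise FormatError(
                f"{path}: header has {len(header.split(chr(9)))} columns, "
                f"expected {4 + n_samples}"
            )
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4 + n_samples:
                raise FormatError(
                    f"{path}: line {lineno}: expected {4 + n_samples} columns, "
                    f"got {len(fields)}"
                )
            chrom, start0, end0, strand = fields[:4]
            counts = tuple(int(c) for c in fields[4:])
            if any(c < 0 for c in counts):
                raise FormatError(f"{path}: line {lineno}: negative read count")
            junctions.append(
                BackspliceJunction(chrom, int(start0) + 1, int(end0), strand, counts)
            )
    return junctions


def write_bsj_table(
    junctions: list[BackspliceJunction], path: str, sample_labels: list[str]
) -> None:
    """Write junctions as a BED-dialect table (converts back to 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "start", "end", "strand"] + list(sample_labels)) + "\n")
        for j in junctions:
            if len(j.counts) != len(sample_labels):
                raise FormatError(
                    f"junction {j.circ_id}: {len(j.counts)} counts for "
                    f"{len(sample_labels)} samples"
                )
            row = [j.chrom, str(j.start - 1), str(j.end), j.strand]
            row += [str(c) for c in j.counts]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str, lib_sizes_path: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a feature × sample count TSV plus its library sizes.

    Library sizes come either from a reserved ``library_size`` row inside the
    matrix or from a two-column sidecar TSV (sample, total reads). They are
    mandatory: the ``(n+1)/N`` normalization is undefined without them.

    Returns ``(counts, library_sizes)`` aligned on sample order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated feature id {dup[0]!r}")

    if lib_sizes_path is not None:
        sizes_df = pd.read_csv(lib_sizes_path, sep="\t", index_col=0)
        lib_sizes = sizes_df.iloc[:, 0].reindex(df.columns)
        if lib_sizes.isna().any():
            missing = lib_sizes.index[lib_sizes.isna()][0]
            raise FormatError(f"{lib_sizes_path}: no library size for sample {missing!r}")
    elif LIBRARY_SIZE_ROW in df.index:
        lib_sizes = df.loc[LIBRARY_SIZE_ROW]
        df = df.drop(index=LIBRARY_SIZE_ROW)
    else:
        raise FormatError(
            f"{path}: library sizes missing (no {LIBRARY_SIZE_ROW!r} row and no sidecar)"
        )

    counts = df.astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    lib_sizes = lib_sizes.astype(float)
    lib_sizes.name = LIBRARY_SIZE_ROW
    return counts, lib_sizes


def write_count_matrix(counts: pd.DataFrame, lib_sizes: pd.Series, path: str) -> None:
    """Write counts with the library-size row embedded first."""
    out = pd.concat(
        [pd.DataFrame([lib_sizes.astype(np.int64)], index=[LIBRARY_SIZE_ROW]), counts]
    )
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Known-circRNA catalogue (PlantcircBase style)
# ---------------------------------------------------------------------------

def read_known_circs(path: str) -> list[tuple[str, int, int, str]]:
    """Read a known-circRNA list: TSV of chrom, start, end, strand (1-based)."""
    out = []
    with open(path) as fh:
        header = fh.readline()  # header required for symmetry with writer
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out


def write_known_circs(entries: list[tuple[str, int, int, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\n")
        for chrom, start, end, strand in entries:
            fh.write(f"{chrom}\t{start}\t{end}\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Network export (Cytoscape-loadable)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "circ_id", "mirna_id", "mrna_id", "stage",
    "circ_score", "mrna_score", "rho_circ", "rho_mrna",
]


def write_network(triplets, path: str, fmt: str = "sif") -> None:
    """Write circRNA–miRNA–mRNA triplets as SIF edges or a TSV table.

    SIF emits two ``targets`` edges per triplet (miRNA→circRNA, miRNA→mRNA),
    deduplicated; TSV emits one row per triplet with scores and correlations.
    """
    if fmt == "sif":
        edges: list[tuple[str, str, str]] = []
        seen = set()
        for t in triplets:
            for target in (t.circ_id, t.mrna_id):
                edge = (t.mirna_id, "targets", target)
                if edge not in seen:
                    seen.add(edge)
                    edges.append(edge)
        with open(path, "w") as fh:
            for src, rel, dst in edges:
                fh.write(f"{src}\t{rel}\t{dst}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for t in triplets:
                fh.write(
                    f"{t.circ_id}\t{t.mirna_id}\t{t.mrna_id}\t{t.stage}\t"
                    f"{t.circ_score:g}\t{t.mrna_score:g}\t{t.rho_circ:g}\t{t.rho_mrna:g}\n"
                )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_tsv(path: str):
    """Re-import a TSV network file as a list of triplets (round-trip check)."""
    from .network import Triplet  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise FormatError(f"{path}: unexpected network TSV header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_TSV_COLUMNS):
                raise FormatError(f"{path}: bad network TSV row")
            out.append(
                Triplet(
                    circ_id=f[0], mirna_id=f[1], mrna_id=f[2], stage=f[3],
                    circ_score=float(f[4]), mrna_score=float(f[5]),
                    rho_circ=float(f[6]), rho_mrna=float(f[7]),
                )
            )
    return out
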
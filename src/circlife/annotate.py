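"""Classify back-splice junctions against a genome annotation.

Each junction is placed into one of six categories modelled on how circRNA
surveys tabulate splice-site configurations: exonic with both breakpoints at
exon boundaries, exonic with both internal, exonic with exactly one boundary
hit, intronic, intergenic, or ambiguous (cross-gene / cross-strand / mixed
exon–intron configurations that a conservative classifier refuses to force
into the main rows).

The module also assigns host genes, counts spanned exons, flags organelle
origin and novelty against a known-circRNA catalogue, and splices out the
circular sequence of a record (exon segments clipped to the junction span,
concatenated, reverse-complemented on the minus strand) together with a
junction-spanning window for target-site scanning.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP

from Bio.Seq import Seq

from .io_formats import BackspliceJunction, Exon, Gene, GenomeAnnotation


class Category(str, enum.Enum):
    EXONIC_BOTH_BOUNDARY = "EXONIC_BOTH_BOUNDARY"
    EXONIC_BOTH_INTERNAL = "EXONIC_BOTH_INTERNAL"
    EXONIC_ONE_BOUNDARY = "EXONIC_ONE_BOUNDARY"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"
    AMBIGUOUS = "AMBIGUOUS"


EXONIC_CATEGORIES = (
    Category.EXONIC_BOTH_BOUNDARY,
    Category.EXONIC_BOTH_INTERNAL,
    Category.EXONIC_ONE_BOUNDARY,
)


@dataclass(frozen=True)
class CircRNARecord:
    junction: BackspliceJunction
    category: Category
    host_gene: str | None
    exon_span: int
    organelle: str
    is_novel: bool | None = None  # None = not yet compared to a catalogue

    def __post_init__(self) -> None:
        is_exonic = self.category in EXONIC_CATEGORIES
        if is_exonic != (self.host_gene is not None):
            raise ValueError(
                f"{self.circ_id}: category {self.category.value} inconsistent with "
                f"host_gene={self.host_gene!r}"
            )
        if self.category is Category.INTERGENIC and self.exon_span != 0:
            raise ValueError(f"{self.circ_id}: intergenic record with exon_span > 0")

    @property
    def circ_id(self) -> str:
        return self.junction.circ_id


def classify_bsj(
    junction: BackspliceJunction,
    annotation: GenomeAnnotation,
    boundary_tolerance: int = 0,
) -> CircRNARecord:
    """Assign exactly one category to a junction.

    A breakpoint *hits* an exon when it lies within ``[exon.start, exon.end]``.
    It is *boundary-matched* when it lies within ``boundary_tolerance`` nt of
    the appropriate edge of the exon it hits — the acceptor edge for the
    transcript-upstream breakpoint and the donor edge for the downstream one.
    With the symmetric ``|delta| <= tolerance`` test both strands compare the
    left breakpoint against the exon's genomic start and the right breakpoint
    against its genomic end; strand only relabels which edge is donor vs
    acceptor.

    Host-gene candidates must contain *both* breakpoints and share the
    junction's strand; among overlapping candidates the gene with the largest
    overlap with the junction interval wins, an exact tie is AMBIGUOUS.
    """
    if junction.chrom not in annotation.chromosomes:
        raise KeyError(f"unknown chromosome {junction.chrom!r}")

    chrom_genes = annotation.genes_on(junction.chrom)
    organelle = annotation.chromosomes[junction.chrom].organelle
    start, end = junction.start, junction.end

    containing = [g for g in chrom_genes if g.start <= start and end <= g.end]
    touches_any = any(
        g.start <= start <= g.end or g.start <= end <= g.end for g in chrom_genes
    )

    def record(category: Category, host: Gene | None) -> CircRNARecord:
        span = 0
        if host is not None:
            span = sum(1 for ex in host.exons if ex.start <= end and start <= ex.end)
        return CircRNARecord(
            junction=junction,
            category=category,
            host_gene=host.gene_id if host is not None else None,
            exon_span=span,
            organelle=organelle,
        )

    if not containing:
        if not touches_any:
            return record(Category.INTERGENIC, None)
        return record(Category.AMBIGUOUS, None)

    strand_matched = [g for g in containing if g.strand == junction.strand]
    if not strand_matched:
        return record(Category.AMBIGUOUS, None)

    # Largest overlap with [start, end]; exact tie -> AMBIGUOUS. When both
    # breakpoints sit inside several genes the overlaps tie by construction.
    def overlap(g: Gene) -> int:
        return min(end, g.end) - max(start, g.start) + 1

    strand_matched.sort(key=overlap, reverse=True)
    if len(strand_matched) > 1 and overlap(strand_matched[0]) == overlap(strand_matched[1]):
        return record(Category.AMBIGUOUS, None)
    host = strand_matched[0]

    start_exon = next((ex for ex in host.exons if ex.contains(start)), None)
    end_exon = next((ex for ex in host.exons if ex.contains(end)), None)

    if start_exon is not None and end_exon is not None:
        start_matched = abs(start - start_exon.start) <= boundary_tolerance
        end_matched = abs(end - end_exon.end) <= boundary_tolerance
        if start_matched and end_matched:
            return record(Category.EXONIC_BOTH_BOUNDARY, host)
        if start_matched or end_matched:
            return record(Category.EXONIC_ONE_BOUNDARY, host)
        return record(Category.EXONIC_BOTH_INTERNAL, host)
    if start_exon is None and end_exon is None:
        # host gene identity is deliberately not stored: the exonic <-> host
        # invariant keeps non-exonic rows host-free
        return record(Category.INTRONIC, None)
    return record(Category.AMBIGUOUS, None)


# ---------------------------------------------------------------------------
# Summary (Table-1 shaped)
# ---------------------------------------------------------------------------

def largest_remainder_percentages(
    counts: dict, total: int, decimals: int = 1
) -> dict:
    """Percentages at fixed precision that sum exactly to 100.

    Hamilton (largest-remainder) apportionment: floor every share to the
    requested precision, then hand the leftover 0.1-units to the categories
    with the largest fractional remainders (ties broken by larger count, then
    input order). This is how summary tables whose percentage column must add
    to 100.0 are conventionally rounded.
    """
    if total <= 0:
        return {k: 0.0 for k in counts}
    unit = 10 ** decimals
    shares = {k: counts[k] * 100.0 * unit / total for k in counts}
    floors = {k: int(shares[k] // 1) for k in counts}
    leftover = 100 * unit - sum(floors.values())
    order = sorted(
        counts,
        key=lambda k: (shares[k] - floors[k], counts[k]),
        reverse=True,
    )
    for k in order[:leftover]:
        floors[k] += 1
    return {k: floors[k] / unit for k in counts}


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassSummary:
    total: int
    counts: dict[Category, int]
    percentages: dict[Category, float]          # largest-remainder, sums to 100.0
    exonic_count: int
    exonic_pct: float                           # sum of the exonic rows
    pct_of_exonic: dict[Category, float]        # round-half-up of count/exonic
    exon_span_hist: dict[int, int]              # exonic records only
    exonic_span_1_5: int
    pct_span_1_5: float                         # of exonic, round-half-up
    organelle_counts: dict[str, int]
    novelty_counts: dict[str, int]              # novel / known / unassessed


def summarize_classes(records: list[CircRNARecord]) -> ClassSummary:
    """Tabulate category counts and percentages the way survey tables print them."""
    total = len(records)
    counts = {c: 0 for c in Category}
    for r in records:
        counts[r.category] += 1

    if total == 0:
        return ClassSummary(
            total=0, counts=counts, percentages={},
            exonic_count=0, exonic_pct=0.0, pct_of_exonic={},
            exon_span_hist={}, exonic_span_1_5=0, pct_span_1_5=0.0,
            organelle_counts={}, novelty_counts={},
        )

    percentages = largest_remainder_percentages(counts, total)
    exonic_count = sum(counts[c] for c in EXONIC_CATEGORIES)
    exonic_pct = round(sum(percentages[c] for c in EXONIC_CATEGORIES), 1)

    pct_of_exonic = {}
    span_hist: dict[int, int] = {}
    if exonic_count:
        for c in EXONIC_CATEGORIES:
            pct_of_exonic[c] = round_half_up(100.0 * counts[c] / exonic_count)
        for r in records:
            if r.category in EXONIC_CATEGORIES:
                span_hist[r.exon_span] = span_hist.get(r.exon_span, 0) + 1
    span_1_5 = sum(n for s, n in span_hist.items() if 1 <= s <= 5)
    pct_span_1_5 = (
        round_half_up(100.0 * span_1_5 / exonic_count) if exonic_count else 0.0
    )

    organelle_counts: dict[str, int] = {}
    novelty = {"novel": 0, "known": 0, "unassessed": 0}
    for r in records:
        organelle_counts[r.organelle] = organelle_counts.get(r.organelle, 0) + 1
        if r.is_novel is None:
            novelty["unassessed"] += 1
        elif r.is_novel:
            novelty["novel"] += 1
        else:
            novelty["known"] += 1

    return ClassSummary(
        total=total, counts=counts, percentages=percentages,
        exonic_count=exonic_count, exonic_pct=exonic_pct,
        pct_of_exonic=pct_of_exonic, exon_span_hist=dict(sorted(span_hist.items())),
        exonic_span_1_5=span_1_5, pct_span_1_5=pct_span_1_5,
        organelle_counts=organelle_counts, novelty_counts=novelty,
    )


# ---------------------------------------------------------------------------
# Novelty against a known-circRNA catalogue
# ---------------------------------------------------------------------------

def flag_novel(
    records: list[CircRNARecord],
    known_list: list[tuple[str, int, int, str]],
    slack: int = 0,
) -> list[CircRNARecord]:
    """Mark each record novel unless a catalogue entry matches it.

    A match shares chromosome and strand with both breakpoint offsets within
    ``slack`` nt (default 0 = exact coordinates).
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, start, end, strand in known_list:
        by_key.setdefault((chrom, strand), []).append((start, end))

    out = []
    for r in records:
        j = r.junction
        candidates = by_key.get((j.chrom, j.strand), ())
        known = any(
            abs(j.start - ks) <= slack and abs(j.end - ke) <= slack
            for ks, ke in candidates
        )
        out.append(replace(r, is_novel=not known))
    return out


# ---------------------------------------------------------------------------
# Circular sequence extraction
# ---------------------------------------------------------------------------

def extract_circ_sequence(
    record: CircRNARecord,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    junction_window_k: int = 22,
) -> tuple[str, str]:
    """Splice-and-circularize: the circular sequence plus its junction window.

    Exonic records concatenate the host gene's exon sub-sequences overlapping
    the junction interval, clipped to it (introns drop out); intronic and
    intergenic records take the plain genomic interval. Minus-strand records
    are reverse-complemented. The junction window is the last ``k - 1`` bases
    followed by the first ``k - 1`` bases of the circular sequence — every
    target-site window that crosses the back-splice seam lies inside it.
    """
    j = record.junction
    chrom_seq = genome[j.chrom]
    if j.end > len(chrom_seq):
        raise ValueError(
            f"{record.circ_id}: span end {j.end} exceeds {j.chrom} length {len(chrom_seq)}"
        )

    if record.category in EXONIC_CATEGORIES and record.host_gene is not None:
        host = annotation.genes[record.host_gene]
        pieces = []
        for ex in host.exons:
            lo, hi = max(ex.start, j.start), min(ex.end, j.end)
            if lo <= hi:
                pieces.append(chrom_seq[lo - 1 : hi])
        seq = "".join(pieces)
    else:
        seq = chrom_seq[j.start - 1 : j.end]

    if j.strand == "-":
        seq = str(Seq(seq).reverse_complement())

    k = junction_window_k
    window = seq[-(k - 1):] + seq[: k - 1] if k > 1 and seq else ""
    return seq, window


def extract_transcript(gene: Gene, genome: dict[str, str]) -> str:
    """Spliced transcript of a gene: exons concatenated, revcomp on minus strand."""
    chrom_seq = genome[gene.chrom]
    seq = "".join(chrom_seq[ex.start - 1 : ex.end] for ex in gene.exons)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
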
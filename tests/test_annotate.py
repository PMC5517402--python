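import numpy as np
import pytest

import circlife as cl
from circlife.annotate import Category, largest_remainder_percentages


def _junction(chrom, start, end, strand="+"):
    return cl.BackspliceJunction(chrom, start, end, strand, tuple([1] * 14))


# ---------------------------------------------------------------------------
# classify_bsj decision rules
# ---------------------------------------------------------------------------

class TestClassification:
    def test_both_boundary_with_exon_span(self, toy_annotation):
        # breakpoints exactly at exon2 start and exon4 end of gA
        rec = cl.classify_bsj(_junction("Chr1", 1201, 1700), toy_annotation)
        assert rec.category is Category.EXONIC_BOTH_BOUNDARY
        assert rec.host_gene == "gA"
        assert rec.exon_span == 3

    def test_intergenic_on_gene_free_scaffold(self, toy_annotation):
        rec = cl.classify_bsj(_junction("Chr2", 100, 400), toy_annotation)
        assert rec.category is Category.INTERGENIC
        assert rec.exon_span == 0 and rec.host_gene is None

    def test_one_boundary_when_other_breakpoint_internal(self, toy_annotation):
        # start at exon1 edge, end 7 nt inside exon3
        rec = cl.classify_bsj(_junction("Chr1", 1001, 1493), toy_annotation)
        assert rec.category is Category.EXONIC_ONE_BOUNDARY
        assert rec.exon_span == 3

    def test_both_internal(self, toy_annotation):
        rec = cl.classify_bsj(_junction("Chr1", 1010, 1490), toy_annotation)
        assert rec.category is Category.EXONIC_BOTH_INTERNAL

    def test_intronic_when_both_breakpoints_between_exons(self, toy_annotation):
        rec = cl.classify_bsj(_junction("Chr1", 1110, 1390), toy_annotation)
        assert rec.category is Category.INTRONIC
        assert rec.host_gene is None

    def test_strand_mismatch_is_ambiguous(self, toy_annotation):
        rec = cl.classify_bsj(_junction("Chr1", 3001, 3300, strand="+"), toy_annotation)
        assert rec.category is Category.AMBIGUOUS

    def test_one_genic_one_intergenic_is_ambiguous(self, toy_annotation):
        rec = cl.classify_bsj(_junction("Chr1", 1050, 2500), toy_annotation)
        assert rec.category is Category.AMBIGUOUS

    def test_minus_strand_boundary_match(self, toy_annotation):
        rec = cl.classify_bsj(_junction("Chr1", 3001, 3300, strand="-"), toy_annotation)
        assert rec.category is Category.EXONIC_BOTH_BOUNDARY
        assert rec.host_gene == "gB" and rec.exon_span == 2

    def test_unknown_chromosome_raises(self, toy_annotation):
        with pytest.raises(KeyError):
            cl.classify_bsj(_junction("ChrX", 10, 20), toy_annotation)

    def test_boundary_tolerance_relaxes_exact_matching(self, toy_annotation):
        j = _junction("Chr1", 1202, 1699)  # 1 nt off each exon edge
        assert cl.classify_bsj(j, toy_annotation).category is Category.EXONIC_BOTH_INTERNAL
        rec = cl.classify_bsj(j, toy_annotation, boundary_tolerance=2)
        assert rec.category is Category.EXONIC_BOTH_BOUNDARY


# ---------------------------------------------------------------------------
# Oracle equivalence on random toy annotations
# ---------------------------------------------------------------------------

def _oracle_classify(j, ann, tol=0):
    """Exhaustive per-gene, per-exon interval testing (independent of the
    implementation's candidate-selection shortcuts)."""
    genes = [g for g in ann.genes.values() if g.chrom == j.chrom]
    containing = [g for g in genes if g.start <= j.start and j.end <= g.end]
    touching = [
        g for g in genes
        if g.start <= j.start <= g.end or g.start <= j.end <= g.end
    ]
    if not containing:
        return "INTERGENIC" if not touching else "AMBIGUOUS"
    same_strand = [g for g in containing if g.strand == j.strand]
    if not same_strand:
        return "AMBIGUOUS"

    def ovl(g):
        return min(j.end, g.end) - max(j.start, g.start) + 1

    best = max(ovl(g) for g in same_strand)
    winners = [g for g in same_strand if ovl(g) == best]
    if len(winners) > 1:
        return "AMBIGUOUS"
    g = winners[0]
    s_ex = [e for e in g.exons if e.start <= j.start <= e.end]
    e_ex = [e for e in g.exons if e.start <= j.end <= e.end]
    if s_ex and e_ex:
        sm = abs(j.start - s_ex[0].start) <= tol
        em = abs(j.end - e_ex[0].end) <= tol
        if sm and em:
            return "EXONIC_BOTH_BOUNDARY"
        if sm or em:
            return "EXONIC_ONE_BOUNDARY"
        return "EXONIC_BOTH_INTERNAL"
    if not s_ex and not e_ex:
        return "INTRONIC"
    return "AMBIGUOUS"


def _random_annotation(rng):
    genes = {}
    n_genes = int(rng.integers(1, 7))
    for k in range(n_genes):
        start = int(rng.integers(1, 1500))
        exons, pos = [], start
        for _ in range(int(rng.integers(1, 7))):
            length = int(rng.integers(5, 60))
            exons.append(cl.Exon(pos, pos + length - 1))
            pos += length + int(rng.integers(1, 40))
        gid = f"g{k}"
        strand = "+" if rng.integers(2) == 0 else "-"
        genes[gid] = cl.Gene(gid, "Chr1", strand, exons[0].start, exons[-1].end, exons)
    ann = cl.GenomeAnnotation({"Chr1": cl.Chromosome("Chr1", 5000)}, genes)
    ann.validate()
    return ann


def test_classification_matches_exhaustive_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(60):
        ann = _random_annotation(rng)
        for _ in range(20):
            a, b = sorted(rng.integers(1, 3000, size=2))
            if a == b:
                continue
            strand = "+" if rng.integers(2) == 0 else "-"
            j = _junction("Chr1", int(a), int(b), strand)
            got = cl.classify_bsj(j, ann).category.value
            assert got == _oracle_classify(j, ann), (j, got)
            checked += 1
    assert checked > 1000


# ---------------------------------------------------------------------------
# summarize_classes
# ---------------------------------------------------------------------------

def test_single_intergenic_record_is_100_percent(toy_annotation):
    rec = cl.classify_bsj(_junction("Chr2", 100, 400), toy_annotation)
    s = cl.summarize_classes([rec])
    assert s.percentages[Category.INTERGENIC] == 100.0
    assert s.exonic_count == 0


def test_empty_input_gives_empty_summary():
    s = cl.summarize_classes([])
    assert s.total == 0 and s.percentages == {}


def test_percentages_sum_to_100_and_counts_to_total(paper_records):
    s = cl.summarize_classes(paper_records)
    assert sum(s.counts.values()) == s.total == len(paper_records)
    assert abs(sum(s.percentages.values()) - 100.0) < 1e-9


def test_largest_remainder_is_close_to_true_share():
    rng = np.random.default_rng(3)
    for _ in range(50):
        counts = {k: int(v) for k, v in enumerate(rng.integers(0, 50, size=5))}
        total = sum(counts.values())
        if total == 0:
            continue
        pct = largest_remainder_percentages(counts, total)
        assert abs(sum(pct.values()) - 100.0) < 1e-9
        for k in counts:
            assert abs(pct[k] - 100.0 * counts[k] / total) <= 0.1 + 1e-9


# ---------------------------------------------------------------------------
# flag_novel
# ---------------------------------------------------------------------------

def test_empty_known_list_makes_everything_novel(paper_records):
    flagged = cl.flag_novel(paper_records, [])
    assert all(r.is_novel for r in flagged)


def test_slack_matches_nearby_known_entry(toy_annotation):
    rec = cl.classify_bsj(_junction("Chr1", 1201, 1700), toy_annotation)
    known = [("Chr1", 1202, 1699, "+")]  # offset by 1 nt
    assert cl.flag_novel([rec], known, slack=0)[0].is_novel
    assert not cl.flag_novel([rec], known, slack=2)[0].is_novel
    # strand must match regardless of slack
    assert cl.flag_novel([rec], [("Chr1", 1201, 1700, "-")], slack=5)[0].is_novel


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def test_single_exon_circ_equals_genomic_substring(toy_annotation, toy_genome):
    rec = cl.classify_bsj(_junction("Chr1", 1001, 1100), toy_annotation)
    seq, _ = cl.extract_circ_sequence(rec, toy_genome, toy_annotation)
    assert seq == toy_genome["Chr1"][1000:1100]
    assert len(seq) == 100


def test_intron_absent_from_spliced_circular_sequence(toy_annotation, toy_genome):
    rec = cl.classify_bsj(_junction("Chr1", 1001, 1300), toy_annotation)
    seq, _ = cl.extract_circ_sequence(rec, toy_genome, toy_annotation)
    manual = toy_genome["Chr1"][1000:1100] + toy_genome["Chr1"][1200:1300]
    assert seq == manual  # the 100 nt intron dropped out


def test_minus_strand_sequence_is_reverse_complement(toy_annotation, toy_genome):
    rec = cl.classify_bsj(_junction("Chr1", 3001, 3100, strand="-"), toy_annotation)
    seq, _ = cl.extract_circ_sequence(rec, toy_genome, toy_annotation)
    plus = toy_genome["Chr1"][3000:3100]
    comp = plus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    assert seq == comp


def test_junction_window_length_is_2k_minus_2(toy_annotation, toy_genome):
    rec = cl.classify_bsj(_junction("Chr1", 1001, 1300), toy_annotation)
    seq, window = cl.extract_circ_sequence(rec, toy_genome, toy_annotation, junction_window_k=22)
    assert len(window) == 42
    assert window == seq[-21:] + seq[:21]


def test_span_beyond_chromosome_raises(toy_annotation, toy_genome):
    rec = cl.CircRNARecord(
        _junction("Chr2", 4990, 50000), Category.INTERGENIC, None, 0, "nuclear"
    )
    with pytest.raises(ValueError, match="exceeds"):
        cl.extract_circ_sequence(rec, toy_genome, toy_annotation)
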
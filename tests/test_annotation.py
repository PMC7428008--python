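"""Gene-model loading, collapse, and fixed feature-window derivation."""

import pytest
from hypothesis import given, settings, strategies as st

from trcscan import _intervals as iv
from trcscan.annotation import (AnnotationError, GeneModel,
                                derive_feature_windows, load_genes,
                                write_windows_bed)

# ---------------------------------------------------------------------------
# feature windows


@pytest.mark.parametrize(
    "strand,tx_start,tx_end,tss,tts",
    [
        ("+", 1000, 5000, (950, 1300), (4950, 5200)),
        ("-", 1000, 5000, (4700, 5050), (800, 1050)),
    ],
)
def test_fixed_windows_strand_aware(strand, tx_start, tx_end, tss, tts):
    """TSS = −50/+300 and TTS = −50/+200 around the strand-aware gene ends."""
    gene = GeneModel("g", "chr1", strand, tx_start, tx_end,
                     exons=((tx_start, tx_end),))
    win = derive_feature_windows(gene, 10_000)
    assert win.tss_region == (tss,)
    assert win.tts_region == (tts,)
    assert sum(e - s for s, e in win.tss_region) == 350
    assert sum(e - s for s, e in win.tts_region) == 250


def test_tss_window_clipped_at_chromosome_start():
    gene = GeneModel("g", "chr1", "+", 20, 4000, exons=((20, 4000),))
    win = derive_feature_windows(gene, 10_000)
    assert win.tss_region == ((0, 320),)


def test_utrs_strand_aware(toy_genes, toy_chrom_sizes):
    """5'UTR is the exonic sequence between the TSS-side end and the CDS."""
    length = toy_chrom_sizes["chr1"]
    plus = derive_feature_windows(toy_genes[0], length)
    assert plus.utr5 == ((10_000, 10_500),)
    assert plus.utr3 == ((19_500, 20_000),)
    minus = derive_feature_windows(toy_genes[1], length)
    assert minus.utr5 == ((51_400, 52_000),)
    assert minus.utr3 == ((40_000, 40_600),)


def test_noncoding_gene_has_empty_utrs(toy_genes, toy_chrom_sizes):
    win = derive_feature_windows(toy_genes[2], toy_chrom_sizes["chr1"])
    assert win.utr5 == () and win.utr3 == ()
    assert iv.merge(win.exonic) == list(toy_genes[2].exons)


def test_transcript_span_partition(toy_genes, toy_chrom_sizes):
    """utr5 ∪ utr3 ∪ exonic ∪ intronic tiles the transcript span exactly."""
    for gene in toy_genes:
        win = derive_feature_windows(gene, toy_chrom_sizes["chr1"])
        union = iv.merge(list(win.utr5) + list(win.utr3)
                         + list(win.exonic) + list(win.intronic))
        assert union == [gene.span]
        # and the pieces are pairwise disjoint: lengths add up
        assert (iv.total_length(win.utr5) + iv.total_length(win.utr3)
                + iv.total_length(win.exonic) + iv.total_length(win.intronic)
                ) == gene.tx_end - gene.tx_start


@settings(deadline=None, max_examples=100, derandomize=True)
@given(tx_start=st.integers(500, 4000), length=st.integers(400, 3000),
       strand=st.sampled_from("+-"))
def test_mirror_symmetry(tx_start, length, strand):
    """Reflecting a gene about the chromosome midpoint and flipping strand
    maps its TSS window onto the reflected TSS window."""
    L = 10_000
    tx_end = tx_start + length
    gene = GeneModel("g", "chr1", strand, tx_start, tx_end,
                     exons=((tx_start, tx_end),))
    flipped = GeneModel("g", "chr1", "-" if strand == "+" else "+",
                        L - tx_end, L - tx_start,
                        exons=((L - tx_end, L - tx_start),))
    win = derive_feature_windows(gene, L)
    win_f = derive_feature_windows(flipped, L)
    reflect = sorted((L - e, L - s) for s, e in win.tss_region)
    assert reflect == sorted(win_f.tss_region)


# ---------------------------------------------------------------------------
# loading

BED12_ONE_GENE = ("chr1\t1000\t5000\tgX\t0\t+\t1200\t4800\t0\t2\t"
                  "500,1000,\t0,3000,\n")


def test_load_single_gene_no_sets(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text(BED12_ONE_GENE)
    genes = load_genes(p)
    assert len(genes) == 1
    g = genes[0]
    assert g.sets == frozenset()
    assert g.exons == ((1000, 1500), (4000, 5000))
    assert (g.cds_start, g.cds_end) == (1200, 4800)


def test_set_membership_is_a_union(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text(BED12_ONE_GENE)
    (tmp_path / "BRD4_JMJD6.txt").write_text("# comment\ngX\n")
    (tmp_path / "BRD4_CHD4.txt").write_text("gX\nnot_a_gene\n")
    with pytest.warns(UserWarning, match="not_a_gene|1 IDs"):
        genes = load_genes(p, {"BRD4_JMJD6": tmp_path / "BRD4_JMJD6.txt",
                               "BRD4_CHD4": tmp_path / "BRD4_CHD4.txt"})
    assert genes[0].sets == frozenset({"BRD4_JMJD6", "BRD4_CHD4"})


TWO_TX_GTF = """\
chr1\ttest\texon\t1001\t1500\t.\t+\t.\tgene_id "gY"; transcript_id "gY.1";
chr1\ttest\texon\t2001\t3000\t.\t+\t.\tgene_id "gY"; transcript_id "gY.1";
chr1\ttest\tCDS\t1101\t1500\t.\t+\t0\tgene_id "gY"; transcript_id "gY.1";
chr1\ttest\texon\t1201\t1600\t.\t+\t.\tgene_id "gY"; transcript_id "gY.2";
chr1\ttest\texon\t3501\t4000\t.\t+\t.\tgene_id "gY"; transcript_id "gY.2";
chr1\ttest\tCDS\t1301\t1600\t.\t+\t0\tgene_id "gY"; transcript_id "gY.2";
"""


def test_gtf_two_transcripts_collapse_to_union(tmp_path):
    """Union span [1000,4000), merged exons, CDS hull — hand-computed.

    GTF is 1-based inclusive: exon 1001-1500 is [1000,1500) internally.
    tx1 exons [1000,1500)+[2000,3000); tx2 [1200,1600)+[3500,4000);
    union = [1000,1600), [2000,3000), [3500,4000); CDS hull [1100,1600).
    """
    p = tmp_path / "genes.gtf"
    p.write_text(TWO_TX_GTF)
    genes = load_genes(p)
    assert len(genes) == 1
    g = genes[0]
    assert (g.tx_start, g.tx_end) == (1000, 4000)
    assert g.exons == ((1000, 1600), (2000, 3000), (3500, 4000))
    assert (g.cds_start, g.cds_end) == (1100, 1600)


def test_malformed_bed_names_line_number(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text(BED12_ONE_GENE + "chr1\t10\tnot_an_int\tg\n")
    with pytest.raises(AnnotationError, match="line 2"):
        load_genes(p)


def test_empty_annotation_is_an_error(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("# nothing here\n")
    with pytest.raises(AnnotationError, match="empty"):
        load_genes(p)


def test_windows_bed_round_trip(tmp_path, toy_genes, toy_chrom_sizes):
    out = tmp_path / "windows.bed"
    write_windows_bed(toy_genes, toy_chrom_sizes, out)
    lines = [l.split("\t") for l in out.read_text().splitlines()]
    assert all(len(f) == 6 for f in lines)
    # every toy gene contributes a 350-base TSS window
    tss = [f for f in lines if f[3].endswith(":tss_region")]
    assert len(tss) == len(toy_genes)
    assert all(int(f[2]) - int(f[1]) == 350 for f in tss)
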
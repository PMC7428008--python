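"""Gene models, gene-set membership, and fixed genomic feature windows.

A :class:`GeneModel` is the unit over which enrichment and read apportionment
are computed: one collapsed transcript span per gene (union of transcripts)
with merged exons and an optional CDS hull. Feature windows are the fixed,
strand-aware regions used for read classification:

* TSS region — 50 bp upstream to 300 bp downstream of the transcription
  start site (350 bp total, clipped at chromosome ends);
* TTS region — 50 bp upstream to 200 bp downstream of the transcript 3′ end
  (250 bp total);
* 5′/3′ UTR — exonic sequence between the transcript end and the CDS,
  strand-aware; empty for non-coding genes;
* exonic — exons minus UTRs; intronic — transcript span minus exons.

All coordinates are 0-based half-open. BED input is native; GTF (ENSEMBL
dialect) is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import _intervals as iv

TSS_UPSTREAM = 50
TSS_DOWNSTREAM = 300
TTS_UPSTREAM = 50
TTS_DOWNSTREAM = 200

#: Canonical gene-set names used by the simulator and the enrichment summary.
#: ``load_genes`` accepts arbitrary set names.
KNOWN_SETS = ("BRD4", "BRD4_JMJD6", "BRD4_CHD4")


class AnnotationError(ValueError):
    """Malformed or empty annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: collapsed transcript span, exon structure, set memberships."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int
    exons: Tuple[Tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    sets: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise AnnotationError(f"{self.gene_id}: tx_start must be < tx_end")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise AnnotationError(
                    f"{self.gene_id}: exon ({s},{e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.gene_id}: cds_start/cds_end must be paired")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise AnnotationError(f"{self.gene_id}: CDS outside transcript span")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> Tuple[int, int]:
        return (self.tx_start, self.tx_end)


@dataclass(frozen=True)
class FeatureWindows:
    """Strand-aware fixed windows and interval sets derived from one gene."""

    gene_id: str
    tss_region: Tuple[Tuple[int, int], ...]
    tts_region: Tuple[Tuple[int, int], ...]
    utr5: Tuple[Tuple[int, int], ...]
    utr3: Tuple[Tuple[int, int], ...]
    exonic: Tuple[Tuple[int, int], ...]
    intronic: Tuple[Tuple[int, int], ...]


def derive_feature_windows(gene: GeneModel, chrom_length: int) -> FeatureWindows:
    """Derive the fixed feature windows for one gene.

    Plus strand: TSS window = [tx_start−50, tx_start+300), TTS window =
    [tx_end−50, tx_end+200). Minus strand mirrors both (upstream is the
    larger-coordinate side). Windows are clipped to [0, chrom_length).
    Genes without a CDS get empty UTRs.
    """
    if chrom_length < gene.tx_end:
        raise AnnotationError(
            f"{gene.gene_id}: chrom_length {chrom_length} < tx_end {gene.tx_end}"
        )
    if gene.strand == "+":
        tss = [(gene.tx_start - TSS_UPSTREAM, gene.tx_start + TSS_DOWNSTREAM)]
        tts = [(gene.tx_end - TTS_UPSTREAM, gene.tx_end + TTS_DOWNSTREAM)]
    else:
        tss = [(gene.tx_end - TSS_DOWNSTREAM, gene.tx_end + TSS_UPSTREAM)]
        tts = [(gene.tx_start - TTS_DOWNSTREAM, gene.tx_start + TTS_UPSTREAM)]
    tss = iv.clip(tss, 0, chrom_length)
    tts = iv.clip(tts, 0, chrom_length)

    exons = list(gene.exons)
    if gene.has_cds:
        before = [(gene.tx_start, gene.cds_start)]  # low-coordinate side of CDS
        after = [(gene.cds_end, gene.tx_end)]
        if gene.strand == "+":
            utr5, utr3 = iv.intersect(exons, before), iv.intersect(exons, after)
        else:
            utr5, utr3 = iv.intersect(exons, after), iv.intersect(exons, before)
    else:
        utr5, utr3 = [], []

    exonic = iv.subtract(exons, utr5 + utr3)
    intronic = iv.subtract([gene.span], exons)
    return FeatureWindows(
        gene_id=gene.gene_id,
        tss_region=tuple(tss),
        tts_region=tuple(tts),
        utr5=tuple(utr5),
        utr3=tuple(utr3),
        exonic=tuple(exonic),
        intronic=tuple(intronic),
    )


# ---------------------------------------------------------------------------
# loading


def read_gene_sets(set_lists: Mapping[str, Path]) -> Dict[str, set]:
    """Read gene-set lists: one gene ID per line, '#' comments allowed."""
    out: Dict[str, set] = {}
    for name, path in set_lists.items():
        ids = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
        out[name] = ids
    return out


def _parse_bed12_line(line: str, lineno: int) -> dict:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise AnnotationError(f"line {lineno}: BED12 record has {len(f)} fields, need 12")
    try:
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: malformed BED12 record ({exc})") from exc
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise AnnotationError(f"line {lineno}: blockCount disagrees with block lists")
    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    cds = None if thick_start >= thick_end else (thick_start, thick_end)
    return dict(gene_id=name, chrom=chrom, strand=strand,
                start=start, end=end, exons=exons, cds=cds)


def _read_bed12(path: Path) -> List[dict]:
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        records.append(_parse_bed12_line(line, lineno))
    return records


def _read_gtf(path: Path) -> List[dict]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    per_tx: Dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            gene_id = feat.attributes.get("gene_id", [None])[0]
            tx_id = feat.attributes.get("transcript_id", [gene_id])[0]
            if gene_id is None:
                raise AnnotationError(f"GTF feature without gene_id: {feat}")
            rec = per_tx.setdefault(
                tx_id, dict(gene_id=gene_id, chrom=feat.seqid, strand=feat.strand,
                            exons=[], cds=[]))
            # gffutils keeps GFF 1-based inclusive coordinates; convert here
            interval = (feat.start - 1, feat.end)
            (rec["exons"] if ftype == "exon" else rec["cds"]).append(interval)
    records = []
    for rec in per_tx.values():
        exons = iv.merge(rec["exons"])
        if not exons:
            continue
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        records.append(dict(gene_id=rec["gene_id"], chrom=rec["chrom"],
                            strand=rec["strand"], start=exons[0][0],
                            end=exons[-1][1], exons=exons, cds=cds))
    return records


def _collapse(records: Sequence[dict], sets: Mapping[str, set]) -> List[GeneModel]:
    """Collapse per-transcript records to one GeneModel per gene.

    Transcript span = union span; exons = union of exons; CDS = min/max hull
    over coding transcripts. The gene must be single-chromosome, single-strand.
    """
    by_gene: Dict[str, List[dict]] = {}
    for rec in records:
        by_gene.setdefault(rec["gene_id"], []).append(rec)
    genes = []
    for gene_id in sorted(by_gene):
        recs = by_gene[gene_id]
        chroms = {r["chrom"] for r in recs}
        strands = {r["strand"] for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"{gene_id}: transcripts disagree on chromosome or strand")
        exons = iv.merge([e for r in recs for e in r["exons"]])
        cds_list = [r["cds"] for r in recs if r["cds"] is not None]
        cds = (min(c[0] for c in cds_list), max(c[1] for c in cds_list)) if cds_list else None
        membership = frozenset(n for n, ids in sets.items() if gene_id in ids)
        genes.append(GeneModel(
            gene_id=gene_id, chrom=chroms.pop(), strand=strands.pop(),
            tx_start=min(r["start"] for r in recs),
            tx_end=max(r["end"] for r in recs),
            exons=tuple(exons),
            cds_start=cds[0] if cds else None,
            cds_end=cds[1] if cds else None,
            sets=membership,
        ))
    return genes


def load_genes(
    annotation_path: Path | str,
    set_lists: Optional[Mapping[str, Path | str]] = None,
) -> List[GeneModel]:
    """Load gene models from BED12 or GTF and attach gene-set memberships.

    Multiple transcripts of one gene collapse to a single model (union span,
    union exons, CDS hull). Unknown IDs in set lists are reported with a
    warning, not fatal. Raises :class:`AnnotationError` on malformed records
    (with line number for BED) or an empty annotation.
    """
    path = Path(annotation_path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff"):
        records = _read_gtf(path)
    else:
        records = _read_bed12(path)
    if not records:
        raise AnnotationError(f"empty annotation: {path}")

    sets = read_gene_sets({k: Path(v) for k, v in (set_lists or {}).items()})
    genes = _collapse(records, sets)
    known = {g.gene_id for g in genes}
    for name, ids in sets.items():
        missing = sorted(ids - known)
        if missing:
            warnings.warn(
                f"gene set {name!r}: {len(missing)} IDs not in annotation "
                f"(e.g. {missing[:3]})", stacklevel=2)
    return genes


def write_windows_bed(
    genes: Iterable[GeneModel],
    chrom_sizes: Mapping[str, int],
    path: Path | str,
) -> None:
    """Write derived feature windows as BED6, feature class in the name column."""
    with open(path, "w") as fh:
        for gene in genes:
            win = derive_feature_windows(gene, chrom_sizes[gene.chrom])
            for category in ("tss_region", "utr5", "tts_region", "utr3",
                             "exonic", "intronic"):
                for s, e in getattr(win, category):
                    fh.write(f"{gene.chrom}\t{s}\t{e}\t"
                             f"{gene.gene_id}:{category}\t0\t{gene.strand}\n")
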
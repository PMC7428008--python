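"""Synthetic two-condition ChIP-seq experiment generator.

Emulates a paired DMSO/JQ1 design with four targets per condition — BRD4,
γH2AX, RNA polymerase II ser2, and whole-cell-extract input — on a small
multi-chromosome genome. Background read 5′ starts are uniform over the
genome; target libraries add enrichment reads over gene bodies (and, for
BRD4, concentrated at TSS windows) on top of that background. A configurable
subset of genes is "JQ1-responsive": γH2AX gains signal under JQ1 while BRD4
and RNAPII ser2 signal drops, mimicking DNA damage accumulating at genes
that lose productive elongation after bromodomain inhibition.

The generator is deterministic: a single integer seed drives one named
pseudo-random stream per purpose/library, so adding a library never perturbs
the reads of another. Every library holds exactly its configured depth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, derive_feature_windows

TARGETS = ("BRD4", "gH2AX", "RNAPII_ser2", "input")
CONDITIONS = ("DMSO", "JQ1")
GENE_CLASSES = ("responsive", "set_member", "other")

FoldKey = Tuple[str, str, str]  # (target, condition, gene class)


def default_enrichment_folds() -> Dict[FoldKey, float]:
    """Per-(target, condition, class) enrichment folds over background.

    Fold 1 means background-only. γH2AX gains 4-fold at responsive genes
    under JQ1 (vs 1 under DMSO, ratio 4 ≥ the 3× responsiveness floor);
    BRD4 and RNAPII ser2 drop under JQ1 at all regulated genes. Input is
    background-only everywhere.
    """
    folds: Dict[FoldKey, float] = {}
    for condition in CONDITIONS:
        for cls in GENE_CLASSES:
            for target in TARGETS:
                folds[(target, condition, cls)] = 1.0
    for cls in ("responsive", "set_member"):
        folds[("BRD4", "DMSO", cls)] = 4.0
        folds[("BRD4", "JQ1", cls)] = 1.5
        folds[("RNAPII_ser2", "DMSO", cls)] = 3.0
        folds[("RNAPII_ser2", "JQ1", cls)] = 1.2
    folds[("gH2AX", "JQ1", "responsive")] = 4.0
    return folds


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_500_000
    n_genes: int = 500
    gene_length: int = 5_000
    set_sizes: Dict[str, int] = field(default_factory=lambda: {
        "BRD4": 100, "BRD4_JMJD6": 150, "BRD4_CHD4": 120})
    n_responsive: int = 39
    background_rate: float = 0.5  # expected read 5' starts per bin per library
    bin_size: int = 25
    read_length: int = 36
    tss_fraction: float = 0.5  # share of BRD4 enrichment placed in TSS windows
    enrichment_fold: Dict[FoldKey, float] = field(
        default_factory=default_enrichment_folds)
    library_depths: Optional[Dict[str, int]] = None  # default: rate × n_bins
    targets: Tuple[str, ...] = TARGETS
    conditions: Tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("genome must have positive size")
        if self.n_genes <= 0:
            raise ValueError("need at least one gene")
        if self.n_responsive > self.n_genes:
            raise ValueError("n_responsive must be <= n_genes")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if any(f <= 0 for f in self.enrichment_fold.values()):
            raise ValueError("enrichment folds must be > 0")
        if self.library_depths is not None and any(
                d <= 0 for d in self.library_depths.values()):
            raise ValueError("library depths must be > 0")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def total_bins(self) -> int:
        return self.n_chroms * (-(-self.chrom_length // self.bin_size))

    @property
    def library_names(self) -> List[str]:
        return [f"{t}_{c}" for t in self.targets for c in self.conditions]

    def depth_of(self, library: str) -> int:
        if self.library_depths and library in self.library_depths:
            return int(self.library_depths[library])
        return int(round(self.background_rate * self.total_bins))


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]
    gene_sets: Dict[str, set]
    libraries: Dict[str, pd.DataFrame]  # library name -> BED-like read table
    truth: pd.DataFrame


def _stream(seed: int, name: str) -> np.random.Generator:
    """One named, stable random stream per purpose."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(zlib.crc32(name.encode()),))))


def _place_genes(config: SimulationConfig) -> List[GeneModel]:
    """Lay out non-overlapping 3-exon genes, evenly spread across chromosomes."""
    rng = _stream(config.seed, "annotation")
    chrom_names = list(config.chrom_sizes)
    per_chrom = -(-config.n_genes // config.n_chroms)
    slot = config.chrom_length // per_chrom
    if slot < config.gene_length + 1000:
        raise ValueError("genome too small for the requested gene layout")
    genes = []
    for i in range(config.n_genes):
        chrom = chrom_names[i // per_chrom]
        j = i % per_chrom
        margin = (slot - config.gene_length) // 2
        start = j * slot + margin
        end = start + config.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        L = config.gene_length
        # three exons of 15% each at 0/42.5/85% of the gene, CDS inside
        e1 = (start, start + int(0.15 * L))
        e2 = (start + int(0.425 * L), start + int(0.575 * L))
        e3 = (end - int(0.15 * L), end)
        cds_start = start + int(0.05 * L)
        cds_end = end - int(0.05 * L)
        genes.append(GeneModel(
            gene_id=f"G{i:04d}", chrom=chrom, strand=strand,
            tx_start=start, tx_end=end, exons=(e1, e2, e3),
            cds_start=cds_start, cds_end=cds_end))
    return genes


def _assign_sets(config: SimulationConfig,
                 genes: List[GeneModel]) -> Tuple[List[GeneModel], List[str]]:
    """Draw gene-set memberships and the responsive subset (from BRD4 members)."""
    rng = _stream(config.seed, "gene_sets")
    ids = [g.gene_id for g in genes]
    membership: Dict[str, set] = {}
    for name in sorted(config.set_sizes):
        size = min(config.set_sizes[name], len(ids))
        membership[name] = set(rng.choice(ids, size=size, replace=False))
    pool = sorted(membership.get("BRD4", set(ids))) or ids
    if len(pool) < config.n_responsive:
        extra = [i for i in ids if i not in pool]
        pool = pool + extra
    responsive = sorted(rng.choice(pool, size=config.n_responsive,
                                   replace=False))
    out = []
    for g in genes:
        sets = frozenset(n for n, m in membership.items() if g.gene_id in m)
        out.append(GeneModel(**{**asdict_gene(g), "sets": sets}))
    return out, list(responsive)


def asdict_gene(g: GeneModel) -> dict:
    return dict(gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                tx_start=g.tx_start, tx_end=g.tx_end, exons=g.exons,
                cds_start=g.cds_start, cds_end=g.cds_end, sets=g.sets)


def _gene_class(gene: GeneModel, responsive: set) -> str:
    if gene.gene_id in responsive:
        return "responsive"
    if gene.sets:
        return "set_member"
    return "other"


def _reads_frame(chroms: np.ndarray, five_prime: np.ndarray,
                 strand: np.ndarray, read_length: int,
                 chrom_sizes: Mapping[str, int], library: str) -> pd.DataFrame:
    """Build BED-like records from 5′ start positions.

    Plus read: [p, p+L); minus read: [p+1−L, p+1) so the 5′-most base is p
    on both strands. Intervals are clipped at chromosome ends (never moved).
    """
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    minus = strand == "-"
    start = np.where(minus, five_prime + 1 - read_length, five_prime)
    end = np.where(minus, five_prime + 1, five_prime + read_length)
    start = np.maximum(start, 0)
    end = np.minimum(end, lengths)
    df = pd.DataFrame({
        "chrom": chroms, "start": start, "end": end,
        "name": [f"{library}.{i}" for i in range(len(chroms))],
        "score": 0,
        "strand": np.where(minus, "-", "+"),
    })
    return df.sort_values(["chrom", "start", "end"], kind="stable",
                          ignore_index=True)


def simulate_library(config: SimulationConfig, library: str,
                     genes: List[GeneModel], responsive: set) -> pd.DataFrame:
    """Simulate one library: uniform background plus implanted enrichment."""
    target, condition = library.rsplit("_", 1)
    rng = _stream(config.seed, f"library:{library}")
    depth = config.depth_of(library)
    chrom_names = np.array(list(config.chrom_sizes))
    genome_len = config.n_chroms * config.chrom_length

    # expected enrichment reads per gene: bins_in_gene × rate × (fold − 1)
    weights = []
    for g in genes:
        fold = config.enrichment_fold.get(
            (target, condition, _gene_class(g, responsive)), 1.0)
        n_gene_bins = (g.tx_end - g.tx_start) / config.bin_size
        weights.append(n_gene_bins * config.background_rate * (fold - 1.0))
    weights = np.asarray(weights)
    n_enrich = int(round(weights.sum()))
    n_enrich = min(n_enrich, depth)
    n_background = depth - n_enrich

    # background: uniform 5' starts over the concatenated genome
    flat = rng.integers(0, genome_len, size=n_background)
    bg_chrom = chrom_names[flat // config.chrom_length]
    bg_pos = flat % config.chrom_length
    bg_strand = np.where(rng.random(n_background) < 0.5, "+", "-")

    parts = [(bg_chrom, bg_pos, bg_strand)]
    if n_enrich > 0:
        per_gene = rng.multinomial(n_enrich, weights / weights.sum())
        chroms, pos = [], []
        for g, n in zip(genes, per_gene):
            if n == 0:
                continue
            if target == "BRD4":
                # a share of BRD4 enrichment concentrates at the TSS window
                win = derive_feature_windows(
                    g, config.chrom_sizes[g.chrom]).tss_region[0]
                at_tss = rng.binomial(n, config.tss_fraction)
                pos.append(rng.integers(win[0], win[1], size=at_tss))
                pos.append(rng.integers(g.tx_start, g.tx_end, size=n - at_tss))
            else:
                pos.append(rng.integers(g.tx_start, g.tx_end, size=n))
            chroms.extend([g.chrom] * n)
        pos = np.concatenate(pos) if pos else np.empty(0, dtype=np.int64)
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        parts.append((np.array(chroms), pos, strand))

    chroms = np.concatenate([p[0] for p in parts])
    pos = np.concatenate([p[1] for p in parts]).astype(np.int64)
    strand = np.concatenate([p[2] for p in parts])
    return _reads_frame(chroms, pos, strand, config.read_length,
                        config.chrom_sizes, library)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate annotation, gene sets, read libraries, and the truth table."""
    genes = _place_genes(config)
    genes, responsive = _assign_sets(config, genes)
    responsive_set = set(responsive)

    libraries = {name: simulate_library(config, name, genes, responsive_set)
                 for name in config.library_names}

    rows = []
    for g in genes:
        cls = _gene_class(g, responsive_set)
        f = config.enrichment_fold
        h2ax = (f.get(("gH2AX", "JQ1", cls), 1.0)
                / f.get(("gH2AX", "DMSO", cls), 1.0))
        brd4 = (f.get(("BRD4", "JQ1", cls), 1.0), f.get(("BRD4", "DMSO", cls), 1.0))
        pol = (f.get(("RNAPII_ser2", "JQ1", cls), 1.0),
               f.get(("RNAPII_ser2", "DMSO", cls), 1.0))
        rows.append((g.gene_id, cls, h2ax,
                     "down" if brd4[0] < brd4[1] else "flat",
                     "down" if pol[0] < pol[1] else "flat"))
    truth = pd.DataFrame(rows, columns=[
        "gene_id", "class", "expected_h2ax_fold",
        "brd4_direction", "rnapii_direction"])

    gene_sets = {name: {g.gene_id for g in genes if name in g.sets}
                 for name in sorted(config.set_sizes)}
    return SimulatedExperiment(config=config, genes=genes,
                               chrom_sizes=config.chrom_sizes,
                               gene_sets=gene_sets, libraries=libraries,
                               truth=truth)


# ---------------------------------------------------------------------------
# serialization


def write_reads(library: pd.DataFrame, path: Path | str) -> None:
    """Write a read library as BED6; record count equals library depth."""
    library.to_csv(path, sep="\t", header=False, index=False)


def write_annotation_bed12(genes: List[GeneModel], path: Path | str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offsets = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
            thick = (g.cds_start, g.cds_end) if g.has_cds else (g.tx_start,
                                                                g.tx_start)
            fh.write("\t".join(map(str, [
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                thick[0], thick[1], 0, len(g.exons), sizes, offsets])) + "\n")


def write_experiment(exp: SimulatedExperiment, outdir: Path | str) -> Dict[str, Path]:
    """Write annotation, gene sets, chrom sizes, read BEDs, and truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["annotation"] = outdir / "genes.bed12"
    write_annotation_bed12(exp.genes, paths["annotation"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, length in exp.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    for name, ids in exp.gene_sets.items():
        p = outdir / f"set_{name}.txt"
        p.write_text("".join(f"{i}\n" for i in sorted(ids)))
        paths[f"set:{name}"] = p
    for name, lib in exp.libraries.items():
        p = outdir / f"{name}.bed"
        write_reads(lib, p)
        paths[f"reads:{name}"] = p
    paths["truth"] = outdir / "truth.tsv"
    exp.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def five_prime_positions(library: pd.DataFrame) -> pd.DataFrame:
    """5′-most base of each read (start for plus, end−1 for minus reads)."""
    minus = library["strand"].to_numpy() == "-"
    pos = np.where(minus, library["end"].to_numpy() - 1,
                   library["start"].to_numpy())
    return pd.DataFrame({"chrom": library["chrom"].to_numpy(), "pos": pos})
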
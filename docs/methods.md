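# Methods

## Scope and data model

`trcscan` quantifies where DNA damage (γH2AX), BRD4, and elongating RNAPII
(ser2 phosphorylated CTD) signal sits on the genome in a two-condition
ChIP-seq design (vehicle vs BET bromodomain inhibition), and complements
that with DRIP-qPCR R-loop quantification and DNA-fiber fork-speed
measurements. Alignment, duplicate marking, and peak calling are upstream
concerns handled by standard tools and are deliberately out of scope; the
package consumes aligned reads as BED6 intervals (optionally SAM/BAM via a
pysam adapter that keeps the forward mate of each properly-paired
fragment).

All genomic coordinates are 0-based half-open throughout. Genes with
multiple transcripts are collapsed to one model per gene: transcript span =
union span, exons = union of exons, CDS = min/max hull over coding
transcripts. Per-gene (not per-transcript) reporting is the reason for the
collapse; the union rule is this package's choice where the upstream
convention is not fixed, and the CDS hull is intersected with exons before
any UTR arithmetic so it never has to be exon-covered itself.

## Binned density model

Reads are extended to `extension` bases (default 200) from the 5′ end —
plus strand `[start, start+E)`, minus strand `[end−E, end)`, clipped at
chromosome ends — and tallied over `bin_size`-wide bins (default 25) tiling
each chromosome from coordinate 0; the final partial bin is kept. A bin
receives one event per extended read overlapping it by at least one base
(presence/absence, not base-fraction weighting: event counts are what a
Poisson background model applies to). For E divisible by B and no clipping,
a read covers exactly E/B bins when its 5′ start is grid-aligned and E/B+1
otherwise; this identity is tested exhaustively over all offsets.

Depth normalization multiplies every bin by `scale_per / depth` (default
one million; depth = reads supplied to the binner, not file line count, so
normalization always matches the counted population). Normalization is
flagged and cannot be applied twice; significance always runs on raw
counts, fold comparisons always on normalized tracks.

## Poisson background and gene calls

The background rate is estimated from the whole-cell-extract input library:
GLOBAL mode (default) takes the mean input events per bin scaled by
`target_depth / input_depth`; LOCAL mode applies the same scaling to a
sliding window mean (`scipy.ndimage.uniform_filter1d`). λ is floored at
`lambda_min` (default 0.1) to avoid degenerate zero-background bins. The
upper tail P(X ≥ k) is computed through the regularized incomplete gamma
function (`scipy.stats.poisson.sf`), which the tests hold to ≤1e-10
absolute against extended-precision pmf summation for λ ∈ {0.1, 1, 5, 20,
50}, k ≤ 200. Significance uses a fixed extreme threshold p ≤ 1e-9 with no
further multiple-testing correction — at that level the expected number of
false bins across a 10⁷-bin genome is ≪1, which the type-I control test
confirms empirically.

Gene-level calls score the gene span expanded by `flank` (default 2000 bp)
per side — a configurable choice, since whole-body vs promoter scoring is a
genuinely open design point. Fold change is
`(S_t + c)/(S_c + c)` with pseudocount `c` defaulting to the normalized
equivalent of one raw read in the shallower library; the call threshold is
strict (`fold > 2`). By default a call additionally requires ≥1
Poisson-significant bin in the raw treatment track inside the scored region
(`require_significant`), which suppresses fold-only artifacts at
low-coverage genes; it is a flag because fold-only calling is also
defensible.

## Sequential apportionment

Feature windows: TSS region = 50 bp upstream to 300 bp downstream of the
TSS; TTS region = 50 bp upstream to 200 bp downstream of the transcript 3′
end; both strand-aware (upstream is the larger-coordinate side on the minus
strand) and clipped at chromosome ends. 5′/3′ UTRs are the exonic sequence
between the transcript ends and the CDS; `exonic` excludes UTRs;
`intronic` is the span minus exons — together with the UTRs these tile the
transcript span exactly.

Classification is genome-wide, not per-gene: a read takes the first class
in TSS_region → UTR5 → TTS_region → UTR3 → exonic → intronic whose pooled
interval set (merged over all genes) it overlaps by ≥1 base, else
intergenic. The unextended read is used. The class counts partition the
library exactly; both properties are tested against an exhaustive per-read
oracle.

## qPCR model

Amplification efficiency is fixed at 2.0 per cycle by default (no standard
curves are modeled) and configurable. DRIP relative abundance per replicate
is `E^(Ct_input,adj − Ct_IP)` with `Ct_input,adj = Ct_input +
log_E(input_fraction)` so that an input well representing a fraction of the
template pool stands in for all of it (`input_fraction` defaults to 1 —
"equal amounts of template"). Replicates pair by replicate number, falling
back to the mean input Ct; aggregates are mean ± SEM. Undetermined Ct is
treated as signal absent (value 0, flagged), never imputed. RNase H
sensitivity is the treated/untreated ratio and is undefined (reported
absent) when the untreated value is 0. ΔΔCt expression requires an explicit
reference gene; per-treated-replicate folds are taken against the mean
control ΔCt, giving the replicate SEM of the fold.

## Fiber model

1 µm of combed DNA ≈ 2.59 kb. Both labels present (above a configurable
threshold, default 0 µm) → ongoing fork, speed = total tract kb / total
pulse minutes (default 20 + 20); an alternative per-label speed (mean of
each segment over its own pulse) sits behind a flag. First-label-only →
stalled; second-label-only → new origin; neither carries a speed, and both
are excluded from cohort mean speed, which is reported as mean ± SEM with
class fractions.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
not sequence-level reality: no FASTQ, mapping, GC bias, fragment-length
distribution, duplicates, or replicates. Defaults define the study
conditions: a 10-Mb genome (4 × 2.5 Mb), 500 non-overlapping 3-exon genes
of 5 kb, gene sets of 100/150/120 members (BRD4 / BRD4_JMJD6 / BRD4_CHD4),
39 responsive genes drawn from the BRD4 set, background rate 0.5 read
starts per 25-bp bin, 36-bp reads with Bernoulli(½) strand, and per-library
depth = rate × bins = 200,000 reads. Background 5′ starts are uniform over
the genome; enrichment reads are multinomial over genes with weight
`gene_bins × rate × (fold − 1)` and uniform within the gene span (half of
BRD4's enrichment concentrates in the TSS window). Default folds: BRD4 4 →
1.5 and RNAPII ser2 3 → 1.2 (DMSO → JQ1, at set members); γH2AX 1 → 4 at
responsive genes only; input flat. Library totals equal configured depth
exactly (enrichment reads displace background reads), so depth
normalization is exercised realistically.

One integer seed drives a named PCG64 stream per purpose
(annotation, gene sets, each library), so adding a library never perturbs
another — tested directly. Per-bin 5′-start counts in input libraries are
Poisson-calibrated (chi-square GOF at 10⁵ bins); note the per-bin
*extended-overlap* counts have a larger mean (≈ rate × (E + B − 1)/B, about
9× here), which is exactly what the background estimator measures from the
input track, keeping the significance model self-consistent.

What passing recovery tests show: under these conditions — well-separated
genes, uniform background, implanted fold 4 — the caller recovers ≥35/39
responders with zero false calls. Real data adds mappability structure,
copy-number variation, overlapping genes, and non-uniform input, none of
which the generator emulates; the tests validate the estimator's logic, not
its field performance.

## Problem sizes and numerical choices

The bundled analyses run the 500-gene / 8-library experiment (1.6 M reads)
for recovery and ten 10⁶-bin background-only libraries for the type-I
control — sizes chosen so the whole suite and the acceptance script each
finish in well under a minute of compute while keeping the bin-level
statistics in the regime the model assumes (λ ≈ 4.5–5). Binning uses an
integer difference-array (exact, no floating accumulation); bedGraph output
prints `%.10g` and round-trips raw integer counts exactly. Ties and
degenerate inputs: empty libraries produce valid empty outputs; genes
without CDS have empty UTRs (signal, not error); a read overlapping windows
of two genes in different classes takes the higher-priority class
(genome-wide rule); per-gene attribution breaks ties toward the
lexicographically smallest gene ID.

## Known limitations

- Headline gene counts from any real JQ1/DMSO experiment require that
  experiment's sequencing data and are not reproduced here; the synthetic
  recovery benchmark validates the method as a property of the estimator,
  not of any particular dataset.
- GLOBAL background ignores regional coverage structure; LOCAL mode exists
  but windows are not insert-size aware.
- The GTF reader handles the ENSEMBL dialect (gene_id/transcript_id
  attributes) only; full GFF3 is out of scope.
- Fold-change SEMs are not reported for gene calls (single-library design,
  no replicates), matching the upstream experiment's structure.
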
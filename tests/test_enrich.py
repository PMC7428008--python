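"""Poisson tail accuracy, background estimation, bin/gene enrichment calls."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trcscan.density import bin_counts, normalize_depth
from trcscan.enrich import (BackgroundModel, call_enriched_genes,
                            estimate_background, fold_enrichment, gene_signal,
                            poisson_upper_tail, significant_bins)
from .conftest import make_reads


def poisson_sf_decimal(k: int, lam: float, prec: int = 60) -> float:
    """Extended-precision oracle: P(X >= k) = 1 - sum_{i<k} pmf(i)."""
    getcontext().prec = prec
    lam_d = Decimal(str(lam))
    term = (-lam_d).exp()  # pmf(0)
    cdf = Decimal(0)
    for i in range(k):
        cdf += term
        term = term * lam_d / (i + 1)
    return float(Decimal(1) - cdf)


def test_poisson_whole_support():
    assert poisson_upper_tail(0, 0.0001) == 1.0
    assert poisson_upper_tail(0, 50) == 1.0


def test_poisson_closed_form_k1():
    assert poisson_upper_tail(1, 1.0) == pytest.approx(1 - math.exp(-1),
                                                       abs=1e-14)


@pytest.mark.parametrize("lam", [0.1, 1, 5, 20, 50])
def test_poisson_matches_pmf_summation(lam):
    for k in range(0, 60, 3):
        assert poisson_upper_tail(k, lam) == pytest.approx(
            poisson_sf_decimal(k, lam), abs=1e-10)


def test_poisson_rejects_bad_lambda():
    with pytest.raises(ValueError):
        poisson_upper_tail(3, 0.0)


# ---------------------------------------------------------------------------
# background estimation

SIZES = {"chr1": 10_000}


def _uniform_track(events_per_bin, depth):
    track = bin_counts(make_reads([]), SIZES)
    track.data["chr1"][:] = events_per_bin
    track.depth = depth
    return track


def test_global_background_uniform_input():
    bg = estimate_background(_uniform_track(4, 1000), target_depth=1000)
    assert bg.lam_global == 4.0


def test_background_scales_linearly_with_depth():
    bg1 = estimate_background(_uniform_track(4, 1000), target_depth=1000)
    bg2 = estimate_background(_uniform_track(4, 1000), target_depth=2000)
    assert bg2.lam_global == pytest.approx(2 * bg1.lam_global)


def test_local_background_equals_windowed_mean_oracle(rng):
    track = bin_counts(make_reads([]), SIZES)
    track.data["chr1"][:] = rng.poisson(5, size=track.data["chr1"].size)
    track.depth = 1000
    w = 11
    bg = estimate_background(track, target_depth=1000, mode="local",
                             window_bins=w, lambda_min=0.0)
    arr = track.data["chr1"].astype(float)
    n = arr.size
    oracle = np.array([
        arr[max(0, i - w // 2): min(n, i + w // 2 + 1)].sum()
        / w if 0 <= i - w // 2 and i + w // 2 < n else np.nan
        for i in range(n)])
    interior = ~np.isnan(oracle)
    np.testing.assert_allclose(bg.lam_local["chr1"][interior],
                               oracle[interior], rtol=1e-9)


def test_background_rejects_normalized_or_empty_track():
    with pytest.raises(ValueError):
        estimate_background(normalize_depth(_uniform_track(4, 1000)), 1000)
    empty = bin_counts(make_reads([]), SIZES)
    with pytest.raises(ValueError, match="empty"):
        estimate_background(empty, 1000)


# ---------------------------------------------------------------------------
# significant bins


def kstar(lam, alpha=1e-9):
    """Smallest count whose upper-tail probability is <= alpha (oracle)."""
    k = 0
    while poisson_sf_decimal(k, lam) > alpha:
        k += 1
    return k


def test_all_zero_track_has_no_significant_bins():
    track = bin_counts(make_reads([]), SIZES)
    out = significant_bins(track, BackgroundModel("global", lam_global=1.0))
    assert len(out) == 0


def test_significance_boundary_at_kstar():
    ks = kstar(1.0)
    track = bin_counts(make_reads([]), SIZES)
    track.data["chr1"][0] = ks - 1
    track.data["chr1"][1] = ks
    out = significant_bins(track, BackgroundModel("global", lam_global=1.0))
    by_bin = out.set_index("bin")["significant"]
    assert not by_bin[0]
    assert by_bin[1]


def test_significance_monotone_in_count_and_lambda():
    track = bin_counts(make_reads([]), SIZES)
    ks = kstar(2.0)
    track.data["chr1"][0] = ks
    assert significant_bins(
        track, BackgroundModel("global", lam_global=2.0))["significant"].all()
    track.data["chr1"][0] = ks + 5  # raising the count keeps the flag
    assert significant_bins(
        track, BackgroundModel("global", lam_global=2.0))["significant"].all()
    # raising lambda clears it
    assert not significant_bins(
        track, BackgroundModel("global", lam_global=100.0))["significant"].any()


def test_alpha_one_marks_every_nonzero_bin(rng):
    track = bin_counts(make_reads([]), SIZES)
    track.data["chr1"][:] = rng.poisson(1, track.data["chr1"].size)
    out = significant_bins(track, BackgroundModel("global", lam_global=1.0),
                           alpha=1.0)
    assert out["significant"].all()
    assert len(out) == int((track.data["chr1"] > 0).sum())


def test_normalized_track_rejected():
    track = normalize_depth(bin_counts(
        make_reads([("chr1", 0, 36, "+")]), SIZES))
    with pytest.raises(ValueError, match="raw"):
        significant_bins(track, BackgroundModel("global", lam_global=1.0))


def test_seeded_null_simulation_yields_zero_significant(rng):
    """1e5 bins at lambda=5: expected significant count ~1e-4, observed 0."""
    track = bin_counts(make_reads([]), {"chr1": 2_500_000})
    track.data["chr1"][:] = rng.poisson(5, track.data["chr1"].size)
    track.depth = 10
    out = significant_bins(track, BackgroundModel("global", lam_global=5.0))
    assert int(out["significant"].sum()) == 0


# ---------------------------------------------------------------------------
# gene signal and fold


def _normed_track(values):
    track = normalize_depth(
        bin_counts(make_reads([("chr1", 0, 36, "+")]), SIZES), 1.0)
    track.data["chr1"][:] = 0.0
    for b, v in values.items():
        track.data["chr1"][b] = v
    return track


def test_gene_signal_hand_summed_fixture():
    track = _normed_track({4: 2.5, 5: 1.5, 40: 7.0})
    # region [100, 150) covers bins 4 and 5 only
    assert gene_signal(track, [("chr1", 100, 150)]) == pytest.approx(4.0)
    assert gene_signal(track, [("chr1", 5000, 6000)]) == 0.0


def test_gene_signal_additive_over_disjoint_regions():
    track = _normed_track({0: 1.0, 10: 2.0, 20: 4.0})
    a = gene_signal(track, [("chr1", 0, 25)])
    b = gene_signal(track, [("chr1", 250, 275)])
    both = gene_signal(track, [("chr1", 0, 25), ("chr1", 250, 275)])
    assert both == pytest.approx(a + b)


def test_gene_signal_unknown_chromosome_errors():
    with pytest.raises(ValueError, match="unknown"):
        gene_signal(_normed_track({}), [("chr9", 0, 100)])


def test_fold_enrichment_examples():
    assert fold_enrichment(3.0, 3.0, 1e-9) == pytest.approx(1.0)
    assert fold_enrichment(10.0, 0.0, 1.0) == pytest.approx(11.0)


@settings(deadline=None, derandomize=True)
@given(base=st.floats(0, 1e6), delta=st.floats(0, 1e6))
def test_fold_monotone_in_treatment(base, delta):
    assert (fold_enrichment(base + delta, 5.0, 0.5)
            >= fold_enrichment(base, 5.0, 0.5))


# ---------------------------------------------------------------------------
# gene calling


def test_identical_tracks_call_nothing(toy_genes, toy_chrom_sizes, rng):
    rows = [("chr1", int(s), int(s) + 36, "+")
            for s in rng.integers(0, 99_000, size=2000)]
    raw = bin_counts(make_reads(rows), toy_chrom_sizes)
    normed = normalize_depth(raw)
    bg = estimate_background(raw, raw.depth)
    table, summary = call_enriched_genes(
        toy_genes, normed, normed, raw_treatment_track=raw, background=bg)
    assert summary["total_called"] == 0
    assert not table["called"].any()


def test_exact_twofold_not_called_at_strict_threshold(toy_genes,
                                                      toy_chrom_sizes):
    """Treatment exactly 2x control stays below the strict '>' threshold."""
    raw = bin_counts(make_reads([("chr1", 10_000, 10_036, "+")]),
                     toy_chrom_sizes)
    control = normalize_depth(raw, 1.0)
    # two duplicate reads normalized at scale 2 give exactly 2x the control
    treatment = normalize_depth(bin_counts(
        make_reads([("chr1", 10_000, 10_036, "+")] * 2), toy_chrom_sizes), 2.0)
    table, _ = call_enriched_genes(
        toy_genes[:1], treatment, control, require_significant=False,
        pseudocount=1e-12)
    assert table["fold_change"].iloc[0] == pytest.approx(2.0, rel=1e-9)
    assert not table["called"].iloc[0]


def test_mismatched_grids_error(toy_genes, toy_chrom_sizes):
    a = normalize_depth(bin_counts(make_reads([("chr1", 0, 36, "+")]),
                                   toy_chrom_sizes))
    b = normalize_depth(bin_counts(make_reads([("chr1", 0, 36, "+")]),
                                   toy_chrom_sizes, bin_size=50))
    with pytest.raises(ValueError, match="grid"):
        call_enriched_genes(toy_genes, a, b, require_significant=False)
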
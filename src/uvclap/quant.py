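"""Quantitative comparison of jointly amplified libraries.

Because signal and mock-control libraries are multiplexed before PCR
and sequenced together, raw event counts remain on a common scale:
the ratio of total crosslinking events between a pulldown and its
matched control is a direct library-wide enrichment measure, and
per-bin counts can be compared across replicates with little or no
normalization.  This module provides genomic binning, MA tables,
median-of-ratios size factors, correlations, relative standard
deviation, and a simple binomial enriched-bin caller used as plumbing
where a dedicated peak caller would run in production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentReport:
    signal_total: int
    control_total: int
    ratio: float
    infinite: bool = False


@dataclass
class NormalizationReport:
    """Per-library size factors from the median-of-ratios estimator.

    Orientation: a library with c-fold more material than the
    pseudo-reference (the per-bin geometric mean across libraries)
    receives factor c.
    """

    factors: pd.Series
    n_reference_bins: int


def bin_counts(
    events: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 100,
    stranded: bool = False,
) -> pd.Series:
    """Count events in fixed-width genomic bins anchored at 0.

    Each event falls in exactly one bin by its crosslink position, so
    bin totals conserve the library's event total.  Bins are
    strand-collapsed by default.  Returns a sparse Series indexed by
    (chrom, bin_start) — or (chrom, strand, bin_start) when stranded —
    holding only nonzero bins.
    """
    if events.empty:
        idx = ["chrom", "strand", "bin"] if stranded else ["chrom", "bin"]
        return pd.Series(
            dtype=int,
            index=pd.MultiIndex.from_arrays([[] for _ in idx], names=idx),
            name="count",
        )
    pos = events["crosslink_pos"].to_numpy()
    for chrom, grp in events.groupby("chrom"):
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"chromosome {chrom!r} not in sizes")
        beyond = grp[grp["crosslink_pos"] >= size]
        if len(beyond):
            rec = beyond.iloc[0]
            raise ValueError(
                f"event beyond chromosome end: {chrom}:{rec['crosslink_pos']} >= {size}"
            )
    binned = pd.DataFrame(
        {"chrom": events["chrom"], "bin": (pos // bin_size) * bin_size}
    )
    keys = ["chrom", "bin"]
    if stranded:
        binned["strand"] = events["strand"]
        keys = ["chrom", "strand", "bin"]
    counts = binned.groupby(keys).size().sort_index()
    counts.name = "count"
    return counts


def align_bins(*tracks: pd.Series) -> pd.DataFrame:
    """Outer-join binned tracks on their bin index, absent bins -> 0."""
    df = pd.concat(tracks, axis=1, join="outer").fillna(0)
    df.columns = [
        t.name if t.name not in (None, "count") else f"lib{i}"
        for i, t in enumerate(tracks)
    ]
    return df.astype(int)


def total_enrichment(
    signal_tracks: list[pd.DataFrame], control_tracks: list[pd.DataFrame]
) -> EnrichmentReport:
    """Library-wide signal-to-control ratio of total event counts.

    Signal replicates are combined, as are controls.  A zero control
    total yields an infinite ratio with a flag rather than a
    pseudocount (the raw ratio is the quantity of interest; use
    pseudocounts downstream if needed).
    """
    if not signal_tracks or not control_tracks:
        raise ValueError("need at least one signal and one control track")
    s = int(sum(len(t) for t in signal_tracks))
    c = int(sum(len(t) for t in control_tracks))
    if c == 0:
        return EnrichmentReport(s, c, math.inf, infinite=True)
    return EnrichmentReport(s, c, s / c)


def ma_table(
    bins_a: pd.Series, bins_b: pd.Series, min_events: int = 2
) -> pd.DataFrame:
    """Per-bin (mean log2 count, log2 fold change) for a replicate pair.

    Only bins covered by at least ``min_events`` events in *both*
    libraries enter the table; the median log2 fold change is attached
    as ``table.attrs['median_log2fc']``.  Uses raw counts: replicate
    pairs of a jointly amplified pool need no prior normalization.
    """
    df = align_bins(bins_a, bins_b)
    a, b = df.iloc[:, 0], df.iloc[:, 1]
    keep = (a >= min_events) & (b >= min_events)
    a, b = a[keep].astype(float), b[keep].astype(float)
    out = pd.DataFrame(
        {
            "mean_log2": 0.5 * (np.log2(a) + np.log2(b)),
            "log2fc": np.log2(a) - np.log2(b),
        }
    )
    out.attrs["median_log2fc"] = float(out["log2fc"].median()) if len(out) else float("nan")
    return out


def median_ratio_factors(counts: pd.DataFrame) -> NormalizationReport:
    """Median-of-ratios size factors across k >= 2 libraries.

    For each bin with a nonzero count in every library, the reference
    is the geometric mean across libraries; a library's factor is the
    median over bins of its count divided by the reference.  On
    noiseless data scaled by c in one library, that library's factor
    is exactly c (scale equivariance).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no bin has nonzero counts in all libraries; increase bin size"
        )
    sub = arr[nonzero]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    factors = pd.Series(
        np.median(ratios, axis=0), index=counts.columns, name="size_factor"
    )
    return NormalizationReport(factors=factors, n_reference_bins=int(nonzero.sum()))


def correlate(
    bins_a: pd.Series,
    bins_b: pd.Series,
    method: str = "spearman",
    min_events: int = 0,
    inclusion: str = "union",
) -> float:
    """Correlation of two binned tracks over included regions.

    ``inclusion='union'`` keeps every bin nonzero in either track
    (absent bins count 0); ``'either_min'`` keeps bins with at least
    ``min_events`` in at least one track; ``'both_min'`` requires it in
    both.  Fewer than 3 included regions is undefined (NaN).
    """
    df = align_bins(bins_a, bins_b)
    a, b = df.iloc[:, 0], df.iloc[:, 1]
    if inclusion == "union":
        keep = (a > 0) | (b > 0)
    elif inclusion == "either_min":
        keep = (a >= min_events) | (b >= min_events)
    elif inclusion == "both_min":
        keep = (a >= min_events) & (b >= min_events)
    else:
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    a, b = a[keep], b[keep]
    if len(a) < 3:
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def relative_std(counts) -> float:
    """Relative standard deviation in percent: 100 * sd / mean.

    Sample standard deviation (ddof=1).  A single value has no spread
    and returns 0 with a warning; a zero mean is undefined (NaN).
    """
    import warnings

    x = np.asarray(counts, dtype=float)
    if x.mean() == 0:
        return float("nan")
    if x.size < 2:
        warnings.warn("relative_std of a single value is 0 by convention")
        return 0.0
    return float(100.0 * x.std(ddof=1) / x.mean())


def call_enriched_bins(
    signal_bins: pd.Series,
    control_bins: pd.Series,
    factors: tuple[float, float] = (1.0, 1.0),
    min_fold: float = 2.0,
    min_events: int = 2,
    alpha: float = 0.05,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Simple binomial enriched-bin caller (plumbing peak caller).

    A bin qualifies when its normalized signal is at least ``min_fold``
    times the normalized control, carries at least ``min_events``
    signal events, and its one-sided binomial test (signal reads among
    signal+control at the bin, against the library-size expectation)
    survives Benjamini-Hochberg at ``alpha``.  Adjacent qualifying
    bins are merged into peaks (chrom, start, end, score = summed
    signal count).
    """
    df = align_bins(signal_bins, control_bins)
    s = df.iloc[:, 0].to_numpy(float)
    c = df.iloc[:, 1].to_numpy(float)
    fs, fc = factors
    ns, nc = s / fs, c / fc
    # expected signal share of a bin's reads under no enrichment, from
    # the normalized library scales
    p0 = (1.0 / fs) / (1.0 / fs + 1.0 / fc)
    n = (s + c).astype(int)
    pvals = stats.binom.sf(s.astype(int) - 1, n, p0)
    qvals = np.ones_like(pvals)
    tested = n > 0
    if tested.any():
        qvals[tested] = stats.false_discovery_control(pvals[tested], method="bh")
    with np.errstate(invalid="ignore"):
        thresh = min_fold * nc  # inf * 0 -> nan, treated as failing
    fold_ok = ~np.isnan(thresh) & (ns >= thresh)
    qualifies = fold_ok & (s >= min_events) & (qvals < alpha) & tested
    hits = df.index[qualifies]
    peaks = []
    for (chrom, b) , count in zip(hits, s[qualifies]):
        if peaks and peaks[-1][0] == chrom and peaks[-1][2] == b:
            peaks[-1][2] = b + bin_size
            peaks[-1][3] += count
        else:
            peaks.append([chrom, b, b + bin_size, count])
    return pd.DataFrame(peaks, columns=["chrom", "start", "end", "score"])


def event_total_concordance(
    pairs: list[tuple[pd.DataFrame, pd.DataFrame]]
) -> tuple[pd.DataFrame, float | None]:
    """Per-replicate-pair event totals and their Pearson correlation.

    With fewer than 3 pairs the totals table is still returned but the
    correlation is refused (None): two points always correlate
    perfectly.
    """
    totals = pd.DataFrame(
        [(len(a), len(b)) for a, b in pairs], columns=["replicate1", "replicate2"]
    )
    if len(pairs) < 3:
        return totals, None
    r = float(stats.pearsonr(totals["replicate1"], totals["replicate2"]).statistic)
    return totals, r
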
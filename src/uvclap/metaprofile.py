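"""Crosslink positioning relative to exon-exon junctions.

The exon junction complex (EJC) is deposited 20-30 nt upstream of
exon-exon junctions, so EJC components make good positional positive
controls: their crosslink histogram relative to junctions should peak
in that window, while a nonspecific control should be uniform.

Distance convention: position -1 is the last exonic nucleotide 5' of
the junction in transcript direction, +1 the first nucleotide of the
downstream exon; there is no position 0.  Events are counted in
genomic coordinates against the genomic junction flanks, once per
junction within the window (a nearest-junction mode is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def extract_junctions(gtf: pd.DataFrame | str) -> pd.DataFrame:
    """Unique exon-exon junctions from multi-exon transcripts.

    Returns a frame with ``chrom, strand, donor_end, acceptor_start``:
    ``donor_end`` is the half-open end of the 5' exon and
    ``acceptor_start`` the start of the 3' exon *in genomic
    coordinates* (for minus-strand transcripts the 5' exon is the
    rightmost one).  Junctions shared between transcripts are
    de-duplicated; single-exon transcripts contribute nothing.
    """
    from .annotate import read_gtf

    if not isinstance(gtf, pd.DataFrame):
        gtf = read_gtf(gtf)
    exons = gtf[gtf["Feature"] == "exon"]
    seen = set()
    rows = []
    for (_, chrom, strand), grp in exons.groupby(
        ["transcript_id", "Chromosome", "Strand"]
    ):
        ivs = sorted(zip(grp["Start"], grp["End"]))
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            key = (chrom, strand, e1, s2)
            if key not in seen:
                seen.add(key)
                rows.append(key)
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "left_exon_end", "right_exon_start"]
    ).sort_values(["chrom", "left_exon_end"]).reset_index(drop=True)


def junction_histogram(
    events: pd.DataFrame,
    junctions: pd.DataFrame,
    window: int = 200,
    mode: str = "per_junction",
) -> pd.DataFrame:
    """Histogram of signed crosslink-to-junction distances.

    Negative distances are upstream of the junction in transcript
    direction (the 5'-exon side), positive downstream; the domain is
    [-window, -1] + [+1, +window].  In ``per_junction`` mode (default)
    a crosslink near several junctions contributes once per junction;
    ``nearest`` keeps only its smallest-|distance| junction.
    Returns a two-column frame (distance, count) covering the full
    domain with zeros.
    """
    domain = [d for d in range(-window, window + 1) if d != 0]
    counts = {d: 0 for d in domain}
    if len(events) and len(junctions):
        contribs = []  # (event index, |distance|, distance)
        ev_by = {
            key: grp for key, grp in events.groupby(["chrom", "strand"])
        }
        for j in junctions.itertuples():
            grp = ev_by.get((j.chrom, j.strand))
            if grp is None:
                continue
            pos = grp["crosslink_pos"].to_numpy()
            if j.strand == "+":
                up_anchor, down_anchor = j.left_exon_end, j.right_exon_start
                d = np.where(
                    pos < up_anchor, pos - up_anchor, pos - down_anchor + 1
                )
                valid = (pos < up_anchor) | (pos >= down_anchor)
            else:
                # transcript direction runs right-to-left: upstream is
                # the rightmost exon (genomic right of the gap)
                up_anchor, down_anchor = j.right_exon_start, j.left_exon_end
                d = np.where(
                    pos >= up_anchor, up_anchor - pos - 1, down_anchor - pos
                )
                valid = (pos >= up_anchor) | (pos < down_anchor)
            sel = valid & (np.abs(d) <= window) & (d != 0)
            for i, dist in zip(grp.index[sel], d[sel]):
                contribs.append((i, abs(int(dist)), int(dist)))
        if mode == "nearest":
            best: dict[int, tuple[int, int]] = {}
            for i, ad, dist in contribs:
                if i not in best or ad < best[i][0]:
                    best[i] = (ad, dist)
            for ad, dist in best.values():
                counts[dist] += 1
        elif mode == "per_junction":
            for _, _, dist in contribs:
                counts[dist] += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {"distance": domain, "count": [counts[d] for d in domain]}
    )


def uniformity_statistic(
    profile: pd.DataFrame, rebin: int = 1
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of the profile against uniformity.

    ``rebin`` pools adjacent unit distances into wider bins before the
    test (useful to keep expected counts comfortably above ~5).  A
    profile with zero total is refused.
    """
    counts = profile["count"].to_numpy(dtype=float)
    if counts.sum() < 1:
        raise ValueError("empty profile: uniformity test needs at least one event")
    if rebin > 1:
        n = len(counts) // rebin * rebin
        counts = counts[:n].reshape(-1, rebin).sum(axis=1)
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)


def modal_bin(profile: pd.DataFrame) -> int:
    """Distance with the maximal count (ties: smallest distance)."""
    i = int(profile["count"].to_numpy().argmax())
    return int(profile["distance"].iloc[i])


def write_profile(profile: pd.DataFrame, path, window: int = 200) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# junction-relative crosslink histogram; distance -1 = last "
            "exonic nt 5' of the junction (transcript direction)\n"
        )
        profile.to_csv(fh, sep="\t", index=False)
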
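"""Crosslinking-event calling from uniquely aligned read pairs.

A crosslinking event is one captured RNA molecule: alignments sharing
the UMI and the start coordinates of both mates are PCR duplicates of
the same molecule and are collapsed into a single event whose
``read_count`` records the duplicate family size.  Events carrying
fewer than 10% of the reads of the strongest event at the same mapped
position are removed as spurious — UMI sequencing/amplification errors
create low-count sibling events at identical coordinates.

Alignments are handled as pandas DataFrames with columns
``read_id, chrom, strand, mate1_start, mate2_start, aln_length, umi,
multimap`` (0-based leftmost mate positions, fragment span in nt).
They can come from a SAM file (:func:`read_sam_pairs`; multi-mapping
detected through the aligner's ``XS:i`` auxiliary tag, a bowtie2
convention) or from the documented TSV table for aligner-free testing.

Coordinates are 0-based half-open throughout; BED is emitted natively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ALIGNMENT_COLUMNS = [
    "read_id", "chrom", "strand", "mate1_start", "mate2_start",
    "aln_length", "umi", "multimap",
]

EVENT_KEY = ["chrom", "strand", "mate1_start", "mate2_start", "umi"]
POSITION_KEY = ["chrom", "strand", "mate1_start", "mate2_start"]


def read_alignment_table(path) -> pd.DataFrame:
    """Read the documented TSV alignment table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    df["multimap"] = df["multimap"].astype(bool)
    return df


def read_sam_pairs(path, multimap_tag: str = "XS") -> pd.DataFrame:
    """Build the alignment table from a paired SAM/BAM file.

    Mates are joined by query name; a pair is flagged ``multimap`` when
    either mate carries the aligner's secondary-score tag (``XS:i`` for
    bowtie2).  The fragment span is taken from TLEN when set, else from
    the union of the mate intervals.
    """
    import pysam

    firsts, seconds = {}, {}
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            (firsts if aln.is_read1 else seconds)[aln.query_name] = {
                "ref": aln.reference_name,
                "start": aln.reference_start,
                "end": aln.reference_end,
                "tlen": abs(aln.template_length),
                "rev": aln.is_reverse,
                "xs": aln.has_tag(multimap_tag),
            }
    rows = []
    for name, m1 in firsts.items():
        m2 = seconds.get(name)
        if m2 is None:
            continue
        span = m1["tlen"] or (
            max(m1["end"], m2["end"]) - min(m1["start"], m2["start"])
        )
        umi = name.rsplit("_", 1)[1] if "_" in name else ""
        rows.append(
            (name, m1["ref"], "-" if m1["rev"] else "+",
             m1["start"], m2["start"], span, umi, m1["xs"] or m2["xs"])
        )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def filter_unique(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only uniquely mapped pairs (multimap == False), order preserved."""
    return records.loc[~records["multimap"].astype(bool)].reset_index(drop=True)


def collapse_to_events(
    records: pd.DataFrame, convention: str = "upstream"
) -> pd.DataFrame:
    """Collapse unique alignments into crosslinking events.

    One event per distinct (chrom, strand, mate1_start, mate2_start,
    umi); ``read_count`` is the group size.  Output is
    coordinate-sorted, hence independent of input order, and the
    operation is idempotent on its own output.
    """
    if records.empty:
        return pd.DataFrame(
            columns=EVENT_KEY + ["read_count", "crosslink_pos", "clamped"]
        )
    ev = (
        records.groupby(EVENT_KEY, sort=False, observed=True)
        .agg(read_count=("aln_length", "size"), aln_length=("aln_length", "min"))
        .reset_index()
        .sort_values(EVENT_KEY, kind="mergesort")
        .reset_index(drop=True)
    )
    pos, clamped = crosslink_position(ev, convention)
    ev["crosslink_pos"] = pos
    ev["clamped"] = clamped
    return ev


def crosslink_position(
    events: pd.DataFrame, convention: str = "upstream"
) -> tuple[np.ndarray, np.ndarray]:
    """Crosslink nucleotide coordinate for each event.

    ``upstream`` (default, the truncation-site convention of UV
    crosslink protocols): the nucleotide immediately 5' of the cDNA
    start — plus strand ``mate1_start - 1``; minus strand the half-open
    fragment end.  ``start``: the cDNA 5' terminal nucleotide itself.
    Negative positions are clamped to 0 and flagged.
    """
    left = np.minimum(events["mate1_start"], events["mate2_start"]).to_numpy()
    end = left + events["aln_length"].to_numpy()  # half-open fragment end
    plus = (events["strand"] == "+").to_numpy()
    if convention == "upstream":
        pos = np.where(plus, events["mate1_start"].to_numpy() - 1, end)
    elif convention == "start":
        pos = np.where(plus, events["mate1_start"].to_numpy(), end - 1)
    else:
        raise ValueError(f"unknown crosslink convention {convention!r}")
    clamped = pos < 0
    return np.where(clamped, 0, pos), clamped


def filter_spurious(events: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Remove spurious UMI-error events.

    Within each genomic position group (same chrom, strand and both
    mate starts; UMIs differ), drop events supported by strictly less
    than ``threshold`` times the reads of the strongest event there.
    The strongest event of a group always survives; threshold 0 is the
    identity.
    """
    if events.empty:
        return events
    gmax = events.groupby(POSITION_KEY, observed=True)["read_count"].transform("max")
    keep = events["read_count"] >= threshold * gmax
    return events.loc[keep].reset_index(drop=True)


def call_events(
    records: pd.DataFrame,
    spurious_threshold: float = 0.10,
    convention: str = "upstream",
) -> pd.DataFrame:
    """Full pipeline: unique filter, UMI collapse, spurious filter."""
    return filter_spurious(
        collapse_to_events(filter_unique(records), convention),
        spurious_threshold,
    )


def duplication_by_length(
    records: pd.DataFrame, events: pd.DataFrame, bin_width: int = 1
) -> pd.DataFrame:
    """Reads, events and duplicate fraction per alignment-length bin.

    The duplicate fraction ``1 - events/reads`` as a function of cDNA
    length exposes amplification length bias (typically an excess of
    duplicates for cDNAs around 40-60 nt); empty bins are omitted.
    """
    rbin = (records["aln_length"] // bin_width) * bin_width
    ebin = (events["aln_length"] // bin_width) * bin_width
    reads = rbin.value_counts().sort_index()
    evs = ebin.value_counts().sort_index()
    table = pd.DataFrame({"reads": reads, "events": evs}).fillna(0).astype(int)
    table = table[table["reads"] > 0]
    table["duplicate_fraction"] = 1.0 - table["events"] / table["reads"]
    table.index.name = "length_bin"
    return table.reset_index()


def events_to_bed(events: pd.DataFrame, path=None) -> pd.DataFrame:
    """BED6 representation: each crosslink nucleotide as a 1-nt interval.

    Score holds the event's read count.  Two events at the same
    position (distinct UMIs) produce two lines.  When ``path`` is
    given, writes the records with a header comment.
    """
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if events.empty:
        bed = pd.DataFrame(columns=cols)
    else:
        bed = pd.DataFrame(
            {
                "chrom": events["chrom"],
                "start": events["crosslink_pos"],
                "end": events["crosslink_pos"] + 1,
                "name": ".",
                "score": events["read_count"],
                "strand": events["strand"],
            }
        )
        bed = bed.sort_values(["chrom", "start", "strand"], kind="mergesort")
        bed = bed.reset_index(drop=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write("# uvclap crosslinking events (BED6; score = read count)\n")
            bed.to_csv(fh, sep="\t", header=False, index=False)
    return bed


def read_events_bed(path) -> pd.DataFrame:
    """Read a BED6 event track back into an event-like frame."""
    bed = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "crosslink_pos": bed["start"],
            "read_count": bed["score"],
        }
    )
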
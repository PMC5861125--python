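"""Peak annotation, standardization and comparison.

Target-class assignment follows a fixed single-label priority:
``rRNA > ncRNA > pseudogene > 3UTR > 5UTR > exon > intron > antisense
> intergenic``.  A peak takes the highest-priority class among
same-strand features it overlaps by at least one nucleotide; a peak
overlapping genes only on the opposite strand is ``antisense``; a peak
overlapping nothing is ``intergenic``.

For cross-method comparisons, peak sets are standardized (extended to
a minimum length of 41 nt and merged when overlapping or abutting)
before overlaps, proximity to control reads and IUPAC consensus-motif
occurrence are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .barcode_design import IUPAC, revcomp

PRIORITY = [
    "rRNA", "ncRNA", "pseudogene", "3UTR", "5UTR",
    "exon", "intron", "antisense", "intergenic",
]

#: GTF gene_biotype -> target class for gene-level classes.  Any
#: biotype not listed and not protein_coding counts as ncRNA.
BIOTYPE_CLASS = {
    "rRNA": "rRNA",
    "rRNA_pseudogene": "rRNA",
    "Mt_rRNA": "rRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
}


@dataclass
class AnnotationIndex:
    """Strand-aware interval index over classified features.

    ``trees[(chrom, strand, cls)]`` holds an IntervalTree of the
    features of one class; ``gene_trees[(chrom, strand)]`` indexes
    gene bodies for the antisense fallback.
    """

    trees: dict = field(default_factory=dict)
    gene_trees: dict = field(default_factory=dict)
    chrom_sizes: dict = field(default_factory=dict)

    def add(self, chrom, strand, cls, start, end) -> None:
        if end <= start:
            return
        self.trees.setdefault((chrom, strand, cls), IntervalTree()).addi(start, end)

    def add_gene(self, chrom, strand, start, end) -> None:
        self.gene_trees.setdefault((chrom, strand), IntervalTree()).addi(start, end)

    def overlaps(self, chrom, strand, cls, start, end) -> bool:
        tree = self.trees.get((chrom, strand, cls))
        return bool(tree and tree.overlap(start, end))

    def overlaps_gene(self, chrom, strand, start, end) -> bool:
        tree = self.gene_trees.get((chrom, strand))
        return bool(tree and tree.overlap(start, end))


def read_gtf(path) -> pd.DataFrame:
    """GTF as a 0-based half-open DataFrame (pyranges dialect)."""
    import pyranges as pr

    return pr.read_gtf(str(path)).df


def build_annotation_index(
    gtf: pd.DataFrame | str,
    chrom_sizes: dict[str, int] | None = None,
    biotype_class: dict[str, str] = BIOTYPE_CLASS,
) -> AnnotationIndex:
    """Classify GTF features and index them for priority lookup.

    Gene-level classes (rRNA, ncRNA, pseudogene) come from the
    ``gene_biotype`` attribute; 3'/5'-UTRs from UTR features; exon
    from exon features of protein-coding genes; introns are derived as
    gene body minus exons.
    """
    if not isinstance(gtf, pd.DataFrame):
        gtf = read_gtf(gtf)
    idx = AnnotationIndex(chrom_sizes=dict(chrom_sizes or {}))
    genes = gtf[gtf["Feature"] == "gene"]
    biotypes = {}
    for g in genes.itertuples():
        bt = getattr(g, "gene_biotype", "protein_coding")
        biotypes[g.gene_id] = bt
        idx.add_gene(g.Chromosome, g.Strand, g.Start, g.End)
        if bt == "protein_coding":
            continue
        cls = biotype_class.get(bt, "ncRNA")
        idx.add(g.Chromosome, g.Strand, cls, g.Start, g.End)
    for f in gtf[gtf["Feature"].isin(["three_prime_utr", "3UTR"])].itertuples():
        idx.add(f.Chromosome, f.Strand, "3UTR", f.Start, f.End)
    for f in gtf[gtf["Feature"].isin(["five_prime_utr", "5UTR"])].itertuples():
        idx.add(f.Chromosome, f.Strand, "5UTR", f.Start, f.End)

    exons = gtf[gtf["Feature"] == "exon"]
    exon_by_gene: dict[str, list] = {}
    for e in exons.itertuples():
        if biotypes.get(e.gene_id, "protein_coding") != "protein_coding":
            continue
        idx.add(e.Chromosome, e.Strand, "exon", e.Start, e.End)
        exon_by_gene.setdefault(e.gene_id, []).append((e.Chromosome, e.Strand, e.Start, e.End))
    # introns: protein-coding gene body minus the union of its exons
    for g in genes.itertuples():
        if biotypes.get(g.gene_id) != "protein_coding":
            continue
        ivs = sorted((s, e) for _, _, s, e in exon_by_gene.get(g.gene_id, []))
        cursor = g.Start
        for s, e in ivs:
            if s > cursor:
                idx.add(g.Chromosome, g.Strand, "intron", cursor, s)
            cursor = max(cursor, e)
        if cursor < g.End:
            idx.add(g.Chromosome, g.Strand, "intron", cursor, g.End)
    return idx


def assign_target_class(peak, index: AnnotationIndex) -> str:
    """Single-label priority classification of one peak.

    ``peak`` needs chrom, start, end, strand attributes (namedtuple /
    itertuples row / dataclass).  Same-strand feature overlap of >= 1
    nt decides among the first seven classes; opposite-strand gene
    overlap alone gives ``antisense``; otherwise ``intergenic``.
    """
    chrom, start, end, strand = peak.chrom, peak.start, peak.end, peak.strand
    size = index.chrom_sizes.get(chrom)
    if start < 0 or (size is not None and end > size):
        raise ValueError(f"peak outside chromosome bounds: {chrom}:{start}-{end}")
    for cls in PRIORITY[:7]:
        if strand in ("+", "-"):
            if index.overlaps(chrom, strand, cls, start, end):
                return cls
        else:  # unstranded peak: either strand counts as sense
            if index.overlaps(chrom, "+", cls, start, end) or index.overlaps(
                chrom, "-", cls, start, end
            ):
                return cls
    if strand in ("+", "-"):
        anti = "-" if strand == "+" else "+"
        if index.overlaps_gene(chrom, anti, start, end):
            return "antisense"
    return "intergenic"


def classify_peaks(peaks: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Class label per peak plus a Fig-3-style per-class count table."""
    labels = [assign_target_class(p, index) for p in peaks.itertuples()]
    out = peaks.copy()
    out["target_class"] = labels
    return out


def class_counts(assigned: pd.DataFrame) -> pd.Series:
    counts = assigned["target_class"].value_counts()
    return counts.reindex(PRIORITY, fill_value=0)


def standardize_and_merge(
    peaks: pd.DataFrame, min_len: int = 41, merge_gap: int = 0
) -> pd.DataFrame:
    """Extend peaks to >= ``min_len`` nt and merge overlapping/abutting ones.

    Short peaks are extended symmetrically about their midpoint; when
    the needed extension is odd the extra base goes 3' (right for plus
    or unstranded peaks, left for minus).  Intervals separated by at
    most ``merge_gap`` (default 0 = abutting) are merged.  Idempotent:
    output intervals are >= min_len, sorted, pairwise non-adjacent.
    Strand is dropped on merge output (cross-method universes are
    unstranded); coordinates are clamped at 0.
    """
    if peaks.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for p in peaks.itertuples():
        start, end = int(p.start), int(p.end)
        length = end - start
        if length < min_len:
            deficit = min_len - length
            left = deficit // 2
            right = deficit - left
            strand = getattr(p, "strand", "+")
            if strand == "-":
                left, right = right, left
            start, end = start - left, end + right
            if start < 0:
                end -= start
                start = 0
        rows.append((p.chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start", "end"]
    )
    merged = []
    for chrom, grp in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for _, s, e in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + merge_gap:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def overlap_sets(*peak_sets: pd.DataFrame, labels=None) -> pd.DataFrame:
    """Venn-style region counts over 2-3 standardized peak sets.

    The universe is the merge of all sets; each universe region is
    attributed to every set with >= 1 nt of overlap.  Returns a table
    of membership combinations and region counts; counts partition the
    universe.
    """
    k = len(peak_sets)
    if k not in (2, 3):
        raise ValueError("overlap_sets takes 2 or 3 peak sets")
    labels = list(labels) if labels else [f"set{i+1}" for i in range(k)]
    universe = standardize_and_merge(
        pd.concat(peak_sets, ignore_index=True)[["chrom", "start", "end"]],
        min_len=0,
    )
    trees = []
    for ps in peak_sets:
        t: dict[str, IntervalTree] = {}
        for p in ps.itertuples():
            if p.end > p.start:
                t.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        trees.append(t)
    combos: dict[tuple[bool, ...], int] = {}
    for r in universe.itertuples():
        member = tuple(
            bool(t.get(r.chrom) and t[r.chrom].overlap(r.start, r.end))
            for t in trees
        )
        combos[member] = combos.get(member, 0) + 1
    rows = [
        {**{labels[i]: m[i] for i in range(k)}, "regions": n}
        for m, n in sorted(combos.items(), reverse=True)
    ]
    return pd.DataFrame(rows)


def peak_control_proximity(
    peaks: pd.DataFrame, control_reads: pd.DataFrame, distance: int = 50
) -> float:
    """Fraction of peaks farther than ``distance`` nt from any control read.

    Distance is the edge-to-edge gap between half-open intervals
    (number of intervening nucleotides); overlap counts as gap 0.
    Strictly greater than ``distance`` counts as far.  With no control
    reads every peak is far (fraction 1.0).
    """
    if peaks.empty:
        return float("nan")
    if control_reads.empty:
        return 1.0
    by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in control_reads.groupby("chrom")
    }
    far = 0
    for p in peaks.itertuples():
        ivs = by_chrom.get(p.chrom)
        if ivs is None:
            far += 1
            continue
        starts, ends = ivs[:, 0], ivs[:, 1]
        # intervening nucleotides between half-open intervals; overlap -> 0
        gaps = np.maximum(np.maximum(starts - p.end, p.start - ends), 0)
        if gaps.min() > distance:
            far += 1
    return far / len(peaks)


def iupac_regex(motif: str) -> "re.Pattern":
    import re

    motif = motif.upper().replace("U", "T")
    parts = []
    for c in motif:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in motif")
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def motif_occurrence(
    peaks: pd.DataFrame, genome, motif: str
) -> tuple[int, float]:
    """Peaks containing >= 1 match of an IUPAC consensus motif.

    ``genome`` is a mapping chrom -> sequence (plain dict or a
    ``pyfaidx.Fasta``).  Each peak's strand-oriented sequence (reverse
    complement for minus strand) is scanned; U in the motif is read as
    T.  Returns (number of peaks with a match, fraction over peaks).
    """
    if peaks.empty:
        return 0, float("nan")
    rx = iupac_regex(motif)
    hits = 0
    for p in peaks.itertuples():
        seq = genome[p.chrom]
        length = len(seq)
        if p.start < 0 or p.end > length:
            raise ValueError(f"peak beyond sequence bounds: {p.chrom}:{p.start}-{p.end}")
        sub = str(seq[p.start : p.end]).upper()
        if getattr(p, "strand", "+") == "-":
            sub = revcomp(sub)
        if rx.search(sub):
            hits += 1
    return hits, hits / len(peaks)
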
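"""Tri-barcode decoding and FASTQ demultiplexing.

Mate 1 carries the 5' barcode block ``NNNTTTTTNN`` (three random bases,
the five-base condition tag, two random bases); mate 2 starts with the
five-base semi-random replicate tag.  Decoding corrects up to one
substitution or indel in the condition tag (the codebook's minimum
Levenshtein distance of 3 guarantees unique nearest-neighbour
decoding) and up to one position-class violation in the replicate
pattern (the two default patterns differ in class at four positions).

The UMI used for duplicate collapse is, by default, the five 5' random
bases concatenated with the realized 3' semi-random 5-mer — both
contribute to the per-position event capacity.  A 5'-only mode is
available for protocols that treat the 3' tag as replicate label only.
"""

from __future__ import annotations

import gzip
import os
from collections import Counter
from dataclasses import dataclass, field

import edlib

from .barcode_design import BarcodeLayout, IUPACPattern, TagSet

UNASSIGNED = "UNASSIGNED"


@dataclass
class ReadPair:
    read_id: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual) or len(self.mate2_seq) != len(
            self.mate2_qual
        ):
            raise ValueError(f"seq/qual length mismatch for {self.read_id}")


@dataclass(frozen=True)
class LibraryKey:
    """Identity of one multiplexed library."""

    condition_tag: str
    replicate_pattern: str  # pattern string, e.g. "DRYYR"
    size_fraction: str = ""  # e.g. "L", "M", "H" (from the PCR index / sample sheet)


@dataclass
class DecodedRead:
    read_id: str
    library: LibraryKey | str  # LibraryKey or UNASSIGNED
    umi: str
    insert1: str
    insert1_qual: str
    insert2: str
    insert2_qual: str
    edits_used: int = 0
    reason: str = ""


@dataclass
class DemuxStats:
    per_library: Counter = field(default_factory=Counter)
    unassigned: int = 0
    edit_histogram: Counter = field(default_factory=Counter)
    unassigned_reasons: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.per_library.values()) + self.unassigned


def parse_architecture(pair: ReadPair, layout: BarcodeLayout):
    """Positional split of the raw mates into barcode fields and inserts.

    Returns ``(tag5, random5, tag3, raw_insert1, raw_insert2)`` where
    ``random5`` concatenates the random positions of the 5' block in
    read order.  Raises ValueError when a mate is shorter than its
    barcode prefix (callers route such pairs to UNASSIGNED).
    """
    p5 = layout.prefix_length
    p3 = len(layout.three_prime_pattern) if layout.three_prime_pattern else 0
    if len(pair.mate1_seq) < p5:
        raise ValueError("mate1 shorter than 5' barcode block")
    if len(pair.mate2_seq) < p3:
        raise ValueError("mate2 shorter than 3' tag")
    prefix = pair.mate1_seq[:p5]
    tag5 = prefix[layout.tag_slice]
    random5 = "".join(
        b for b, c in zip(prefix, layout.five_prime_layout) if c == "N"
    )
    tag3 = pair.mate2_seq[:p3]
    return tag5, random5, tag3, pair.mate1_seq[p5:], pair.mate2_seq[p3:]


def correct_tag(
    observed: str, codebook: TagSet, max_edits: int = 1
) -> tuple[str, int]:
    """Nearest-neighbour decode of an observed condition tag.

    Returns ``(tag, edits)`` for the unique codebook tag within
    ``max_edits`` Levenshtein edits, else ``(UNASSIGNED, -1)``.  Ties
    (possible only when the codebook's distance guarantee is weaker
    than ``2*max_edits + 1``) are unassigned.
    """
    best, best_d, tie = None, max_edits + 1, False
    for tag in codebook.tags:
        d = edlib.align(observed, tag, mode="NW", task="distance",
                        k=max_edits)["editDistance"]
        if d < 0:  # beyond k
            continue
        if d < best_d:
            best, best_d, tie = tag, d, False
        elif d == best_d:
            tie = True
    if best is None or tie:
        return UNASSIGNED, -1
    return best, best_d


def assign_pattern(
    observed: str, patterns: list[IUPACPattern], max_mismatch: int = 1
) -> str:
    """Assign a 5-mer to the unique pattern with <= max_mismatch class violations.

    The default patterns (DRYYR, DYRRY) disagree in base class at four
    positions, so a wrong assignment needs four substitutions; one
    violation still decodes uniquely.
    """
    hits = [
        p for p in patterns
        if len(observed) == len(p) and p.mismatches(observed) <= max_mismatch
    ]
    if len(hits) != 1:
        return UNASSIGNED
    return hits[0].pattern


def clip_readthrough(
    insert1: str,
    insert2: str,
    layout: BarcodeLayout,
    qual1: str = "",
    qual2: str = "",
):
    """Remove barcode read-through from the 3' ends of both inserts.

    ``clip_mate1`` bases leave mate 1 (the 3' semi-random tag length),
    ``clip_mate2`` bases leave mate 2 (5' tag + UMI length).  The
    clipped genomic sequence, if any, is still present on the other
    mate.  Qualities are clipped in lockstep.
    """
    c1 = min(layout.clip_mate1, len(insert1))
    c2 = min(layout.clip_mate2, len(insert2))
    i1 = insert1[: len(insert1) - c1]
    i2 = insert2[: len(insert2) - c2]
    q1 = qual1[: len(i1)]
    q2 = qual2[: len(i2)]
    return i1, i2, q1, q2


def decode_read(
    pair: ReadPair,
    codebook: TagSet,
    patterns: list[IUPACPattern],
    layout: BarcodeLayout,
    max_edits: int = 1,
    max_pattern_mismatch: int = 1,
    umi_mode: str = "both",
) -> DecodedRead:
    """Full tri-barcode decode of one read pair.

    When the condition tag is corrected through an indel, the 5'
    block boundary shifts by the indel length; the block is re-sliced
    by trying prefix windows one base shorter and longer than nominal
    and keeping the best-scoring decode (ties favour the nominal
    window).
    """
    try:
        tag5, random5, tag3, raw1, raw2 = parse_architecture(pair, layout)
    except ValueError as exc:
        return DecodedRead(
            pair.read_id, UNASSIGNED, "", "", "", "", "",
            reason=str(exc),
        )

    # Decode the condition tag from windows one base shorter and longer
    # than nominal as well: an indel inside the tag shifts the boundary,
    # and the shifted window is then the one within correction radius.
    # Ties prefer the nominal window (substitution errors dominate).
    start = layout.tag_slice.start
    taglen = layout.tag_length
    n_after = layout.prefix_length - layout.tag_slice.stop
    tag, edits, best_delta = UNASSIGNED, -1, 0
    for delta in (0, -1, 1):
        w = pair.mate1_seq[start : start + taglen + delta]
        cand, e = correct_tag(w, codebook, max_edits)
        if cand is not UNASSIGNED and (tag is UNASSIGNED or e < edits):
            tag, edits, best_delta = cand, e, delta
    if best_delta != 0 and tag is not UNASSIGNED:
        # re-slice: the whole downstream read shifts with the boundary
        stop = start + taglen + best_delta
        random5 = pair.mate1_seq[:start] + pair.mate1_seq[stop : stop + n_after]
        raw1 = pair.mate1_seq[stop + n_after :]
    if tag is UNASSIGNED:
        return DecodedRead(
            pair.read_id, UNASSIGNED, "", "", "", "", "",
            reason="condition tag beyond correction radius",
        )

    pat = assign_pattern(tag3, patterns, max_pattern_mismatch)
    if pat is UNASSIGNED:
        return DecodedRead(
            pair.read_id, UNASSIGNED, "", "", "", "", "",
            reason="replicate pattern unassigned",
        )

    q1 = pair.mate1_qual[len(pair.mate1_seq) - len(raw1):]
    q2 = pair.mate2_qual[len(pair.mate2_seq) - len(raw2):]
    i1, i2, q1, q2 = clip_readthrough(raw1, raw2, layout, q1, q2)
    umi = random5 + tag3 if umi_mode == "both" else random5
    return DecodedRead(
        pair.read_id,
        LibraryKey(condition_tag=tag, replicate_pattern=pat),
        umi, i1, q1, i2, q2, edits_used=edits,
    )


def _open_maybe_gz(path, mode="rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(fastq1, fastq2):
    """Iterate ReadPair objects from two (optionally gzipped) FASTQ files."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gz(fastq1) as f1, _open_maybe_gz(fastq2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = id1.split()[0].removesuffix("/1")
            yield ReadPair(rid, s1, q1, s2, q2)


def read_sample_sheet(path):
    """TSV with columns library_name, condition_tag, replicate_pattern,
    size_fraction, pcr_index (last two optional)."""
    import pandas as pd

    sheet = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"library_name", "condition_tag", "replicate_pattern"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def demultiplex_fastq(
    fastq1,
    fastq2,
    codebook: TagSet,
    patterns: list[IUPACPattern],
    layout: BarcodeLayout,
    sample_sheet,
    out_dir,
    umi_mode: str = "both",
    umi_delimiter: str = "_",
    max_edits: int = 1,
) -> DemuxStats:
    """Split a multiplexed FASTQ pair into per-library pairs.

    ``sample_sheet`` is a DataFrame (see :func:`read_sample_sheet`)
    mapping (condition_tag, replicate_pattern) to library names.  Each
    input pair lands in exactly one library or in the UNASSIGNED pair;
    the extracted UMI is appended to the read name.  Returns counting
    statistics whose totals conserve the input read count.
    """
    import pandas as pd

    if isinstance(sample_sheet, (str, os.PathLike)):
        sample_sheet = read_sample_sheet(sample_sheet)
    known = set(codebook.tags)
    bad = set(sample_sheet["condition_tag"]) - known
    if bad:
        raise ValueError(f"sample sheet references unknown tags: {sorted(bad)}")
    pattern_ids = {p.pattern for p in patterns}
    bad = set(sample_sheet["replicate_pattern"]) - pattern_ids
    if bad:
        raise ValueError(f"sample sheet references unknown patterns: {sorted(bad)}")

    lib_of = {
        (r.condition_tag, r.replicate_pattern): r.library_name
        for r in sample_sheet.itertuples()
    }
    os.makedirs(out_dir, exist_ok=True)
    handles: dict[str, tuple] = {}

    def get_handles(name):
        if name not in handles:
            handles[name] = (
                open(os.path.join(out_dir, f"{name}_1.fastq"), "w"),
                open(os.path.join(out_dir, f"{name}_2.fastq"), "w"),
            )
        return handles[name]

    stats = DemuxStats()
    try:
        for pair in read_fastq_pairs(fastq1, fastq2):
            dec = decode_read(
                pair, codebook, patterns, layout,
                max_edits=max_edits, umi_mode=umi_mode,
            )
            if dec.library is UNASSIGNED:
                stats.unassigned += 1
                stats.unassigned_reasons[dec.reason] += 1
                f1, f2 = get_handles(UNASSIGNED)
                f1.write(f"@{pair.read_id}\n{pair.mate1_seq}\n+\n{pair.mate1_qual}\n")
                f2.write(f"@{pair.read_id}\n{pair.mate2_seq}\n+\n{pair.mate2_qual}\n")
                continue
            key = (dec.library.condition_tag, dec.library.replicate_pattern)
            name = lib_of.get(key)
            if name is None:
                stats.unassigned += 1
                stats.unassigned_reasons["tag/pattern combination not in sheet"] += 1
                f1, f2 = get_handles(UNASSIGNED)
                f1.write(f"@{pair.read_id}\n{pair.mate1_seq}\n+\n{pair.mate1_qual}\n")
                f2.write(f"@{pair.read_id}\n{pair.mate2_seq}\n+\n{pair.mate2_qual}\n")
                continue
            stats.per_library[name] += 1
            stats.edit_histogram[dec.edits_used] += 1
            rid = f"{dec.read_id}{umi_delimiter}{dec.umi}"
            f1, f2 = get_handles(name)
            f1.write(f"@{rid}\n{dec.insert1}\n+\n{dec.insert1_qual}\n")
            f2.write(f"@{rid}\n{dec.insert2}\n+\n{dec.insert2_qual}\n")
    finally:
        for f1, f2 in handles.values():
            f1.close()
            f2.close()
    return stats
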
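"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and shares no code with the
package: textbook dynamic-programming edit distance, hash-based event
grouping, per-base interval arithmetic.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Classic O(nm) Wagner-Fischer edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def group_events_naive(records) -> dict:
    """Hash-grouping of alignment rows by the event key -> read count."""
    groups: dict[tuple, int] = defaultdict(int)
    for r in records.itertuples():
        groups[(r.chrom, r.strand, r.mate1_start, r.mate2_start, r.umi)] += 1
    return dict(groups)


def spurious_filter_naive(groups: dict, threshold: float = 0.10) -> dict:
    """Keep events with count >= threshold * positional max (strict-< removal)."""
    by_pos = defaultdict(list)
    for key, n in groups.items():
        by_pos[key[:4]].append((key, n))
    kept = {}
    for members in by_pos.values():
        mx = max(n for _, n in members)
        for key, n in members:
            if not n < threshold * mx:
                kept[key] = n
    return kept


def overlap_counts_per_base(peak_sets, genome_length: int, chroms) -> dict:
    """Per-base Venn region counts over peak sets on a small genome.

    Marks coverage per set in boolean arrays, finds connected
    components of the union, and attributes each component by which
    sets touch it.  Abutting intervals merge automatically.
    """
    k = len(peak_sets)
    cover = {c: np.zeros((k, genome_length), dtype=bool) for c in chroms}
    for i, ps in enumerate(peak_sets):
        for p in ps.itertuples():
            cover[p.chrom][i, p.start : p.end] = True
    combos: dict[tuple, int] = defaultdict(int)
    for c in chroms:
        union = cover[c].any(axis=0)
        pos = 0
        n = genome_length
        while pos < n:
            if not union[pos]:
                pos += 1
                continue
            end = pos
            while end < n and union[end]:
                end += 1
            member = tuple(bool(cover[c][i, pos:end].any()) for i in range(k))
            combos[member] += 1
            pos = end
    return dict(combos)
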
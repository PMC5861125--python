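"""Design and validation of the tri-barcode tag sets.

The multiplexing scheme uses three levels of tags:

* fixed 5-nt *condition tags* drawn from a codebook with minimum
  pairwise Levenshtein distance 3, so a single substitution or indel
  can be corrected by nearest-neighbour decoding;
* *semi-random replicate tags* constrained to an IUPAC pattern
  (``DRYYR`` or ``DYRRY``); the pattern class identifies the replicate
  while the realized 5-mer contributes UMI capacity;
* a commercial PCR index for size fractions (handled at the sample
  sheet level, not designed here).

On the 5' side the condition tag is interleaved with five random
nucleotides (``NNNTTTTTNN``), yielding 4**5 = 1024 UMI combinations;
the 48 realizations of the 3' pattern extend the per-position event
capacity to 49 152.
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass, field

import edlib

DNA = "ACGT"

#: IUPAC nucleotide ambiguity classes (DNA alphabet).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def levenshtein(a: str, b: str) -> int:
    """Edit distance via edlib (global alignment)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate DNA pattern such as ``DRYYR``.

    ``D`` = not C, ``R`` = purine (A/G), ``Y`` = pyrimidine (C/T),
    ``N`` = any base.
    """

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty IUPAC pattern")
        bad = [c for c in self.pattern if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s): {bad!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def expansion_count(self) -> int:
        n = 1
        for c in self.pattern:
            n *= len(IUPAC[c])
        return n

    def matches(self, seq: str) -> bool:
        return len(seq) == len(self.pattern) and all(
            b in IUPAC[c] for b, c in zip(seq, self.pattern)
        )

    def mismatches(self, seq: str) -> int:
        """Number of positions of ``seq`` violating the pattern class."""
        if len(seq) != len(self.pattern):
            raise ValueError("sequence length does not match pattern")
        return sum(b not in IUPAC[c] for b, c in zip(seq, self.pattern))


@dataclass
class TagSet:
    """A codebook of equal-length tags with a pairwise distance guarantee."""

    tags: list[str]
    min_distance: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("duplicate tags in codebook")
        lens = {len(t) for t in self.tags}
        if len(lens) > 1:
            raise ValueError("tags of mixed length")
        for t in self.tags:
            if set(t) - set(DNA):
                raise ValueError(f"non-ACGT tag {t!r}")

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def tag_length(self) -> int:
        return len(self.tags[0]) if self.tags else 0

    def verify(self) -> int:
        """All-pairs minimum Levenshtein distance (raises if below spec)."""
        d = min_pairwise_distance(self.tags, self.tags, metric="levenshtein")
        if self.tags and len(self.tags) > 1 and d < self.min_distance:
            raise ValueError(
                f"codebook violates its distance guarantee: {d} < {self.min_distance}"
            )
        return d


@dataclass
class BarcodeLayout:
    """Read architecture of the tri-barcode libraries.

    ``five_prime_layout`` is a template over ``N`` (random/UMI base) and
    ``T`` (condition-tag base) describing the mate-1 prefix.
    ``three_prime_pattern`` is the semi-random tag read as the mate-2
    prefix.  ``clip_mate1``/``clip_mate2`` are the unconditional 3'-end
    clips that remove read-through into the opposite barcode (no
    information is lost: the clipped genomic bases are covered by the
    other mate).
    """

    five_prime_layout: str = "NNNTTTTTNN"
    three_prime_pattern: IUPACPattern | None = field(
        default_factory=lambda: IUPACPattern("DRYYR")
    )
    clip_mate1: int = 5
    clip_mate2: int = 10

    def __post_init__(self) -> None:
        if set(self.five_prime_layout) - {"N", "T"}:
            raise ValueError("5' layout template must be over {N, T}")

    @property
    def n_random_positions(self) -> int:
        return self.five_prime_layout.count("N")

    @property
    def tag_length(self) -> int:
        return self.five_prime_layout.count("T")

    @property
    def prefix_length(self) -> int:
        return len(self.five_prime_layout)

    @property
    def tag_slice(self) -> slice:
        i = self.five_prime_layout.index("T")
        return slice(i, i + self.tag_length)


@dataclass
class FilterReport:
    input_count: int
    removed_end_repeat: list[str]
    removed_adapter_revcomp: list[str]
    surviving: list[str]

    @property
    def removed_end_repeat_count(self) -> int:
        return len(self.removed_end_repeat)

    @property
    def removed_adapter_revcomp_count(self) -> int:
        return len(self.removed_adapter_revcomp)


def enumerate_pattern_tags(pattern: IUPACPattern | str) -> list[str]:
    """Every sequence matching the pattern, lexicographically sorted."""
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    choices = [sorted(IUPAC[c]) for c in pattern.pattern]
    return ["".join(p) for p in itertools.product(*choices)]


def count_layout_combinations(layout: BarcodeLayout) -> int:
    """Per-position UMI capacity of a layout.

    4 ** (number of random 5' positions) times the expansion count of
    the 3' semi-random pattern.  The default layout gives
    1024 x 48 = 49 152.
    """
    n = len(DNA) ** layout.n_random_positions
    if layout.three_prime_pattern is not None:
        n *= layout.three_prime_pattern.expansion_count
    return n


def min_pairwise_distance(
    set_a: list[str], set_b: list[str], metric: str = "levenshtein"
) -> int:
    """Exhaustive minimum distance over cross pairs.

    When both arguments are the same set, the minimum is taken over
    distinct index pairs; duplicated sequences therefore yield 0.
    """
    if metric == "levenshtein":
        dist = levenshtein
    elif metric == "hamming":
        dist = hamming
    else:
        raise ValueError(f"unknown metric {metric!r}")
    same = set_a is set_b or set_a == set_b
    best = None
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if same and i == j:
                continue
            d = dist(a, b)
            best = d if best is None else min(best, d)
            if best == 0:
                return 0
    if best is None:
        raise ValueError("no pairs to compare")
    return best


def _has_polybase_run(seq: str, run: int) -> bool:
    return bool(re.search(r"(.)\1{%d,}" % (run - 1), seq)) if run else False


def generate_edit_distance_tags(
    length: int = 5,
    min_dist: int = 3,
    seed: int = 0,
    forbid_polybase_run: int = 3,
    forbid_self_complement: bool = False,
) -> TagSet:
    """Greedy construction of a codebook with pairwise edit distance >= min_dist.

    All 4**length candidates are shuffled with the seeded generator and
    accepted greedily if they keep the pairwise Levenshtein minimum.
    Candidates containing a homopolymer run of ``forbid_polybase_run``
    or longer are excluded up front; with ``forbid_self_complement`` a
    candidate whose reverse complement is already accepted is skipped
    (guards against tag/revcomp collisions during ligation).

    Infeasible parameters yield a small (possibly singleton) set rather
    than an error.
    """
    if length < 1 or min_dist < 1:
        raise ValueError("length and min_dist must be >= 1")
    candidates = ["".join(p) for p in itertools.product(DNA, repeat=length)]
    if forbid_polybase_run:
        candidates = [c for c in candidates if not _has_polybase_run(c, forbid_polybase_run)]
    rng = random.Random(seed)
    rng.shuffle(candidates)
    accepted: list[str] = []
    for cand in candidates:
        if forbid_self_complement and revcomp(cand) in accepted:
            continue
        if all(levenshtein(cand, t) >= min_dist for t in accepted):
            accepted.append(cand)
    return TagSet(
        tags=accepted,
        min_distance=min_dist,
        metadata={
            "seed": seed,
            "length": length,
            "forbid_polybase_run": forbid_polybase_run,
            "forbid_self_complement": forbid_self_complement,
        },
    )


def filter_tags(tags: list[str], adapter: str = "") -> FilterReport:
    """Post-filter a candidate codebook for ligation/sequencing artifacts.

    Removes tags whose two terminal bases (either end) are identical
    and tags whose reverse complement occurs as a substring of the
    adapter.  Order-preserving; every input tag lands in exactly one
    output bucket.
    """
    end_repeat, adapter_rc, surviving = [], [], []
    for t in tags:
        if len(t) >= 2 and (t[0] == t[1] or t[-1] == t[-2]):
            end_repeat.append(t)
        elif adapter and revcomp(t) in adapter:
            adapter_rc.append(t)
        else:
            surviving.append(t)
    return FilterReport(
        input_count=len(tags),
        removed_end_repeat=end_repeat,
        removed_adapter_revcomp=adapter_rc,
        surviving=surviving,
    )


#: Two-channel chemistry convention: red detects {A, C}, green {G, T}.
#: The channel-to-base assignment is configurable because instrument
#: documentation names channels, not a universal base mapping.
RED_BASES = frozenset("AC")
GREEN_BASES = frozenset("GT")


def check_color_balance(
    tags: list[str],
    red: frozenset = RED_BASES,
    green: frozenset = GREEN_BASES,
) -> bool:
    """True iff every position has at least one red- and one green-channel base.

    Two-channel sequencers need signal in both channels at each cycle
    to call bases reliably across a multiplexed pool.
    """
    if not tags:
        return False
    if len({len(t) for t in tags}) > 1:
        raise ValueError("tags of mixed length")
    for pos in range(len(tags[0])):
        bases = {t[pos] for t in tags}
        if not (bases & red) or not (bases & green):
            return False
    return True


def max_correctable_edits(codebook: TagSet, max_probe: int = 2) -> int:
    """Verified number of edits nearest-neighbour decoding corrects.

    Exhaustively applies every combination of up to ``max_probe``
    single-base substitutions, insertions and deletions to every tag
    and checks whether the corrupted word still decodes uniquely to its
    source (strictly closer to it than to any other tag).  Returns the
    largest k for which *all* k-edit corruptions of all tags decode
    correctly.
    """
    tags = codebook.tags

    def decodes_uniquely(word: str, source: str) -> bool:
        d_src = levenshtein(word, source)
        return all(levenshtein(word, t) > d_src for t in tags if t != source)

    def single_edits(word: str):
        for i in range(len(word)):
            for b in DNA:
                if b != word[i]:
                    yield word[:i] + b + word[i + 1:]
            yield word[:i] + word[i + 1:]
        for i in range(len(word) + 1):
            for b in DNA:
                yield word[:i] + b + word[i:]

    verified = 0
    frontier = {t: {t} for t in tags}
    for k in range(1, max_probe + 1):
        frontier = {
            src: {e for w in words for e in single_edits(w)}
            for src, words in frontier.items()
        }
        ok = all(
            decodes_uniquely(w, src) for src, words in frontier.items() for w in words
        )
        if not ok:
            break
        verified = k
    return verified


def write_codebook(path, codebook: TagSet) -> None:
    """Write a TSV codebook: `#`-prefixed parameter header, tag<TAB>index lines."""
    with open(path, "w") as fh:
        fh.write(f"# min_distance={codebook.min_distance}\n")
        for k, v in sorted(codebook.metadata.items()):
            fh.write(f"# {k}={v}\n")
        for i, t in enumerate(codebook.tags):
            fh.write(f"{t}\t{i}\n")


def read_codebook(path) -> TagSet:
    tags, meta, min_dist = [], {}, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, v = body.split("=", 1)
                    if k == "min_distance":
                        min_dist = int(v)
                    else:
                        meta[k] = v
                continue
            tags.append(line.split("\t")[0])
    return TagSet(tags=tags, min_distance=min_dist, metadata=meta)
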
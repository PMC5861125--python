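"""Design an error-correcting condition-tag codebook and check its guarantees.

Builds a set of 5-nt tags with minimum pairwise Levenshtein distance 3
(so one substitution or indel per tag is correctable), filters ligation
and sequencing artifacts, and reports the combinatorial UMI capacity of
the full barcode layout.
"""

from uvclap import barcode_design as bd

tags = bd.generate_edit_distance_tags(length=5, min_dist=3, seed=1)
report = bd.filter_tags(tags.tags, adapter="AGATCGGAAGAGC")
codebook = bd.TagSet(report.surviving, 3, dict(tags.metadata))

print(f"candidate tags: {report.input_count}")
print(f"removed (terminal base repeats): {report.removed_end_repeat_count}")
print(f"removed (revcomp in adapter):    {report.removed_adapter_revcomp_count}")
print(f"final codebook: {codebook.tags}")
print(f"verified min pairwise edit distance: {codebook.verify()}")
print(f"errors correctable per tag (exhaustive check): "
      f"{bd.max_correctable_edits(codebook)}")

layout = bd.BarcodeLayout()  # NNNTTTTTNN + semi-random DRYYR 3' tag
print(f"5' random positions alone: "
      f"{bd.count_layout_combinations(bd.BarcodeLayout(three_prime_pattern=None))} "
      f"UMI combinations")
print(f"full layout capacity: {bd.count_layout_combinations(layout)} "
      f"distinguishable events per genomic position")
# The two replicate patterns are 4 substitutions apart at minimum, so a
# replicate tag is never mis-assigned by fewer than 4 errors:
a, b = bd.enumerate_pattern_tags("DRYYR"), bd.enumerate_pattern_tags("DYRRY")
print(f"DRYYR vs DYRRY minimum Hamming distance: "
      f"{bd.min_pairwise_distance(a, b, 'hamming')}")
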
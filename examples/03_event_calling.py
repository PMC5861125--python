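"""Collapse aligned reads into crosslinking events and inspect duplication.

One crosslinking event = one captured RNA molecule, identified by the
UMI plus the start coordinates of both mates.  The 10% positional
filter then removes low-count sibling events created by UMI errors,
and the duplication-by-length table shows the PCR length bias (excess
duplicates for cDNAs of 40-60 nt) that collapse removes.
"""

from uvclap import event_caller as ec
from uvclap import synthetic_data as sd

cfg = sd.SimConfig(seed=11, molecules_per_library=2000)
sim = sd.simulate_multiplexed(cfg)
truth = sim["truth"]
lib = truth[truth["library"] == "signal_rep1"]

aln = sd.simulate_alignments(lib, multimap_fraction=0.05)
unique = ec.filter_unique(aln)
events = ec.collapse_to_events(unique)
kept = ec.filter_spurious(events, threshold=0.10)

print(f"alignments: {len(aln)} ({len(aln) - len(unique)} multi-mapping removed)")
print(f"crosslinking events after UMI collapse: {len(events)}")
print(f"after 10% spurious filter: {len(kept)}")
print(f"duplicate reads absorbed: {int(events['read_count'].sum() - len(events))}")

table = ec.duplication_by_length(unique, events, bin_width=10)
print("\nlength bin  reads  events  duplicate fraction")
for r in table.itertuples():
    marker = " <- bias window" if 40 <= r.length_bin <= 60 else ""
    print(f"{r.length_bin:>9}  {r.reads:>5}  {r.events:>6}  "
          f"{r.duplicate_fraction:17.3f}{marker}")
# Duplicate fractions peak inside 40-60 nt, mirroring the amplification
# bias; at the event level the bias is gone.
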
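"""Profile crosslink positions relative to exon-exon junctions.

An EJC-like binder deposited 20-30 nt upstream of junctions produces a
sharp peak at negative distances, while a nonspecific control is flat;
a chi-square test quantifies the contrast.
"""

from uvclap import event_caller as ec
from uvclap import metaprofile as mp
from uvclap import synthetic_data as sd

cfg = sd.SimConfig(
    seed=29, binding_mode="junction_upstream",
    molecules_per_library=4000, background_fraction=0.05,
)
sim = sd.simulate_multiplexed(cfg)
truth = sim["truth"]
junctions = mp.extract_junctions(sim["annotation"])
print(f"annotation: {len(junctions)} unique exon-exon junctions")

for name, label in (("signal_rep1", "EJC-mode signal"), ("control_rep1", "control")):
    ev = ec.call_events(sd.simulate_alignments(truth[truth["library"] == name]))
    prof = mp.junction_histogram(ev, junctions, window=200)
    stat, p = mp.uniformity_statistic(prof, rebin=10)
    total = prof["count"].sum()
    window_mass = prof[prof["distance"].between(-30, -20)]["count"].sum()
    print(f"\n{label}: {total} in-window crosslinks")
    print(f"  modal distance: {mp.modal_bin(prof)} nt "
          f"(negative = upstream of the junction)")
    print(f"  mass in [-30, -20]: {100 * window_mass / total:.1f}%")
    print(f"  chi-square vs uniform (20-nt bins): {stat:.0f}, p = {p:.3g}")
# The signal's modal bin falls in the deposition window and uniformity
# is rejected decisively; the control's histogram is statistically flat.
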
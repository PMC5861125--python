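import numpy as np
import pandas as pd
import pytest

from uvclap import barcode_design as bd
from uvclap import synthetic_data as sd


@pytest.fixture(scope="session")
def codebook():
    tags = bd.generate_edit_distance_tags(length=5, min_dist=3, seed=11)
    report = bd.filter_tags(tags.tags, adapter="AGATCGGAAGAGC")
    return bd.TagSet(report.surviving, 3, dict(tags.metadata))


@pytest.fixture(scope="session")
def patterns():
    return [bd.IUPACPattern("DRYYR"), bd.IUPACPattern("DYRRY")]


@pytest.fixture(scope="session")
def layout():
    return bd.BarcodeLayout()


@pytest.fixture(scope="session")
def small_sim():
    """Motif-mode study with duplication and length bias."""
    cfg = sd.SimConfig(seed=5, molecules_per_library=800)
    return sd.simulate_multiplexed(cfg)


@pytest.fixture(scope="session")
def noiseless_sim():
    """No sequencing error, no PCR duplication: pipeline output must equal truth."""
    cfg = sd.SimConfig(
        seed=9, molecules_per_library=500,
        duplication_mean=1.0, duplication_bias=1.0, error_rate=0.0,
    )
    return sd.simulate_multiplexed(cfg)


@pytest.fixture(scope="session")
def junction_annotation():
    """Annotation with exons long enough that junction flanks never overlap."""
    cfg = sd.SimConfig(
        seed=21, binding_mode="junction_upstream",
        exon_length=500, chrom_length=80_000, n_protein_coding=12,
    )
    rng = cfg.rng()
    genome, sizes = sd.make_genome(cfg, rng)
    annotation = sd.make_annotation(cfg, sizes, rng)
    return cfg, genome, sizes, annotation


def random_alignments(n, rng, n_pos=200, n_umi=50):
    """Random alignment table concentrated enough to exercise grouping."""
    starts = rng.integers(0, 5000, size=n_pos)
    idx = rng.integers(0, n_pos, size=n)
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n)],
            "chrom": np.where(rng.random(n) < 0.5, "chr1", "chr2"),
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "mate1_start": starts[idx],
            "mate2_start": starts[idx],
            "aln_length": rng.integers(30, 81, size=n),
            "umi": [f"U{u}" for u in rng.integers(0, n_umi, size=n)],
            "multimap": rng.random(n) < 0.1,
        }
    )
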
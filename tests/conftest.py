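import numpy as np
import pandas as pd
import pytest

from cnaburden import SampleTable, SimParams, simulate_cohort, toy_genome


@pytest.fixture(scope="session")
def toy():
    return toy_genome()


@pytest.fixture(scope="session")
def cohort(toy):
    """A small simulated cohort shared across tests (seeded)."""
    params = SimParams(n_samples=40, genome=toy, broad_rate=2.0,
                       focal_rate=3.0, noise_sd=0.03,
                       purity_range=(0.7, 1.0), baf_loh_rate=0.05, seed=11)
    return simulate_cohort(params)


def make_table(rows, annotations=None):
    """Build a SampleTable from (sample, chrom, start, end, seg_mean[, purity, baf])."""
    recs = []
    for r in rows:
        rec = {"sample_id": r[0], "chrom": r[1], "start": r[2], "end": r[3],
               "seg_mean": float(r[4]),
               "purity": float(r[5]) if len(r) > 5 and r[5] is not None else np.nan,
               "baf": float(r[6]) if len(r) > 6 and r[6] is not None else np.nan}
        recs.append(rec)
    seg = pd.DataFrame(recs)
    if annotations is not None:
        ann = pd.DataFrame(annotations).set_index("sample_id")
        return SampleTable(seg, ann)
    return SampleTable(seg)


@pytest.fixture
def seg_file(tmp_path):
    """Write a SEG-style TSV and return its path."""

    def write(text, name="input.seg"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
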
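import numpy as np
import pytest

from clonaldyn import synthetic_data as sd
from clonaldyn.variant_pipeline import SampleSheet, VariantRecord

import pandas as pd


@pytest.fixture(scope="session")
def sim_catalog():
    """The synthetic scored catalog used for simulator tests: 1000 neutral,
    50 driver, 10 strong-driver entries."""
    return sd.gen_catalog(1000, 50, 10, seed=0)


@pytest.fixture(scope="session")
def two_sample_sheet():
    """Minimal design: one seed sample plus two culture samples."""
    return SampleSheet(
        pd.DataFrame(
            [
                {"sample_id": "S", "fbs_group": "none", "timepoint": "baseline",
                 "replicate": 0, "role": "seed"},
                {"sample_id": "A", "fbs_group": "1%", "timepoint": "week3",
                 "replicate": 1, "role": "culture"},
                {"sample_id": "B", "fbs_group": "5%", "timepoint": "week3",
                 "replicate": 1, "role": "culture"},
            ]
        )
    )


def _rec(chrom, pos, depth_a, vaf_a, depth_b, vaf_b, seed_vaf):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="T",
        depth={"A": depth_a, "B": depth_b, "S": 50},
        vaf={"A": vaf_a, "B": vaf_b, "S": seed_vaf},
        seed_vaf=seed_vaf,
    )


@pytest.fixture(scope="session")
def filter_truth_table():
    """Eight hand-constructed records exercising every exclusion branch,
    with the hand-derived retained sets for both filter modes.

    r1 low depth everywhere            -> dropped (both modes)
    r2 VAF < 0.1 in all cultures       -> dropped (both modes)
    r3 clean novel variant             -> kept (both modes)
    r4 seed fraction 0.02              -> dropped strict, kept relaxed
    r5 seed VAF 0.15                   -> dropped (both modes)
    r6 VAF exactly 0.1 in one sample   -> kept (boundary: not below 0.1)
    r7 depth 11 boundary, seed exactly
       0.01 (not *more than* 1%)       -> kept (both modes)
    r8 max culture depth exactly 10    -> dropped (boundary: "10 or less")
    """
    records = [
        _rec("chr1", 100, 8, 0.30, 9, 0.25, 0.0),     # r1
        _rec("chr1", 200, 60, 0.05, 55, 0.08, 0.0),   # r2
        _rec("chr1", 300, 40, 0.30, 45, 0.20, 0.0),   # r3
        _rec("chr2", 400, 50, 0.25, 50, 0.30, 0.02),  # r4
        _rec("chr2", 500, 50, 0.25, 50, 0.30, 0.15),  # r5
        _rec("chr2", 600, 80, 0.10, 80, 0.02, 0.0),   # r6
        _rec("chr3", 700, 11, 0.30, 5, 0.00, 0.01),   # r7
        _rec("chr3", 800, 10, 0.30, 10, 0.40, 0.0),   # r8
    ]
    strict_kept = {("chr1", 300), ("chr2", 600), ("chr3", 700)}
    relaxed_kept = strict_kept | {("chr2", 400)}
    return records, strict_kept, relaxed_kept
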
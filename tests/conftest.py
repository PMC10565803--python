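"""Shared fixtures: small hand-built datasets and simulated harmonized sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrscreen.harmonize import HarmonizedInstrument, HarmonizedSet
from mrscreen.sumstats import CANONICAL_COLUMNS, GwasDataset, _coerce_dtypes

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_dataset(rows, trait_id="genus.Test", trait_type="exposure"):
    """Build a GwasDataset from dicts of (subsets of) canonical columns."""
    defaults = {
        "chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.02, "pvalue": 1e-6, "n": 18_340,
    }
    full = []
    for i, row in enumerate(rows):
        r = {"snp_id": f"rs{i}", **defaults, **row}
        full.append(r)
    df = _coerce_dtypes(pd.DataFrame(full, columns=CANONICAL_COLUMNS))
    return GwasDataset(trait_id, trait_type, df)


def make_harmonized(rng, k, theta=0.2, se_out=0.05, se_exp=0.02, exposure_id="genus.Sim"):
    """k independent instruments with exact per-SNP model βY = θ·βX + noise."""
    bx = rng.uniform(0.1, 0.5, size=k)
    by = theta * bx + rng.normal(0, se_out, size=k)
    insts = [
        HarmonizedInstrument(f"rs{i}", bx[i], se_exp, by[i], se_out, eaf_exp=0.3)
        for i in range(k)
    ]
    return HarmonizedSet.from_instruments(exposure_id, insts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_instrument_set():
    """The worked IVW example: (βX, βY, σY) = (0.5, 0.1, 0.1) and (0.2, 0.06, 0.2)."""
    return HarmonizedSet.from_instruments(
        "genus.Example",
        [
            HarmonizedInstrument("rs1", 0.5, 0.05, 0.1, 0.1),
            HarmonizedInstrument("rs2", 0.2, 0.05, 0.06, 0.2),
        ],
    )
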
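"""Shared fixtures: small alignments and the ABC reference tables.

The gene-conversion reference tables (20,000 simulations per model) are
expensive, so they are built once per session and shared by the recovery
and model-choice tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from paraconv.abc_inference import (
    DEFAULT_GC_PRIORS,
    PriorSpec,
    run_simulations,
    sample_priors,
)
from paraconv.seq_model import Alignment

GC_FIXED = {"n_A": 14, "n_B": 9, "L": 1000, "theta": 0.0085}
GC_TABLE_SIZE = 20_000


@pytest.fixture
def toy_alignment() -> Alignment:
    # n=4, two segregating sites with minor counts {2, 1}: pi_total = 7/6
    return Alignment(
        ["s1", "s2", "s3", "s4"],
        ["AAAA", "AAAA", "ATAA", "ATCA"],
    )


@pytest.fixture(scope="session")
def gc_priors() -> PriorSpec:
    return PriorSpec(dict(DEFAULT_GC_PRIORS))


@pytest.fixture(scope="session")
def gc_table_m2(gc_priors):
    """Reference table under the conversion model (M2)."""
    params = sample_priors(gc_priors, GC_TABLE_SIZE, seed=20220901)
    return run_simulations(params, GC_FIXED, seed=20220902, model="M2")


@pytest.fixture(scope="session")
def gc_table_m1():
    """Reference table under the no-conversion model (M1)."""
    prior = PriorSpec({"t_dup": DEFAULT_GC_PRIORS["t_dup"]})
    params = sample_priors(prior, GC_TABLE_SIZE, seed=20220903)
    return run_simulations(params, GC_FIXED, seed=20220904, model="M1")


def random_alignment(rng: np.random.Generator, n: int = 10, L: int = 50,
                     missing_rate: float = 0.0) -> Alignment:
    bases = np.array(list("ACGT"))
    base_row = rng.choice(bases, size=L)
    mat = np.tile(base_row, (n, 1))
    # sprinkle biallelic variation over ~30% of columns
    for c in np.flatnonzero(rng.random(L) < 0.3):
        alt = rng.choice([b for b in "ACGT" if b != base_row[c]])
        carriers = rng.random(n) < rng.uniform(0.1, 0.9)
        mat[carriers, c] = alt
    if missing_rate > 0:
        mask = rng.random((n, L)) < missing_rate
        mat[mask] = "-"
    return Alignment([f"t{i}" for i in range(n)], ["".join(r) for r in mat])
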
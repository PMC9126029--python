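import numpy as np
import pandas as pd
import pytest

import xselscan as xs
from xselscan.genotype_io import GenotypeMatrix, make_sample_sheet, make_snp_map


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by read-only tests."""
    params = xs.SimParams(n_snps=400, par_snps=60, n_males=40, n_females=30, seed=11)
    gm, haps, truth = xs.simulate_neutral(params)
    return params, gm, haps, truth


@pytest.fixture
def tiny_gm():
    """1 chromosome, 4 SNPs, 4 samples (2 male focal, 1 female focal, 1 outgroup male)."""
    snps = make_snp_map(["s1", "s2", "s3", "s4"], [100, 200, 300, 400])
    samples = make_sample_sheet(
        ["m1", "m2", "f1", "o1"],
        ["male", "male", "female", "male"],
        ["b1", "b1", "b2", "mouflon"],
        ["focal", "focal", "focal", "outgroup"],
    )
    calls = np.array(
        [
            [0, 2, 1, 0],
            [2, 0, 2, 2],
            [0, 0, 1, 0],
            [2, 2, 0, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(snps, samples, calls)


def make_female_gm(pos, calls_per_sample):
    """Build a female-only GenotypeMatrix from per-sample call vectors."""
    n = len(pos)
    calls = np.array(calls_per_sample, dtype=np.int8).T
    n_samples = calls.shape[1]
    snps = make_snp_map([f"s{i}" for i in range(n)], pos)
    samples = make_sample_sheet(
        [f"f{i}" for i in range(n_samples)],
        ["female"] * n_samples,
        ["b"] * n_samples,
        ["focal"] * n_samples,
    )
    return GenotypeMatrix(snps, samples, calls)
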
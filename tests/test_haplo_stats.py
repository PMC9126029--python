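"""EHH/iHS/nSL scores against brute-force pairwise oracles, plus windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xselscan as xs
from xselscan import haplo_stats as hs
from xselscan.genotype_io import make_snp_map


def snpmap_for(n, spacing=1000, ancestral="a"):
    return make_snp_map([f"s{i}" for i in range(n)], (np.arange(n) + 1) * spacing,
                        ancestral=[ancestral] * n)


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------


def test_ehh_is_one_at_core():
    haps = np.array([[0, 1, 0], [0, 0, 1], [0, 1, 1]])
    curve = xs.ehh(haps, core_snp=0, allele=0, direction="right")
    assert curve[0] == (0, 1.0)


def test_ehh_two_identical_pairs():
    # 4 carriers forming two identical pairs one SNP out: EHH = 2/C(4,2) = 1/3
    haps = np.array([
        [0, 0],
        [0, 0],
        [0, 1],
        [0, 1],
    ])
    curve = xs.ehh(haps, core_snp=0, allele=0, direction="right", cutoff=0.0)
    assert curve[1][1] == pytest.approx(1 / 3)


def test_ehh_all_distinct_is_zero():
    haps = np.array([
        [0, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
    ])
    # make all three pairwise distinct at SNP 1..2
    haps[2, 1] = 1
    haps[2, 2] = 1  # rows: (0,0),(1,0),(1,1) -> two share state at snp1
    haps = np.array([[0, 0], [0, 1], [0, 2]])  # force distinct with 3 states
    curve = xs.ehh(haps, core_snp=0, allele=0, direction="right", cutoff=0.0)
    assert curve[1][1] == 0.0


def test_ehh_needs_two_carriers():
    haps = np.array([[0, 0], [1, 0]])
    with pytest.raises(ValueError):
        xs.ehh(haps, core_snp=0, allele=0, direction="right")


def test_ehh_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    haps = rng.integers(0, 2, size=(10, 15))
    haps[:, 7] = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
    curve = xs.ehh(haps, core_snp=7, allele=0, direction="right", cutoff=0.0)
    for j, val in curve[1:]:
        assert val == pytest.approx(hs.ehh_pairwise_oracle(haps, 7, 0, j), abs=1e-12)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 10_000))
def test_ehh_non_increasing(seed):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(12, 20))
    haps[:6, 10] = 0
    haps[6:, 10] = 1
    for direction in ("left", "right"):
        curve = xs.ehh(haps, core_snp=10, allele=0, direction=direction, cutoff=0.0)
        vals = [v for _, v in curve]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# iHH integration
# ---------------------------------------------------------------------------


def test_ihh_rectangle():
    positions = np.array([0, 5_000, 10_000])
    curve = [(0, 1.0), (1, 1.0), (2, 1.0)]
    assert xs.ihh(curve, positions) == pytest.approx(10_000)


def test_ihh_linear_decay():
    positions = np.array([0, 10_000])
    curve = [(0, 1.0), (1, 0.0)]
    assert xs.ihh(curve, positions) == pytest.approx(5_000)


def test_ihh_empty_side_contributes_zero():
    assert xs.ihh([(0, 1.0)], np.array([0])) == 0.0


# ---------------------------------------------------------------------------
# iHS raw
# ---------------------------------------------------------------------------


def mirror_fixture():
    """Ancestral and derived carrier sets with mirror-image decay patterns."""
    anc = np.array([
        [0, 0, 0, 0, 0],
        [1, 0, 0, 0, 1],
        [0, 1, 0, 1, 0],
    ])
    der = 1 - anc  # identical internal structure, derived at the core
    return np.concatenate([anc, der])


def test_ihs_mirror_symmetric_is_zero():
    haps = mirror_fixture()
    sm = snpmap_for(5)
    raw = xs.ihs_raw(haps, sm, maf_floor=0.05)["raw"]
    assert raw[2] == pytest.approx(0.0, abs=1e-12)


def test_ihs_low_maf_is_na():
    rng = np.random.default_rng(1)
    haps = rng.integers(0, 2, size=(30, 9))
    haps[:, 4] = 0
    haps[0, 4] = 1  # derived freq 1/30 ~ 0.033 < 0.05
    sm = snpmap_for(9)
    raw = xs.ihs_raw(haps, sm)["raw"]
    assert np.isnan(raw[4])


def test_ihs_unknown_ancestral_is_na():
    rng = np.random.default_rng(2)
    haps = rng.integers(0, 2, size=(20, 7))
    sm = snpmap_for(7)
    sm.loc[3, "ancestral"] = "unknown"
    raw = xs.ihs_raw(haps, sm)["raw"]
    assert np.isnan(raw[3])


@pytest.mark.parametrize("seed", range(5))
def test_ihs_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(8, 11))
    core = 5
    haps[:, core] = [0, 0, 0, 0, 1, 1, 1, 1]
    sm = snpmap_for(11)
    raw = xs.ihs_raw(haps, sm)["raw"][core]
    ihh_a = hs.ihh_pairwise_oracle(haps, sm["pos_bp"].to_numpy(), core, 0)
    ihh_d = hs.ihh_pairwise_oracle(haps, sm["pos_bp"].to_numpy(), core, 1)
    assert raw == pytest.approx(np.log(ihh_a / ihh_d), abs=1e-12)


@settings(deadline=None, max_examples=10)
@given(st.integers(0, 10_000))
def test_ihs_antisymmetric_under_label_swap(seed):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(12, 9))
    haps[:6, 4] = 0
    haps[6:, 4] = 1
    sm = snpmap_for(9)
    fwd = xs.ihs_raw(haps, sm)["raw"][4]
    rev = xs.ihs_raw(1 - haps, sm)["raw"][4]
    if np.isfinite(fwd) and np.isfinite(rev):
        assert fwd == pytest.approx(-rev, abs=1e-12)


# ---------------------------------------------------------------------------
# nSL raw
# ---------------------------------------------------------------------------


def test_nsl_homogeneous_classes_zero():
    anc = np.tile([0, 0, 0, 0, 0], (3, 1))
    der = np.tile([1, 1, 1, 1, 1], (3, 1))
    haps = np.concatenate([anc, der])
    sm = snpmap_for(5)
    raw = xs.nsl_raw(haps, sm)["raw"][2]
    assert raw == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_nsl_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed + 100)
    haps = rng.integers(0, 2, size=(6, 13))
    core = 6
    haps[:, core] = [0, 0, 0, 1, 1, 1]
    sm = snpmap_for(13)
    raw = xs.nsl_raw(haps, sm)["raw"][core]
    sl_a = hs.sl_pairwise_oracle(haps, core, 0)
    sl_d = hs.sl_pairwise_oracle(haps, core, 1)
    assert raw == pytest.approx(np.log(sl_a / sl_d), abs=1e-12)


def test_nsl_low_maf_is_na():
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(30, 5))
    haps[:, 2] = 0
    sm = snpmap_for(5)
    assert np.isnan(xs.nsl_raw(haps, sm)["raw"][2])


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def test_single_bin_standardized_moments():
    rng = np.random.default_rng(4)
    n = 50
    scores = pd.DataFrame({
        "snp_id": [str(i) for i in range(n)],
        "pos_bp": (np.arange(n) + 1) * 1000,
        "derived_freq": np.full(n, 0.51),
        "raw": rng.normal(2.0, 3.0, size=n),
    })
    out = xs.bin_standardize(scores)
    z = out["z"].to_numpy()
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_two_sided_neglogp_at_two_sigma():
    from scipy.stats import norm
    # |z| = 2 -> two-sided p = 0.04550 -> -log10 ~ 1.342
    assert -np.log10(2 * norm.sf(2.0)) == pytest.approx(1.3420, abs=5e-4)
    n = 40
    raw = np.zeros(n)
    raw[:20] = 1.0
    raw[20:] = -1.0
    scores = pd.DataFrame({
        "snp_id": [str(i) for i in range(n)],
        "pos_bp": (np.arange(n) + 1) * 1000,
        "derived_freq": np.full(n, 0.3),
        "raw": raw,
    })
    out = xs.bin_standardize(scores)
    expect = -np.log10(2 * norm.sf(1.0))  # all |z| = 1 here
    assert out["neglogp"].to_numpy() == pytest.approx(np.full(n, expect))


def test_na_propagates_through_standardization():
    scores = pd.DataFrame({
        "snp_id": list("abc"),
        "pos_bp": [1000, 2000, 3000],
        "derived_freq": [0.5, 0.5, 0.5],
        "raw": [1.0, np.nan, -1.0],
    })
    out = xs.bin_standardize(scores, min_bin_count=1)
    assert np.isnan(out["z"][1]) and np.isnan(out["neglogp"][1])
    assert np.isfinite(out["z"][0])


def test_standardization_within_generous_bins():
    """With plenty of SNPs per 0.025 bin, each bin's z has mean 0 and sd 1."""
    rng = np.random.default_rng(9)
    n = 4000  # ~100 SNPs per bin, so no merging occurs
    scores = pd.DataFrame({
        "snp_id": [str(i) for i in range(n)],
        "pos_bp": (np.arange(n) + 1) * 1000,
        "derived_freq": rng.uniform(0.01, 0.99, size=n),
        "raw": rng.normal(size=n),
    })
    out = xs.bin_standardize(scores)
    bins = (out["derived_freq"] // 0.025).astype(int)
    for _, grp in out.groupby(bins):
        zz = grp["z"].dropna().to_numpy()
        if len(zz) >= 2:
            assert zz.mean() == pytest.approx(0.0, abs=1e-9)
            assert zz.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_all_na_in_all_na_out():
    scores = pd.DataFrame({
        "snp_id": ["a", "b"], "pos_bp": [1, 2],
        "derived_freq": [0.5, 0.5], "raw": [np.nan, np.nan],
    })
    out = xs.bin_standardize(scores)
    assert out["z"].isna().all() and out["neglogp"].isna().all()


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------


def _scores(pos, neglogp):
    return pd.DataFrame({"snp_id": [str(p) for p in pos], "pos_bp": pos,
                         "derived_freq": 0.5, "raw": 0.0, "z": 0.0,
                         "neglogp": neglogp})


def test_no_outliers_no_significant_windows():
    pos = (np.arange(50) + 1) * 10_000
    ws = xs.window_outlier_scan(_scores(pos, np.ones(50)))
    assert all(not w.significant for w in ws)


def test_twelve_percent_outliers_significant():
    pos = (np.arange(50) + 1) * 10_000   # one 500 kb window
    nl = np.ones(50)
    nl[:6] = 3.0                          # 6/50 = 12% > 10%
    ws = xs.window_outlier_scan(_scores(pos, nl))
    sig = [w for w in ws if w.significant]
    assert sig and sig[0].n_outliers >= 6


def test_overlap_suppression_keeps_best():
    # two overlapping 500 kb candidates; the denser one wins
    pos = np.concatenate([(np.arange(50) + 1) * 10_000,
                          500_000 + (np.arange(50) + 1) * 10_000])
    nl = np.ones(100)
    nl[30:50] = 3.0    # window 1..500k: prop 20/50
    nl[50:58] = 3.0    # overlapping windows catch some of both
    ws = xs.window_outlier_scan(_scores(pos, nl))
    sig = [w for w in ws if w.significant]
    for a in sig:
        for b in sig:
            if a is not b:
                assert a.end_bp < b.start_bp or a.start_bp > b.end_bp


def test_window_with_no_scored_snps_skipped():
    pos = (np.arange(20) + 1) * 10_000
    nl = np.full(20, np.nan)
    assert xs.window_outlier_scan(_scores(pos, nl)) == []
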
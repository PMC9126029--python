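"""EHH, iHS and nSL scans on phased haplotypes with windowed outlier calling.

Scores are computed on a binary haplotype matrix whose columns are recoded so
0 = ancestral and 1 = derived (see :func:`xselscan.genotype_io.recode_ancestral`).
Raw per-SNP statistics are standardized within derived-allele-frequency bins
and converted to two-sided -log10(P); sliding physical windows with an excess
proportion of outlier SNPs become significant signals.

Integration for iHS uses physical bp distance (a uniform per-bp map);
nSL counts SNP steps instead and therefore needs no map at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

MISSING = -1


# ---------------------------------------------------------------------------
# EHH machinery
# ---------------------------------------------------------------------------


def _ehh_walk(haps, carriers, core_idx, step, stop_at_zero, cutoff):
    """Yield (snp_index, ehh) walking from the core in direction ``step``.

    EHH at SNP j is the probability that two random carriers of the core
    allele are identical at every SNP from the core through j.  The walk
    stops when EHH falls below ``cutoff`` (or hits zero when
    ``stop_at_zero``), or at the chromosome end.
    """
    n = len(carriers)
    pairs_total = n * (n - 1) / 2
    ids = np.zeros(n, dtype=np.int64)
    j = core_idx + step
    n_snps = haps.shape[1]
    while 0 <= j < n_snps:
        col = haps[carriers, j]
        _, ids = np.unique(ids * 3 + col, return_inverse=True)
        counts = np.bincount(ids)
        ehh = (counts * (counts - 1) / 2).sum() / pairs_total
        if ehh < cutoff or (stop_at_zero and ehh == 0):
            yield j, ehh
            return
        yield j, ehh
        j += step


def ehh(haps, core_snp: int, allele: int, direction: str, cutoff: float = 0.05):
    """EHH decay curve for carriers of ``allele`` at ``core_snp``.

    Returns a list of ``(pos_index, ehh)`` starting at the core (EHH = 1)
    and truncated once EHH < ``cutoff``.  ``direction`` is "left" or
    "right".  Fewer than two carriers is undefined (ValueError).
    """
    carriers = np.flatnonzero(haps[:, core_snp] == allele)
    if len(carriers) < 2:
        raise ValueError("EHH needs at least two carriers of the core allele")
    step = -1 if direction == "left" else 1
    curve = [(core_snp, 1.0)]
    curve.extend(_ehh_walk(haps, carriers, core_snp, step, False, cutoff))
    return curve


def ihh(curve, positions) -> float:
    """Trapezoidal integral of one EHH decay curve over bp distance.

    ``curve`` is a list of ``(snp_index, ehh)`` as produced by :func:`ehh`
    (core first); an empty or single-point curve contributes 0.
    """
    if len(curve) < 2:
        return 0.0
    idx = np.array([c[0] for c in curve])
    vals = np.array([c[1] for c in curve])
    dist = np.abs(positions[idx] - positions[idx[0]]).astype(float)
    return float(np.trapezoid(vals, dist))


def _ihh_both_sides(haps, positions, core_idx, allele, cutoff):
    carriers = np.flatnonzero(haps[:, core_idx] == allele)
    if len(carriers) < 2:
        return np.nan
    total = 0.0
    for step in (-1, 1):
        curve = [(core_idx, 1.0)]
        curve.extend(_ehh_walk(haps, carriers, core_idx, step, False, cutoff))
        total += ihh(curve, positions)
    return total


def _sl_both_sides(haps, core_idx, allele):
    """Mean pairwise shared-tract length in SNPs (counting the core)."""
    carriers = np.flatnonzero(haps[:, core_idx] == allele)
    if len(carriers) < 2:
        return np.nan
    total = 1.0  # the core SNP itself
    for step in (-1, 1):
        for _, e in _ehh_walk(haps, carriers, core_idx, step, True, 0.0):
            total += e
    return total


def ihs_raw(haps, snpmap: pd.DataFrame, maf_floor: float = 0.05, cutoff: float = 0.05) -> pd.DataFrame:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) per SNP.

    NA when the minor allele frequency is below ``maf_floor``, the ancestral
    state is unknown, either allele has < 2 carriers, or either integral is
    zero.  ``haps`` must already be ancestral/derived recoded (0/1).
    """
    return _raw_scan(haps, snpmap, maf_floor, kind="ihs", cutoff=cutoff)


def nsl_raw(haps, snpmap: pd.DataFrame, maf_floor: float = 0.05) -> pd.DataFrame:
    """Unstandardized nSL = ln(SL_ancestral / SL_derived) per SNP.

    SL is the mean over carrier pairs of the number of consecutive SNPs
    (counting the core) over which the pair is identical, extended in both
    directions; no genetic or physical map is involved.
    """
    return _raw_scan(haps, snpmap, maf_floor, kind="nsl", cutoff=0.0)


def _raw_scan(haps, snpmap, maf_floor, kind, cutoff):
    haps = np.asarray(haps)
    positions = snpmap["pos_bp"].to_numpy()
    anc_known = (snpmap["ancestral"].to_numpy() != "unknown") if "ancestral" in snpmap else np.ones(len(positions), bool)
    n_haps = haps.shape[0]
    derived_freq = (haps == 1).sum(axis=0) / n_haps
    raw = np.full(len(positions), np.nan)
    for i in range(len(positions)):
        f = derived_freq[i]
        maf = min(f, 1 - f)
        if maf < maf_floor or not anc_known[i]:
            continue
        if kind == "ihs":
            a = _ihh_both_sides(haps, positions, i, 0, cutoff)
            d = _ihh_both_sides(haps, positions, i, 1, cutoff)
        else:
            a = _sl_both_sides(haps, i, 0)
            d = _sl_both_sides(haps, i, 1)
        if not (np.isfinite(a) and np.isfinite(d)) or a == 0 or d == 0:
            continue
        raw[i] = np.log(a / d)
    return pd.DataFrame(
        {
            "snp_id": snpmap["snp_id"].to_numpy(),
            "pos_bp": positions,
            "derived_freq": derived_freq,
            "raw": raw,
        }
    )


# ---------------------------------------------------------------------------
# Brute-force oracles (tests only; independent of the scan path above)
# ---------------------------------------------------------------------------


def ehh_pairwise_oracle(haps, core_idx, allele, j):
    """EHH at SNP j by direct enumeration of carrier pairs."""
    carriers = np.flatnonzero(haps[:, core_idx] == allele)
    lo, hi = sorted((core_idx, j))
    same = sum(
        1
        for x, y in combinations(carriers, 2)
        if np.array_equal(haps[x, lo:hi + 1], haps[y, lo:hi + 1])
    )
    npairs = len(carriers) * (len(carriers) - 1) // 2
    return same / npairs


def sl_pairwise_oracle(haps, core_idx, allele):
    """Mean shared-tract length (in SNPs, counting the core) over carrier
    pairs, by direct per-pair extension."""
    carriers = np.flatnonzero(haps[:, core_idx] == allele)
    n_snps = haps.shape[1]
    lengths = []
    for x, y in combinations(carriers, 2):
        length = 1
        j = core_idx - 1
        while j >= 0 and haps[x, j] == haps[y, j]:
            length += 1
            j -= 1
        j = core_idx + 1
        while j < n_snps and haps[x, j] == haps[y, j]:
            length += 1
            j += 1
        lengths.append(length)
    return float(np.mean(lengths))


def ihh_pairwise_oracle(haps, positions, core_idx, allele, cutoff=0.05):
    """iHH by computing EHH at every SNP via pair enumeration, then
    trapezoid-integrating each side with the same truncation rule."""
    total = 0.0
    for step in (-1, 1):
        curve = [(core_idx, 1.0)]
        j = core_idx + step
        while 0 <= j < haps.shape[1]:
            e = ehh_pairwise_oracle(haps, core_idx, allele, j)
            curve.append((j, e))
            if e < cutoff:
                break
            j += step
        total += ihh(curve, positions)
    return total


# ---------------------------------------------------------------------------
# Standardization and window scan
# ---------------------------------------------------------------------------


def bin_standardize(scores: pd.DataFrame, bin_width: float = 0.025, min_bin_count: int = 10) -> pd.DataFrame:
    """Standardize raw scores within derived-allele-frequency bins.

    Bins of ``bin_width`` cover (0, 1); bins holding fewer than
    ``min_bin_count`` non-NA scores are merged with their left neighbour
    (the first bin merges right) to avoid zero-variance artifacts.  Adds
    ``z`` and two-sided ``neglogp`` columns; NA raw values propagate.
    """
    out = scores.copy()
    raw = out["raw"].to_numpy(dtype=float)
    freq = out["derived_freq"].to_numpy(dtype=float)
    z = np.full(len(out), np.nan)
    n_bins = int(np.ceil(1.0 / bin_width))
    bin_idx = np.minimum((freq / bin_width).astype(int), n_bins - 1)
    valid = np.isfinite(raw)
    # merge sparse bins leftwards
    counts = np.bincount(bin_idx[valid], minlength=n_bins)
    merged = np.arange(n_bins)
    acc = 0
    group = 0
    for b in range(n_bins):
        merged[b] = group
        acc += counts[b]
        if acc >= min_bin_count:
            group += 1
            acc = 0
    if acc > 0 and group > 0:  # leftover tail joins the previous group
        merged[merged == group] = group - 1
    groups = merged[bin_idx]
    for g in np.unique(groups):
        m = valid & (groups == g)
        if m.sum() >= 2 and raw[m].std(ddof=0) > 0:
            z[m] = (raw[m] - raw[m].mean()) / raw[m].std(ddof=0)
    out["z"] = z
    with np.errstate(invalid="ignore"):
        out["neglogp"] = np.where(
            np.isfinite(z), -(norm.logsf(np.abs(z)) + np.log(2)) / np.log(10), np.nan
        )
    return out


@dataclass(frozen=True)
class ScanWindow:
    start_bp: int
    end_bp: int
    n_snps: int
    n_scored: int
    n_outliers: int
    proportion: float
    significant: bool


def window_outlier_scan(
    scores: pd.DataFrame,
    win_bp: int = 500_000,
    slide_bp: int = 100_000,
    outlier_neglogp: float = 2.0,
    prop_threshold: float = 0.10,
):
    """Sliding-window aggregation of per-SNP outliers.

    Windows of ``win_bp`` tile the chromosome every ``slide_bp`` (aligned to
    the slide grid).  The outlier proportion is computed over scored
    (non-NA) SNPs; windows with proportion > ``prop_threshold`` are
    candidate signals, thinned greedily by descending proportion so that the
    reported significant set is non-overlapping.  Returns all non-empty
    windows, significant ones first in descending proportion.
    """
    pos = scores["pos_bp"].to_numpy()
    nl = scores["neglogp"].to_numpy(dtype=float)
    if len(pos) == 0:
        return []
    start0 = (int(pos.min()) // slide_bp) * slide_bp
    windows = []
    start = start0
    while start <= pos.max():
        lo, hi = start + 1, start + win_bp  # 1-based closed
        m = (pos >= lo) & (pos <= hi)
        n_snps = int(m.sum())
        if n_snps:
            scored = np.isfinite(nl[m])
            n_scored = int(scored.sum())
            if n_scored > 0:
                n_out = int((nl[m][scored] > outlier_neglogp).sum())
                prop = n_out / n_scored
                windows.append(
                    ScanWindow(lo, hi, n_snps, n_scored, n_out,
                               float(prop), prop > prop_threshold)
                )
        start += slide_bp
    candidates = sorted(
        (w for w in windows if w.significant),
        key=lambda w: (-w.proportion, w.start_bp),
    )
    selected = []
    for w in candidates:
        if all(w.end_bp < s.start_bp or w.start_bp > s.end_bp for s in selected):
            selected.append(w)
    others = [w for w in windows if w not in selected]
    flagged = [
        ScanWindow(w.start_bp, w.end_bp, w.n_snps, w.n_scored, w.n_outliers, w.proportion, False)
        for w in others
    ]
    return selected + sorted(flagged, key=lambda w: w.start_bp)


def windows_frame(windows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.start_bp, w.end_bp, w.n_snps, w.n_scored, w.n_outliers, w.proportion, w.significant)
            for w in windows
        ],
        columns=["start_bp", "end_bp", "n_snps", "n_scored", "n_outliers", "proportion", "significant"],
    )
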
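"""Haplotype Richness Drop (HRiD) on hemizygous male haplotypes.

Male X genotypes outside the pseudo-autosomal region are single haplotypes,
so haplotype richness can be measured directly, without phasing.  The
chromosome is cut into overlapping windows of a fixed number of SNPs; in
each window the effective number of haplotypes

    n_h = 1 / sum_k p_k^2

(the reciprocal of the expected haplotype homozygosity, the haplotype
analogue of the effective number of alleles) is computed over the male
haplotypes.  A hard selective sweep collapses richness locally, so the score

    HRiD_i = (n_h(w_{i-1}) + n_h(w_{i+1})) / (2 * n_h(w_i))

fluctuates around 1 under neutrality and rises sharply where a window's
richness drops relative to its flanks.  The first and last windows use the
single available flank twice: HRiD_1 = 2*n_h(w_2) / (2*n_h(w_1)) and
HRiD_L = 2*n_h(w_{L-1}) / (2*n_h(w_L)).  Scores are standardized and mapped
to a one-sided upper-tail -log10(P); windows above the significance
threshold are merged (when overlapping or adjacent) into signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

MISSING = -1

logger = logging.getLogger(__name__)


@dataclass
class HridWindow:
    index: int                    # 1-based window index
    first_snp: int                # 0-based index into the non-PAR SNP array
    last_snp: int                 # inclusive
    start_bp: int
    end_bp: int
    n_males_used: int = 0
    n_a: int = 0                  # unique haplotypes
    n_h: float = np.nan           # effective number of haplotypes
    usable: bool = True
    hrid: float = np.nan
    neglogp: float = np.nan
    significant: bool = False
    counts: dict = field(default_factory=dict, repr=False)


def build_windows(snpmap_nonpar: pd.DataFrame, size: int = 70, step: int = 35):
    """SNP-count windows over the non-PAR SNP map (spans only).

    Window ``i`` (1-based) covers SNP indices ``[(i-1)*step, (i-1)*step +
    size - 1]``; only full windows of exactly ``size`` SNPs are emitted, so
    a trailing remainder shorter than ``size`` is left unscanned (logged).
    """
    if size <= 0 or not 0 < step <= size:
        raise ValueError("need size > 0 and 0 < step <= size")
    if snpmap_nonpar["in_par"].any():
        raise ValueError("window construction expects non-PAR SNPs only")
    n = len(snpmap_nonpar)
    if n < size:
        raise ValueError(f"{n} SNPs is fewer than one window of {size}")
    pos = snpmap_nonpar["pos_bp"].to_numpy()
    windows = []
    i = 1
    first = 0
    while first + size <= n:
        last = first + size - 1
        windows.append(
            HridWindow(index=i, first_snp=first, last_snp=last,
                       start_bp=int(pos[first]), end_bp=int(pos[last]))
        )
        i += 1
        first += step
    leftover = n - (windows[-1].last_snp + 1)
    if leftover > 0:
        logger.info("trailing %d SNPs do not fill a %d-SNP window; unscanned", leftover, size)
    return windows


def window_haplotype_counts(male_haps: np.ndarray, window: HridWindow, max_missing_frac: float = 0.0):
    """Unique-haplotype multiset for one window.

    ``male_haps`` is the (n_males, n_snps_nonpar) hemizygous haplotype
    matrix (missing = -1).  Males whose fraction of missing calls inside the
    window exceeds ``max_missing_frac`` are excluded; the remaining rows are
    grouped into haplotype-string counts.  A window where every male is
    excluded is flagged unusable.
    """
    sub = male_haps[:, window.first_snp:window.last_snp + 1]
    miss_frac = (sub == MISSING).mean(axis=1)
    keep = miss_frac <= max_missing_frac
    window.n_males_used = int(keep.sum())
    if window.n_males_used == 0:
        window.usable = False
        window.counts = {}
        window.n_a = 0
        window.n_h = np.nan
        return {}
    rows = sub[keep]
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    cdict = {bytes(u.astype(np.int8)): int(c) for u, c in zip(uniq, counts)}
    window.counts = cdict
    window.n_a = len(cdict)
    window.n_h = effective_num_haplotypes(list(cdict.values()))
    return cdict


def effective_num_haplotypes(counts) -> float:
    """n_h = 1 / sum(p_k^2) with p_k the haplotype frequencies."""
    counts = np.asarray(list(counts), dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("empty haplotype count multiset")
    p = counts / total
    return float(1.0 / np.sum(p**2))


def hrid_scores(windows):
    """Fill the HRiD score on a list of windows with n_h computed.

    Interior windows compare against both flanks; the first and last use
    their single flank twice.  An unusable window (or flank) propagates NA.
    Needs >= 2 windows.  Returns the same list, scores filled in place.
    """
    L = len(windows)
    if L < 2:
        raise ValueError("HRiD needs at least two windows")
    nh = np.array([w.n_h if w.usable else np.nan for w in windows])
    for i, w in enumerate(windows):
        if not w.usable or not np.isfinite(nh[i]):
            w.hrid = np.nan
            continue
        if i == 0:
            num = 2.0 * nh[1]
        elif i == L - 1:
            num = 2.0 * nh[L - 2]
        else:
            num = nh[i - 1] + nh[i + 1]
        w.hrid = float(num / (2.0 * nh[i])) if np.isfinite(num) else np.nan
    return windows


def hrid_neglogp(windows, threshold: float = 3.3):
    """Standardize HRiD scores and attach one-sided -log10(P).

    z = (HRiD - mean)/sd over non-NA windows; P is the upper-tail
    standard-normal probability, so richness drops (large HRiD) are
    significant.  ``significant`` is set where -log10(P) >= ``threshold``.
    """
    vals = np.array([w.hrid for w in windows], dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-NA HRiD values to normalize")
    sd = vals[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("HRiD scores have zero variance; cannot normalize")
    mean = vals[ok].mean()
    for w, v in zip(windows, vals):
        if np.isfinite(v):
            z = (v - mean) / sd
            w.neglogp = float(-norm.logsf(z) / np.log(10))
            w.significant = w.neglogp >= threshold
        else:
            w.neglogp = np.nan
            w.significant = False
    return windows


@dataclass(frozen=True)
class HridSignal:
    start_bp: int
    end_bp: int
    window_indices: tuple
    peak_hrid: float
    peak_neglogp: float


def hrid_signals(windows, merge: bool = True):
    """Group significant windows into signals.

    With ``merge`` (default), significant windows whose bp spans overlap or
    are adjacent (consecutive window indices) are unioned into one signal;
    without it, each significant window is reported on its own — the
    convention under which two overlapping windows over one swept region
    appear as two listed signals.
    """
    sig = [w for w in windows if w.significant]
    if not sig:
        return []
    if not merge:
        return [
            HridSignal(w.start_bp, w.end_bp, (w.index,), w.hrid, w.neglogp)
            for w in sig
        ]
    sig = sorted(sig, key=lambda w: w.index)
    out = []
    cluster = [sig[0]]
    for w in sig[1:]:
        prev = cluster[-1]
        if w.index == prev.index + 1 or w.start_bp <= prev.end_bp:
            cluster.append(w)
        else:
            out.append(_make_signal(cluster))
            cluster = [w]
    out.append(_make_signal(cluster))
    return out


def _make_signal(cluster):
    return HridSignal(
        start_bp=min(w.start_bp for w in cluster),
        end_bp=max(w.end_bp for w in cluster),
        window_indices=tuple(w.index for w in cluster),
        peak_hrid=max(w.hrid for w in cluster),
        peak_neglogp=max(w.neglogp for w in cluster),
    )


def hrid_scan(male_haps, snpmap_nonpar, size: int = 70, step: int = 35,
              threshold: float = 3.3, max_missing_frac: float = 0.0,
              merge: bool = True):
    """Full HRiD pipeline: windows -> n_h -> scores -> significance -> signals.

    Returns ``(windows, signals)``.
    """
    windows = build_windows(snpmap_nonpar, size=size, step=step)
    for w in windows:
        window_haplotype_counts(male_haps, w, max_missing_frac=max_missing_frac)
    hrid_scores(windows)
    hrid_neglogp(windows, threshold=threshold)
    return windows, hrid_signals(windows, merge=merge)


def windows_frame(windows) -> pd.DataFrame:
    """Per-window table mirroring the published reporting columns."""
    return pd.DataFrame(
        [
            (w.index, w.start_bp, w.end_bp, w.n_males_used, w.n_a, w.n_h, w.hrid, w.neglogp, w.significant)
            for w in windows
        ],
        columns=["index", "start_bp", "end_bp", "n_males_used", "n_a", "n_h", "hrid", "neglogp", "significant"],
    )
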
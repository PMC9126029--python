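"""Runs of homozygosity in diploid females and extreme-ROH-island signals.

ROH are called per length class (0.25-1, 1-2, 2-4, 4-8, 8-16, >16 Mb) with
class-specific heterozygote/missing allowances, so that short classes stay
strict while long classes tolerate the array's genotyping error rate.  The
per-SNP ROH frequency across females is standardized and mapped to an
upper-tail -log10(P); runs of consecutive outlier SNPs become candidate
positive-selection signals.  The multiple-testing threshold can be derived
from the effective number of independent tests (simpleM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import MISSING, GenotypeMatrix

MB = 1_000_000

#: (lo_bp, hi_bp, max_het, max_missing) for the six length classes.  The
#: 0.25-1 Mb class allows no heterozygotes or missing calls; allowances for
#: the longer classes follow common HD-chip practice and are configurable.
DEFAULT_CLASSES = [
    (250_000, 1 * MB, 0, 0),
    (1 * MB, 2 * MB, 0, 1),
    (2 * MB, 4 * MB, 0, 2),
    (4 * MB, 8 * MB, 1, 4),
    (8 * MB, 16 * MB, 2, 8),
    (16 * MB, 10**12, 4, 16),
]


@dataclass
class ROHParams:
    min_snps: int = 15
    max_gap_bp: int = 250_000
    min_density_bp_per_snp: int = 20_000   # at least one SNP per 20 kb
    min_len_bp: int = 250_000
    classes: list = field(default_factory=lambda: [tuple(c) for c in DEFAULT_CLASSES])

    def __post_init__(self):
        for (lo, hi, _, _), (lo2, _, _, _) in zip(self.classes, self.classes[1:]):
            if hi != lo2:
                raise ValueError("length classes must be contiguous and non-overlapping")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int
    length_class: int  # index into params.classes

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _segment_ok(pos, het, mis, i, j, params, max_het, max_missing):
    """Constraint check for SNP-index window [i, j] (closed)."""
    n = j - i + 1
    if n < params.min_snps:
        return False
    length = pos[j] - pos[i] + 1
    if length < params.min_len_bp:
        return False
    if het[i:j + 1].sum() > max_het or mis[i:j + 1].sum() > max_missing:
        return False
    if n > 1 and np.max(np.diff(pos[i:j + 1])) > params.max_gap_bp:
        return False
    if length > n * params.min_density_bp_per_snp:
        return False
    return True


def _call_roh_one(pos, calls, params: ROHParams, sample_id):
    """All maximal qualifying runs for one female, over all classes."""
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    n = len(pos)
    het_cum = np.concatenate([[0], np.cumsum(het)])
    mis_cum = np.concatenate([[0], np.cumsum(mis)])
    gaps = np.diff(pos)
    out = []
    for ci, (lo, hi, max_het, max_missing) in enumerate(params.classes):
        # two-pointer scan for maximal windows satisfying het/missing/gap
        segs = []
        i = 0
        j = -1
        last_j = -1
        while i < n:
            if j < i:
                j = i
            # extend right as far as the allowance and gap constraints permit
            while j + 1 < n:
                if gaps[j] > params.max_gap_bp:
                    break
                if het_cum[j + 2] - het_cum[i] > max_het:
                    break
                if mis_cum[j + 2] - mis_cum[i] > max_missing:
                    break
                j += 1
            if j > last_j:  # maximal: not contained in the previous window
                segs.append((i, j))
                last_j = j
            if j + 1 < n and gaps[j] > params.max_gap_bp:
                i = j + 1
                j = i - 1
            else:
                i += 1
        for i, j in segs:
            n_snps = j - i + 1
            length = pos[j] - pos[i] + 1
            if n_snps < params.min_snps or length < params.min_len_bp:
                continue
            if not (lo <= length < hi) or length < lo:
                continue
            if length > n_snps * params.min_density_bp_per_snp:
                continue
            out.append(
                ROHSegment(
                    sample_id=sample_id,
                    start_bp=int(pos[i]),
                    end_bp=int(pos[j]),
                    n_snps=n_snps,
                    n_het=int(het_cum[j + 1] - het_cum[i]),
                    n_missing=int(mis_cum[j + 1] - mis_cum[i]),
                    length_class=ci,
                )
            )
    return out


def call_roh(gm_females: GenotypeMatrix, params: ROHParams | None = None):
    """Call ROH segments in a diploid (female) genotype matrix.

    Every maximal run satisfying the SNP-count, gap, density and length
    constraints plus its class's het/missing allowance is reported once per
    class whose length range contains it.  Passing males raises: hemizygous
    samples are homozygous by construction and would flood the caller.
    """
    params = params or ROHParams()
    if (gm_females.samples["sex"] == "male").any():
        raise ValueError("call_roh expects diploid females only")
    pos = gm_females.snps["pos_bp"].to_numpy()
    segments = []
    for k, sid in enumerate(gm_females.samples["sample_id"]):
        segments.extend(_call_roh_one(pos, gm_females.calls[:, k], params, sid))
    return segments


def roh_brute_force(pos, calls, params: ROHParams, sample_id="s"):
    """Independent oracle: enumerate all subsegments, keep qualifying maximal
    ones per class.  Quadratic; for small test inputs only."""
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    n = len(pos)
    out = []
    for ci, (lo, hi, max_het, max_missing) in enumerate(params.classes):
        ok = [
            (i, j)
            for i in range(n)
            for j in range(i, n)
            if _segment_ok(pos, het, mis, i, j, params, max_het, max_missing)
            and lo <= pos[j] - pos[i] + 1 < hi
        ]
        # maximality is with respect to the allowance constraints (not the
        # class length range): a window extendable without breaking the
        # het/missing/gap rules is not maximal
        def extendable(i, j):
            for i2, j2 in ((i - 1, j), (i, j + 1)):
                if 0 <= i2 and j2 < n:
                    if (
                        het[i2:j2 + 1].sum() <= max_het
                        and mis[i2:j2 + 1].sum() <= max_missing
                        and np.max(np.diff(pos[i2:j2 + 1])) <= params.max_gap_bp
                    ):
                        return True
            return False

        for i, j in ok:
            if not extendable(i, j):
                out.append(
                    ROHSegment(sample_id, int(pos[i]), int(pos[j]), j - i + 1,
                               int(het[i:j + 1].sum()), int(mis[i:j + 1].sum()), ci)
                )
    return out


def segments_frame(segments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.start_bp, s.end_bp, s.length_bp, s.n_snps, s.n_het, s.n_missing, s.length_class)
            for s in segments
        ],
        columns=["sample_id", "start_bp", "end_bp", "length_bp", "n_snps", "n_het", "n_missing", "length_class"],
    )


def snp_roh_frequency(segments, snpmap: pd.DataFrame, n_females: int) -> pd.DataFrame:
    """Fraction of females whose ROH (union over classes) cover each SNP.

    A female counts once per SNP no matter how many of her segments overlap
    it.  Returns a per-SNP frame with ``count`` and ``frequency``.
    """
    pos = snpmap["pos_bp"].to_numpy()
    covered = {}
    for s in segments:
        lo = np.searchsorted(pos, s.start_bp, side="left")
        hi = np.searchsorted(pos, s.end_bp, side="right")
        mask = covered.setdefault(s.sample_id, np.zeros(len(pos), dtype=bool))
        mask[lo:hi] = True
    count = np.zeros(len(pos), dtype=np.int64)
    for mask in covered.values():
        count += mask
    return pd.DataFrame(
        {
            "snp_id": snpmap["snp_id"],
            "pos_bp": pos,
            "count": count,
            "frequency": count / n_females,
        }
    )


def roh_neglogp(freqs: pd.DataFrame) -> pd.DataFrame:
    """Standardize ROH frequencies and convert to upper-tail -log10(P).

    z = (f - mean)/sd across SNPs; P is the one-sided standard-normal
    upper-tail probability, so high-frequency (island) SNPs get large
    -log10(P).
    """
    f = freqs["frequency"].to_numpy(dtype=float)
    sd = f.std(ddof=0)
    if len(f) < 2 or sd == 0:
        raise ValueError("ROH frequencies have zero variance; cannot standardize")
    z = (f - f.mean()) / sd
    out = freqs.copy()
    out["z"] = z
    out["neglogp"] = -norm.logsf(z) / np.log(10)
    return out


@dataclass(frozen=True)
class Signal:
    start_bp: int
    end_bp: int
    n_outlier_snps: int
    peak_neglogp: float


def call_erohi_signals(snp_freqs: pd.DataFrame, threshold: float, min_consecutive: int = 2):
    """Merge runs of >= ``min_consecutive`` consecutive outlier SNPs into
    signals, ranked by peak -log10(P)."""
    nl = snp_freqs["neglogp"].to_numpy()
    pos = snp_freqs["pos_bp"].to_numpy()
    outlier = nl >= threshold
    signals = []
    i = 0
    n = len(nl)
    while i < n:
        if outlier[i]:
            j = i
            while j + 1 < n and outlier[j + 1]:
                j += 1
            if j - i + 1 >= min_consecutive:
                signals.append(
                    Signal(int(pos[i]), int(pos[j]), j - i + 1, float(nl[i:j + 1].max()))
                )
            i = j + 1
        else:
            i += 1
    return sorted(signals, key=lambda s: -s.peak_neglogp)


# ---------------------------------------------------------------------------
# simpleM effective number of tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimpleMResult:
    m_snps: int
    m_eff: int
    threshold_neglogp: float


def simple_m(gm, variance_explained: float = 0.995, block_size: int | None = None) -> SimpleMResult:
    """Effective number of independent tests from genotype correlations.

    Eigendecomposes the SNP x SNP composite-LD (Pearson) correlation matrix
    and takes the smallest number of principal components whose cumulative
    eigenvalue share reaches ``variance_explained``.  With ``block_size``,
    contiguous blocks are processed independently and their m_eff summed,
    the method's standard practice for large maps.  Constant SNPs are
    excluded before the decomposition.

    Accepts a :class:`GenotypeMatrix` or a plain (n_snps, n_samples) dosage
    array.  Threshold is the Bonferroni-style ``-log10(0.05 / m_eff)``.
    """
    calls = gm.calls if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    m_snps = calls.shape[0]
    x = calls.astype(float)
    x[x == MISSING] = np.nan
    mean = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), mean, x)  # mean-impute missing for correlation
    keep = np.nanstd(x, axis=1) > 0
    x = x[keep]
    if x.shape[0] == 0:
        raise ValueError("all SNPs constant; simpleM undefined")
    if x.shape[0] == 1:
        return SimpleMResult(m_snps, 1, float(-np.log10(0.05)))
    if block_size is None or block_size >= x.shape[0]:
        blocks = [x]
    else:
        blocks = [x[i:i + block_size] for i in range(0, x.shape[0], block_size)]
    m_eff = 0
    for b in blocks:
        if b.shape[0] == 1:
            m_eff += 1
            continue
        corr = np.corrcoef(b)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        ev = np.linalg.eigvalsh(corr)[::-1]
        ev = np.clip(ev, 0, None)
        share = np.cumsum(ev) / ev.sum()
        m_eff += int(np.searchsorted(share, variance_explained) + 1)
    return SimpleMResult(m_snps, m_eff, float(-np.log10(0.05 / m_eff)))
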
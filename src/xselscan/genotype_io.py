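"""Genotype containers, PLINK/VCF input-output, sex-aware QC and PAR detection.

The central object is :class:`GenotypeMatrix`: an allele-B dosage matrix
(SNPs x samples, values 0/1/2 with -1 for missing) together with a SNP map
and a sample sheet.  The X chromosome is treated sex-aware throughout: males
are hemizygous outside the pseudo-autosomal region (PAR), so their legal
dosages there are {0, 2, missing} and a heterozygous male call outside the
PAR is a genotyping artifact.

Conventions
-----------
* Positions are 1-based; intervals are reported closed ``[start_bp, end_bp]``.
* ``calls`` is ``int8`` with ``-1`` encoding a missing call.
* The ancestral allele per SNP is one of ``"a"``, ``"b"`` or ``"unknown"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b", "ancestral", "in_par"]
SAMPLE_COLUMNS = ["sample_id", "sex", "population", "species"]


def make_snp_map(
    snp_id,
    pos_bp,
    chrom="X",
    allele_a=None,
    allele_b=None,
    ancestral=None,
    in_par=None,
    gentrain=None,
    gencall=None,
) -> pd.DataFrame:
    """Assemble a SNP map DataFrame with the canonical columns.

    Positions must be strictly increasing within the chromosome; alleles
    default to A/B placeholders and the ancestral state to ``"unknown"``.
    """
    n = len(snp_id)
    df = pd.DataFrame(
        {
            "snp_id": list(snp_id),
            "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "allele_a": list(allele_a) if allele_a is not None else ["A"] * n,
            "allele_b": list(allele_b) if allele_b is not None else ["B"] * n,
            "ancestral": list(ancestral) if ancestral is not None else ["unknown"] * n,
            "in_par": np.asarray(in_par, dtype=bool) if in_par is not None else np.zeros(n, dtype=bool),
        }
    )
    if gentrain is not None:
        df["gentrain"] = np.asarray(gentrain, dtype=float)
    if gencall is not None:
        df["gencall"] = np.asarray(gencall, dtype=float)
    for c in df.groupby("chrom", sort=False):
        pos = c[1]["pos_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError("SNP positions must be strictly increasing within a chromosome")
    return df


def make_sample_sheet(sample_id, sex, population, species) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": list(sample_id),
            "sex": list(sex),
            "population": list(population),
            "species": list(species),
        }
    )
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {bad_sex}")
    bad_sp = set(df["species"]) - {"focal", "outgroup"}
    if bad_sp:
        raise ValueError(f"unknown species labels: {bad_sp}")
    return df


@dataclass
class GenotypeMatrix:
    """SNP x sample allele-B dosage matrix with sex/species metadata.

    Attributes
    ----------
    snps
        SNP map (one row per SNP, sorted by position).
    samples
        Sample sheet (sample_id, sex, population, species).
    calls
        ``int8`` array of shape ``(n_snps, n_samples)``; allele-B dosage
        0/1/2, ``-1`` for missing.
    """

    snps: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snps), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_mask(self, sex=None, species=None) -> np.ndarray:
        m = np.ones(self.n_samples, dtype=bool)
        if sex is not None:
            m &= (self.samples["sex"] == sex).to_numpy()
        if species is not None:
            m &= (self.samples["species"] == species).to_numpy()
        return m

    def subset(self, snp_mask=None, sample_mask=None) -> "GenotypeMatrix":
        snps = self.snps if snp_mask is None else self.snps.loc[snp_mask].reset_index(drop=True)
        samples = self.samples if sample_mask is None else self.samples.loc[sample_mask].reset_index(drop=True)
        calls = self.calls
        if snp_mask is not None:
            calls = calls[np.asarray(snp_mask)]
        if sample_mask is not None:
            calls = calls[:, np.asarray(sample_mask)]
        return GenotypeMatrix(snps, samples, calls.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.snps[SNP_COLUMNS].reset_index(drop=True).equals(other.snps[SNP_COLUMNS].reset_index(drop=True))
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK bed v1.00, SNP-major

# two-bit PLINK codes -> allele-B dosage of allele2 (bim column 5 = A1 = minor
# by PLINK convention; we store dosage of allele_b = bim allele 6)
_BED_CODE_TO_DOSAGE = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet (sample_id, sex, population, species)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return make_sample_sheet(df["sample_id"], df["sex"], df["population"], df["species"])


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str, sample_sheet) -> GenotypeMatrix:
    """Read genotypes from ``plink-bed`` (.bed/.bim/.fam trio) or ``vcf``.

    ``sample_sheet`` is a path to a TSV or an already-parsed DataFrame mapping
    every genotyped sample id to sex, population and species.  Calls are
    returned as allele-B dosage; SNPs are sorted by position (a warning is
    emitted if the input map was unsorted).
    """
    sheet = read_sample_sheet(sample_sheet) if not isinstance(sample_sheet, pd.DataFrame) else sample_sheet
    if format == "plink-bed":
        gm = _read_plink(path, sheet)
    elif format == "vcf":
        gm = _read_vcf(path, sheet)
    else:
        raise ValueError(f"unknown format {format!r}")
    pos = gm.snps["pos_bp"].to_numpy()
    if not np.all(np.diff(pos) > 0):
        warnings.warn("SNP map not sorted by position; sorting")
        order = np.argsort(pos, kind="stable")
        gm = GenotypeMatrix(gm.snps.iloc[order].reset_index(drop=True), gm.samples, gm.calls[order])
    return gm


def _align_sheet(ids, sheet: pd.DataFrame) -> pd.DataFrame:
    lookup = sheet.set_index("sample_id")
    unknown = [s for s in ids if s not in lookup.index]
    if unknown:
        raise ValueError(f"sample ids absent from sample sheet: {unknown[:5]}")
    out = lookup.loc[list(ids)].reset_index()
    return out[SAMPLE_COLUMNS]


def _read_plink(prefix, sheet: pd.DataFrame) -> GenotypeMatrix:
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele_a1", "allele_a2"],
        dtype={"chrom": str, "snp_id": str, "allele_a1": str, "allele_a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex_code", "pheno"],
        dtype=str,
    )
    n_snps, n_samples = len(bim), len(fam)
    data = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if bytes(data[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK v1.00 .bed file")
    bytes_per_snp = (n_samples + 3) // 4
    body = data[3:].reshape(n_snps, bytes_per_snp)
    # unpack two-bit genotype codes, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snps, -1)[:, :n_samples]
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    calls = lut[codes]
    snps = make_snp_map(
        bim["snp_id"],
        bim["pos_bp"],
        chrom=bim["chrom"],
        allele_a=bim["allele_a1"],  # A1: dosage counts allele_b = A2? see below
        allele_b=bim["allele_a2"],
    )
    # PLINK counts A1 copies in its additive coding; bed code 0b00 is "hom A1".
    # We store allele-B dosage with allele_b = bim A1 so that code 0b00 -> 2.
    snps["allele_a"], snps["allele_b"] = list(bim["allele_a2"]), list(bim["allele_a1"])
    samples = _align_sheet(fam["iid"], sheet)
    return GenotypeMatrix(snps, samples, calls)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write a SNP-major PLINK v1.00 .bed/.bim/.fam trio."""
    prefix = str(prefix)
    with open(prefix + ".bim", "w") as fh:
        for r in gm.snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\t{r.allele_b}\t{r.allele_a}\n")
    with open(prefix + ".fam", "w") as fh:
        for r in gm.samples.itertuples(index=False):
            code = 1 if r.sex == "male" else 2
            fh.write(f"{r.population}\t{r.sample_id}\t0\t0\t{code}\t-9\n")
    n_samples = gm.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    code_map = np.empty(4, dtype=np.uint8)
    code_map[0] = 0b11
    code_map[1] = 0b10
    code_map[2] = 0b00
    code_map[3] = 0b01  # index 3 stands for missing (-1 mod 4)
    codes = code_map[gm.calls % 4]
    pad = (-n_samples) % 4
    if pad:
        codes = np.concatenate([codes, np.ones((gm.n_snps, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(gm.n_snps, bytes_per_snp, 4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    out = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def _read_vcf(path, sheet: pd.DataFrame) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    samples = _align_sheet(ids, sheet)
    rows, call_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at {var.CHROM}:{var.POS}")
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1)
        a0, a1 = gts[:, 0], gts[:, 1]
        dos = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
        call_rows.append(dos)
    vcf.close()
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"])
    snps = make_snp_map(df["snp_id"], df["pos_bp"], chrom=df["chrom"],
                        allele_a=df["allele_a"], allele_b=df["allele_b"])
    calls = np.array(call_rows, dtype=np.int8) if call_rows else np.zeros((0, len(ids)), dtype=np.int8)
    return GenotypeMatrix(snps, samples, calls)


def read_phased_vcf(path, sample_sheet):
    """Read a phased VCF into ``(GenotypeMatrix, haplotype array)``.

    The haplotype array has shape ``(n_samples, 2, n_snps)`` with missing
    alleles as -1.  Unphased heterozygous records raise: statistical phasing
    is out of scope, so phase must come from upstream (or from hemizygosity).
    """
    from cyvcf2 import VCF

    sheet = read_sample_sheet(sample_sheet) if not isinstance(sample_sheet, pd.DataFrame) else sample_sheet
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    samples = _align_sheet(ids, sheet)
    rows, h0_rows, h1_rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at {var.CHROM}:{var.POS}")
            continue
        gts = var.genotype.array()
        a0 = gts[:, 0].astype(np.int8)
        a1 = gts[:, 1].astype(np.int8)
        phased = gts[:, 2].astype(bool) if gts.shape[1] > 2 else np.zeros(len(ids), bool)
        het = (a0 >= 0) & (a1 >= 0) & (a0 != a1)
        if (het & ~phased).any():
            raise ValueError(
                f"unphased heterozygous call at {var.CHROM}:{var.POS}; phased input required"
            )
        a0[a0 < 0] = MISSING
        a1[a1 < 0] = MISSING
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
        h0_rows.append(a0)
        h1_rows.append(a1)
    vcf.close()
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"])
    snps = make_snp_map(df["snp_id"], df["pos_bp"], chrom=df["chrom"],
                        allele_a=df["allele_a"], allele_b=df["allele_b"])
    h0 = np.array(h0_rows, dtype=np.int8).T  # (n_samples, n_snps)
    h1 = np.array(h1_rows, dtype=np.int8).T
    haps = np.stack([h0, h1], axis=1)
    calls = np.where((h0 == MISSING) | (h1 == MISSING), MISSING, h0 + h1).astype(np.int8)
    gm = GenotypeMatrix(snps, samples, calls.T)
    return gm, haps


def write_vcf(gm: GenotypeMatrix, path, haplotypes=None) -> None:
    """Write a VCF 4.2 with GT calls.

    Without ``haplotypes``, diploid dosages are written unphased ("0/1") and
    dosage-2/0 hemizygous-style calls stay diploid for portability.  With a
    ``(n_samples, 2, n_snps)`` phased array, calls are written phased ("0|1").
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples["sample_id"]) + "\n")
        for i, r in enumerate(gm.snps.itertuples(index=False)):
            fields = [r.chrom, str(r.pos_bp), r.snp_id, r.allele_a, r.allele_b, ".", "PASS", ".", "GT"]
            if haplotypes is not None:
                h0, h1 = haplotypes[:, 0, i], haplotypes[:, 1, i]
                gts = [
                    "./." if (a < 0 or b < 0) else f"{a}|{b}"
                    for a, b in zip(h0, h1)
                ]
            else:
                lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [lut[int(d)] for d in gm.calls[i]]
            fh.write("\t".join(fields + gts) + "\n")


# ---------------------------------------------------------------------------
# Heterozygosity and PAR detection
# ---------------------------------------------------------------------------


def observed_heterozygosity(gm: GenotypeMatrix, sex: str) -> pd.DataFrame:
    """Per-SNP observed heterozygosity H_O for one sex.

    H_O is the fraction of non-missing calls equal to dosage 1.  SNPs where
    every call of the requested sex is missing get ``NaN`` H_O and
    ``defined=False`` rather than zero.
    """
    mask = gm.sample_mask(sex=sex)
    if mask.sum() < 1:
        raise ValueError(f"no samples of sex {sex!r}")
    sub = gm.calls[:, mask]
    nonmiss = (sub != MISSING).sum(axis=1)
    het = (sub == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ho = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    return pd.DataFrame(
        {
            "snp_id": gm.snps["snp_id"],
            "pos_bp": gm.snps["pos_bp"],
            "h_obs": ho,
            "n_nonmissing": nonmiss,
            "defined": nonmiss > 0,
        }
    )


def detect_par(gm: GenotypeMatrix, window_snps: int = 50, het_floor: float = 0.01):
    """Locate the pseudo-autosomal boundary from male heterozygosity.

    Males are diploid (heterozygous at typical rates) inside the PAR and
    hemizygous beyond it, so male H_O collapses to ~0 at the boundary.  For
    each SNP index ``i`` the mean male H_O over the ``window_snps`` SNPs
    starting at ``i`` is computed; the boundary is the position of the last
    SNP before the first index at which this mean drops below ``het_floor``
    and stays below for the rest of the chromosome.  Isolated heterozygous
    SNPs beyond the boundary are tolerated by the windowed mean and returned
    as mis-genotyped.

    Returns
    -------
    (par_boundary_bp, mis_genotyped_snp_ids)
        ``par_boundary_bp`` is 0 when no SNP is in the PAR.
    """
    n_males = int(gm.sample_mask(sex="male").sum())
    if n_males < 10:
        raise ValueError(f"PAR detection needs >=10 males, got {n_males}")
    prof = observed_heterozygosity(gm, "male")
    ho = prof["h_obs"].to_numpy()
    ho_filled = np.nan_to_num(ho, nan=0.0)
    n = len(ho_filled)
    w = min(window_snps, n)
    # forward-looking windowed mean at each start index
    csum = np.concatenate([[0.0], np.cumsum(ho_filled)])
    starts = np.arange(n - w + 1)
    win_mean = (csum[starts + w] - csum[starts]) / w
    below = win_mean < het_floor
    # first start index from which every later window is also below the floor
    suffix_all_below = np.logical_and.accumulate(below[::-1])[::-1]
    idx = np.flatnonzero(suffix_all_below)
    pos = gm.snps["pos_bp"].to_numpy()
    if len(idx) == 0:
        warnings.warn("no hemizygous transition found; treating whole chromosome as PAR")
        boundary_idx = n  # all PAR
    else:
        boundary_idx = int(idx[0])  # approximate first hemizygous SNP index
        # refine within the first qualifying window: a trailing diploid SNP
        # (H_O well above the floor) can sit inside it, while isolated
        # mis-genotyped hemizygous SNPs stay near zero H_O and are ignored
        hi = min(boundary_idx + w, n)
        diploid_like = np.flatnonzero(ho_filled[boundary_idx:hi] > 10 * het_floor)
        if len(diploid_like):
            boundary_idx += int(diploid_like[-1]) + 1
        if boundary_idx == 0:
            warnings.warn("male heterozygosity low from the start; no PAR detected")
    boundary_bp = int(pos[boundary_idx - 1]) if boundary_idx > 0 else 0
    # mis-genotyped: any male het call beyond the boundary
    male_calls = gm.calls[:, gm.sample_mask(sex="male")]
    has_het = (male_calls == 1).any(axis=1)
    beyond = np.arange(n) >= boundary_idx
    mis_ids = gm.snps.loc[has_het & beyond, "snp_id"].tolist()
    return boundary_bp, mis_ids


def flag_par(gm: GenotypeMatrix, boundary_bp: int) -> GenotypeMatrix:
    """Set the SNP map's ``in_par`` flag for positions up to ``boundary_bp``."""
    snps = gm.snps.copy()
    snps["in_par"] = snps["pos_bp"].to_numpy() <= boundary_bp
    return GenotypeMatrix(snps, gm.samples, gm.calls)


def clean_hemizygous(gm: GenotypeMatrix, drop_snps=True):
    """Remove male-heterozygote artifacts outside the PAR.

    Heterozygous male calls beyond the PAR boundary are physically impossible
    (one X copy).  Offending calls are set to missing; with ``drop_snps``
    (default) any non-PAR SNP carrying at least one such call is removed
    entirely, mirroring array-QC practice for mis-clustered probes.

    Returns ``(cleaned GenotypeMatrix, list of dropped/flagged snp_ids)``.
    """
    male = gm.sample_mask(sex="male")
    nonpar = ~gm.snps["in_par"].to_numpy()
    bad = (gm.calls == 1) & male[None, :] & nonpar[:, None]
    flagged = gm.snps.loc[bad.any(axis=1), "snp_id"].tolist()
    calls = gm.calls.copy()
    calls[bad] = MISSING
    out = GenotypeMatrix(gm.snps, gm.samples, calls)
    if drop_snps and flagged:
        keep = ~out.snps["snp_id"].isin(flagged).to_numpy()
        out = out.subset(snp_mask=keep)
    return out, flagged


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def hwe_exact_midp(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Mid-p Hardy-Weinberg exact test for one biallelic SNP.

    Exact conditional distribution of the heterozygote count given allele
    counts; the mid-p variant halves the probability of the observed
    configuration, reducing the conservativeness of the plain exact test.
    """
    n = n_het + n_hom_a + n_hom_b
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    # enumerate heterozygote counts with the parity of n_rare
    het_possible = np.arange(n_rare % 2, n_rare + 1, 2)
    logprob = np.zeros(len(het_possible))
    from scipy.special import gammaln

    rare_hom = (n_rare - het_possible) // 2
    common_hom = n - het_possible - rare_hom
    logprob = (
        het_possible * np.log(2)
        + gammaln(n + 1)
        - gammaln(het_possible + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    p_obs = prob[het_possible == n_het][0]
    p = prob[prob <= p_obs].sum() - 0.5 * p_obs
    return float(min(max(p, 0.0), 1.0))


def qc_filter(
    gm: GenotypeMatrix,
    snp_call_rate: float = 0.90,
    hwe_p: float = 1e-7,
    ind_call_rate: float = 0.95,
    gentrain: float = 0.4,
    gencall: float = 0.8,
):
    """Array-quality and population-genetic SNP/sample filtering.

    Removal rules (each applied when the needed metadata exists):

    * GenTrain score < ``gentrain``; GenCall score <= ``gencall``
    * SNP call rate < ``snp_call_rate``
    * Hardy-Weinberg exact mid-p < ``hwe_p`` (strict "<": a SNP exactly at
      the threshold is retained).  Outside the PAR only diploid females
      enter the test; inside the PAR all samples do.
    * individuals with call rate < ``ind_call_rate``

    Returns ``(filtered GenotypeMatrix, report DataFrame)`` where the report
    lists each dropped SNP/sample and the first reason that removed it.
    """
    reasons = []
    n_snps, n_samples = gm.n_snps, gm.n_samples
    drop_snp = np.zeros(n_snps, dtype=bool)
    reason_snp = np.array([""] * n_snps, dtype=object)

    def _mark(mask, reason):
        new = mask & ~drop_snp
        reason_snp[new] = reason
        drop_snp[new] = True

    if "gentrain" in gm.snps.columns:
        _mark(gm.snps["gentrain"].to_numpy() < gentrain, "gentrain")
    else:
        logger.info("no GenTrain scores in SNP map; skipping GenTrain filter")
    if "gencall" in gm.snps.columns:
        _mark(gm.snps["gencall"].to_numpy() <= gencall, "gencall")
    else:
        logger.info("no GenCall scores in SNP map; skipping GenCall filter")

    callrate = (gm.calls != MISSING).mean(axis=1)
    _mark(callrate < snp_call_rate, "call_rate")

    in_par = gm.snps["in_par"].to_numpy()
    female = gm.sample_mask(sex="female")
    hwe_fail = np.zeros(n_snps, dtype=bool)
    for i in range(n_snps):
        if drop_snp[i]:
            continue
        row = gm.calls[i, :] if in_par[i] else gm.calls[i, female]
        n_het = int((row == 1).sum())
        n_a = int((row == 0).sum())
        n_b = int((row == 2).sum())
        if n_het + n_a + n_b == 0:
            continue
        if hwe_exact_midp(n_het, n_a, n_b) < hwe_p:
            hwe_fail[i] = True
    _mark(hwe_fail, "hwe")

    kept = gm.subset(snp_mask=~drop_snp)
    for sid, reason in zip(gm.snps.loc[drop_snp, "snp_id"], reason_snp[drop_snp]):
        reasons.append((sid, "snp", reason))

    ind_rate = (kept.calls != MISSING).mean(axis=0) if kept.n_snps else np.ones(n_samples)
    drop_ind = ind_rate < ind_call_rate
    for sid in kept.samples.loc[drop_ind, "sample_id"]:
        reasons.append((sid, "sample", "ind_call_rate"))
    kept = kept.subset(sample_mask=~drop_ind)
    if kept.n_snps == 0:
        warnings.warn("QC removed every SNP")
    report = pd.DataFrame(reasons, columns=["id", "kind", "reason"])
    return kept, report


# ---------------------------------------------------------------------------
# Ancestral alleles
# ---------------------------------------------------------------------------


def assign_ancestral(gm: GenotypeMatrix) -> pd.DataFrame:
    """Set each SNP's ancestral allele to the outgroup majority allele.

    Allele copies are counted over all non-missing outgroup calls; an exact
    tie or an all-missing SNP yields ``"unknown"``.  Returns a new SNP map.
    """
    out_mask = gm.sample_mask(species="outgroup")
    if out_mask.sum() == 0:
        raise ValueError("no outgroup samples available for ancestral assignment")
    sub = gm.calls[:, out_mask]
    nonmiss = sub != MISSING
    b_copies = np.where(nonmiss, sub, 0).sum(axis=1)
    total = 2 * nonmiss.sum(axis=1)
    a_copies = total - b_copies
    anc = np.where(a_copies > b_copies, "a", np.where(b_copies > a_copies, "b", "unknown"))
    anc = np.where(total == 0, "unknown", anc)
    snps = gm.snps.copy()
    snps["ancestral"] = anc
    return snps


def recode_ancestral(haplotypes: np.ndarray, snpmap: pd.DataFrame):
    """Flip haplotype columns so 0 = ancestral, 1 = derived.

    Columns whose SNP has ``ancestral == "b"`` are inverted (missing values
    preserved); unknown-ancestral columns are left untouched and reported.
    The operation is an involution: applying it twice restores the input.

    Returns ``(recoded array, boolean mask of unknown-ancestral columns)``.
    """
    anc = snpmap["ancestral"].to_numpy()
    flip = anc == "b"
    unknown = anc == "unknown"
    out = np.array(haplotypes, copy=True)
    col = out[..., flip]
    col[col >= 0] = 1 - col[col >= 0]
    out[..., flip] = col
    return out, unknown
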
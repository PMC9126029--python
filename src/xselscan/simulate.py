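"""Synthetic X-chromosome SNP-array data with PAR, hemizygous males and sweeps.

A founder-mosaic copying model: ``k_founders`` haplotypes are derived from an
all-ancestral root by independent per-SNP mutation, every sampled chromosome
is then a mosaic of founders (the founder index is resampled at each SNP
boundary with a fixed switch probability, emulating historical recombination),
and genotyping noise (missing calls plus symmetric allele flips) is layered on
last.  Females carry two haplotypes everywhere; males carry two inside the
pseudo-autosomal region (PAR) and a single one beyond it.  Outgroup animals
copy from the founders nearest the root, so the outgroup majority allele
tracks the true ancestral state.

Hard sweeps are injected by overwriting each haplotype inside a SNP span with
a designated swept haplotype with probability ``f_s`` — the signature the
haplotype-richness statistics are designed to detect.

Everything is reproducible from the seed; the returned :class:`SimTruth`
carries the noise-free haplotypes and all latent structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, make_sample_sheet, make_snp_map


@dataclass
class SweepSpec:
    """One hard sweep: haplotypes in ``[snp_start, snp_end]`` (0-based,
    closed, non-PAR indices into the full SNP array) are replaced by a single
    swept haplotype with probability ``f_s`` per haplotype."""

    snp_start: int
    snp_end: int
    f_s: float
    origin: str = "derived"  # {"ancestral", "derived"}


@dataclass
class SimParams:
    """Generator settings.

    Defaults emulate an ovine X-chromosome array scaled to desk size: ~2k
    SNPs with a PAR prefix, 100 hemizygous males + 101 diploid females of the
    focal species and 10 outgroup animals (5 male), neutral mosaic diversity
    from 30 founder haplotypes, and the HD-chip genotyping error rate of
    0.25%.
    """

    n_snps: int = 2000
    par_snps: int = 150
    n_males: int = 100
    n_females: int = 101
    n_outgroup_males: int = 5
    n_outgroup_females: int = 5
    k_founders: int = 30
    founder_mutation_rate: float = 0.3
    switch_rate: float = 0.02
    missing_rate: float = 0.002
    error_rate: float = 0.0025
    sweeps: list = field(default_factory=list)
    seed: int = 0
    bp_start: int = 30_000
    bp_step_mean: int = 7_000
    n_populations: int = 4

    def __post_init__(self):
        for r in (self.founder_mutation_rate, self.switch_rate, self.missing_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.par_snps >= self.n_snps:
            raise ValueError("par_snps must be smaller than n_snps")
        for s in self.sweeps:
            if s.snp_start < self.par_snps or s.snp_end >= self.n_snps or s.snp_start > s.snp_end:
                raise ValueError("sweep span must lie inside the non-PAR range")


@dataclass
class SimTruth:
    """Latent state sufficient to recompute every emitted genotype."""

    founders: np.ndarray          # (k, n_snps) 0/1
    founder_freqs: np.ndarray     # (k,)
    mosaic_paths: np.ndarray      # (n_samples, 2, n_snps) founder index
    clean_haps: np.ndarray        # (n_samples, 2, n_snps) 0/1, pre-noise
    par_boundary_bp: int
    par_snps: int
    sweeps: list
    swept_haplotypes: dict        # sweep index -> haplotype vector on the span
    seed: int


def _mosaic(rng, founder_freqs, founders, n_hap, n_snps, switch_rate):
    k = len(founder_freqs)
    paths = np.empty((n_hap, n_snps), dtype=np.int32)
    paths[:, 0] = rng.choice(k, size=n_hap, p=founder_freqs)
    switches = rng.random((n_hap, n_snps - 1)) < switch_rate
    new_idx = rng.choice(k, size=(n_hap, n_snps - 1), p=founder_freqs)
    for j in range(1, n_snps):
        paths[:, j] = np.where(switches[:, j - 1], new_idx[:, j - 1], paths[:, j - 1])
    return paths


def simulate_neutral(params: SimParams):
    """Generate a neutral dataset (plus any sweeps listed in ``params``).

    Returns ``(GenotypeMatrix, phased haplotype array, SimTruth)``.  The
    haplotype array has shape ``(n_samples, 2, n_snps)`` with male non-PAR
    columns duplicated across both rows (a male has one X copy there); the
    dosage matrix is the row sum after noise injection, so male non-PAR
    dosages are in {0, 2, missing} apart from error-induced het artifacts.
    """
    rng = np.random.default_rng(params.seed)
    n_snps = params.n_snps
    positions = params.bp_start + np.cumsum(
        rng.integers(1, 2 * params.bp_step_mean, size=n_snps)
    )
    par_boundary_bp = int(positions[params.par_snps - 1])

    # root haplotype is all-ancestral (all zeros); founders mutate from it
    founders = (rng.random((params.k_founders, n_snps)) < params.founder_mutation_rate).astype(np.int8)
    founder_freqs = rng.dirichlet(np.ones(params.k_founders))
    dist_to_root = founders.sum(axis=1)
    n_near = max(2, params.k_founders // 6)
    near_root = np.argsort(dist_to_root, kind="stable")[:n_near]

    n_focal = params.n_males + params.n_females
    n_out = params.n_outgroup_males + params.n_outgroup_females
    n_samples = n_focal + n_out

    paths = _mosaic(rng, founder_freqs, founders, 2 * n_focal, n_snps, params.switch_rate)
    # outgroup copies the founders nearest the root, dominated by the single
    # nearest one (a small, closely related population carrying mostly one
    # ancestral haplotype), so a clear most-common outgroup haplotype exists
    out_freqs = np.zeros(params.k_founders)
    out_freqs[near_root] = 0.25 ** np.arange(n_near)
    out_freqs /= out_freqs.sum()
    out_paths = _mosaic(rng, out_freqs, founders, 2 * n_out, n_snps, params.switch_rate)
    all_paths = np.concatenate([paths, out_paths]).reshape(n_samples, 2, n_snps)

    haps = founders[all_paths, np.arange(n_snps)[None, None, :]]

    # sample sheet: males first, then females, then outgroup (male, female)
    sexes = (
        ["male"] * params.n_males
        + ["female"] * params.n_females
        + ["male"] * params.n_outgroup_males
        + ["female"] * params.n_outgroup_females
    )
    species = ["focal"] * n_focal + ["outgroup"] * n_out
    pops = [
        f"breed{1 + i % params.n_populations}" for i in range(n_focal)
    ] + ["mouflon"] * n_out
    ids = [f"S{i:04d}" for i in range(n_samples)]
    samples = make_sample_sheet(ids, sexes, pops, species)

    male = np.array([s == "male" for s in sexes])
    nonpar = np.zeros(n_snps, dtype=bool)
    nonpar[params.par_snps:] = True
    # males: one haplotype outside the PAR -> duplicate copy 0 into copy 1
    for i in np.flatnonzero(male):
        haps[i, 1, nonpar] = haps[i, 0, nonpar]
        all_paths[i, 1, nonpar] = all_paths[i, 0, nonpar]

    truth = SimTruth(
        founders=founders,
        founder_freqs=founder_freqs,
        mosaic_paths=all_paths,
        clean_haps=haps.copy(),
        par_boundary_bp=par_boundary_bp,
        par_snps=params.par_snps,
        sweeps=[],
        swept_haplotypes={},
        seed=params.seed,
    )

    snps = make_snp_map(
        [f"snp{i:05d}" for i in range(n_snps)],
        positions,
        in_par=~nonpar,
    )
    gm, phased = _emit(params, snps, samples, truth, rng_noise_seed=params.seed + 1)
    if params.sweeps:
        gm, phased, truth = inject_sweep(gm, phased, truth, params.sweeps, params=params)
    return gm, phased, truth


def _emit(params: SimParams, snps, samples, truth: SimTruth, rng_noise_seed: int):
    """Apply genotyping noise to the clean haplotypes and build outputs."""
    rng = np.random.default_rng(rng_noise_seed)
    haps = truth.clean_haps.astype(np.int8).copy()
    n_samples, _, n_snps = haps.shape
    male = (samples["sex"] == "male").to_numpy()
    nonpar = ~snps["in_par"].to_numpy()

    # symmetric genotyping error: flip one allele of a diploid call, or the
    # single allele of a hemizygous call (kept consistent across its 2 rows)
    err = rng.random((n_samples, n_snps)) < params.error_rate
    which = rng.integers(0, 2, size=(n_samples, n_snps))
    hemi = male[:, None] & nonpar[None, :]
    for copy in (0, 1):
        hit = err & ((which == copy) | hemi)
        haps[:, copy, :][hit] = 1 - haps[:, copy, :][hit]

    miss = rng.random((n_samples, n_snps)) < params.missing_rate
    haps[:, 0, :][miss] = MISSING
    haps[:, 1, :][miss] = MISSING

    calls = np.where(
        (haps[:, 0, :] == MISSING) | (haps[:, 1, :] == MISSING),
        MISSING,
        haps[:, 0, :] + haps[:, 1, :],
    ).astype(np.int8)
    gm = GenotypeMatrix(snps, samples, calls.T)
    return gm, haps


def inject_sweep(gm, phased, truth: SimTruth, sweep_spec, params: SimParams | None = None):
    """Overlay hard sweeps on an existing dataset.

    For each :class:`SweepSpec`, every haplotype (one per male, two per
    female, focal samples only) is replaced over the span by the swept
    haplotype with probability ``f_s``.  ``origin="ancestral"`` selects the
    founder nearest the root; ``origin="derived"`` builds a novel haplotype
    at Hamming distance >= 5 from every founder on the span.  Noise is then
    re-applied to the modified clean haplotypes, so ``f_s = 0`` returns a
    dataset identical to the input.
    """
    if params is None:
        params = SimParams(seed=truth.seed, n_snps=truth.clean_haps.shape[2], par_snps=truth.par_snps)
    specs = [sweep_spec] if isinstance(sweep_spec, SweepSpec) else list(sweep_spec)
    truth = replace(truth, clean_haps=truth.clean_haps.copy(),
                    sweeps=list(truth.sweeps), swept_haplotypes=dict(truth.swept_haplotypes))
    rng = np.random.default_rng((truth.seed + 7919) % (2**31))
    founders = truth.founders
    focal = (gm.samples["species"] == "focal").to_numpy()
    male = (gm.samples["sex"] == "male").to_numpy()
    for si, spec in enumerate(specs):
        if spec.snp_start < truth.par_snps:
            raise ValueError("sweep span overlaps the PAR")
        span = slice(spec.snp_start, spec.snp_end + 1)
        width = spec.snp_end - spec.snp_start + 1
        dist = founders.sum(axis=1)
        nearest = int(np.argsort(dist, kind="stable")[0])
        if spec.origin == "ancestral":
            swept = founders[nearest, span].copy()
        else:
            swept = founders[nearest, span].copy()
            # flip sites until >=5 mutations from every founder on the span
            order = rng.permutation(width)
            k = 0
            while ((founders[:, span] != swept[None, :]).sum(axis=1) < 5).any():
                swept[order[k % width]] = 1 - swept[order[k % width]]
                k += 1
                if k > 10 * width:
                    raise RuntimeError("could not build a sufficiently novel swept haplotype")
        truth.swept_haplotypes[len(truth.sweeps)] = swept
        truth.sweeps.append(spec)
        for i in np.flatnonzero(focal):
            copies = (0,) if male[i] else (0, 1)
            for c in copies:
                if rng.random() < spec.f_s:
                    truth.clean_haps[i, c, span] = swept
            if male[i]:
                truth.clean_haps[i, 1, span] = truth.clean_haps[i, 0, span]
    gm2, phased2 = _emit(params, gm.snps, gm.samples, truth, rng_noise_seed=truth.seed + 1)
    return gm2, phased2, truth


def male_haplotypes(gm: GenotypeMatrix, phased: np.ndarray, species="focal") -> np.ndarray:
    """One haplotype row per male of the requested species (copy 0)."""
    mask = gm.sample_mask(sex="male", species=species)
    return phased[mask, 0, :]
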
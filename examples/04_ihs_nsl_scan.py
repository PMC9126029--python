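"""iHS and nSL scans on phased haplotypes with windowed outlier calling.

Both statistics compare haplotype homozygosity around ancestral vs derived
core alleles (iHS integrates EHH over physical distance; nSL counts SNP
steps).  Raw scores are standardized within 0.025-wide derived-frequency
bins, converted to two-sided -log10(P), and aggregated in 500 kb windows
sliding by 100 kb.
"""

import numpy as np

import xselscan as xs

start = 150 + 35 * 20
params = xs.SimParams(seed=4, n_snps=1000, par_snps=100,
                      sweeps=[xs.SweepSpec(start, start + 69, 0.8, "derived")])
gm, phased, truth = xs.simulate_neutral(params)
gm = xs.flag_par(gm, truth.par_boundary_bp)
gm.snps = xs.assign_ancestral(gm)

# non-PAR scan: one haplotype per male, two per female
in_par = gm.snps["in_par"].to_numpy()
male = gm.sample_mask(sex="male")
rows = []
for i in np.flatnonzero(gm.sample_mask(species="focal")):
    rows.append(phased[i, 0, ~in_par])
    if not male[i]:
        rows.append(phased[i, 1, ~in_par])
haps = np.array(rows)
submap = gm.snps.loc[~in_par].reset_index(drop=True)
haps, unknown = xs.recode_ancestral(haps, submap)
print(f"haplotypes: {haps.shape[0]}; SNPs scanned: {haps.shape[1]} "
      f"({unknown.sum()} with unknown ancestral state)")

ihs = xs.bin_standardize(xs.ihs_raw(haps, submap))
nsl = xs.bin_standardize(xs.nsl_raw(haps, submap))
print(f"iHS scored at {np.isfinite(ihs['raw']).sum()} SNPs "
      f"(NA at {np.isnan(ihs['raw']).sum()}: MAF<5% or unknown ancestral)")

pos = submap["pos_bp"].to_numpy()
sweep_lo, sweep_hi = pos[start - 100], pos[start - 100 + 69]
for name, table in (("iHS", ihs), ("nSL", nsl)):
    windows = xs.window_outlier_scan(table)
    sig = [w for w in windows if w.significant]
    print(f"{name}: {len(sig)} significant windows "
          f"(sweep span {sweep_lo:,}-{sweep_hi:,} bp)")
    for w in sig[:3]:
        print(f"  {w.start_bp:,}-{w.end_bp:,} bp  "
              f"{w.n_outliers}/{w.n_scored} outliers ({w.proportion:.0%})")
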
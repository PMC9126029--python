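"""Extreme-ROH-island scan on diploid females.

Runs of homozygosity are called per length class, the per-SNP ROH frequency
across females is standardized to an upper-tail -log10(P), and runs of
consecutive outlier SNPs become candidate selection signals.  The
significance threshold comes from simpleM (the effective number of
independent tests).
"""

import numpy as np

import xselscan as xs
from xselscan import erohi

# engineer elevated autozygosity by sweeping one region of female haplotypes
start = 150 + 35 * 20
params = xs.SimParams(seed=3, sweeps=[xs.SweepSpec(start, start + 69, 0.8, "derived")])
gm, phased, truth = xs.simulate_neutral(params)
gm = xs.flag_par(gm, truth.par_boundary_bp)

females = gm.subset(sample_mask=gm.sample_mask(sex="female", species="focal"))
segments = xs.call_roh(females)
print(f"ROH segments in {females.n_samples} females: {len(segments)}")
lengths = [s.length_bp / 1e6 for s in segments]
print(f"segment length: median {np.median(lengths):.2f} Mb, max {max(lengths):.2f} Mb")

freqs = xs.snp_roh_frequency(segments, gm.snps, n_females=females.n_samples)
freqs = xs.roh_neglogp(freqs)
sm = xs.simple_m(females)
print(f"simpleM: {sm.m_eff} effective tests of {sm.m_snps} SNPs "
      f"-> threshold -log10(P) = {sm.threshold_neglogp:.2f}")

signals = xs.call_erohi_signals(freqs, sm.threshold_neglogp)
pos = gm.snps["pos_bp"].to_numpy()
print(f"signals: {len(signals)} (sweep span {pos[start]:,}-{pos[start+69]:,} bp)")
for s in signals:
    print(f"  {s.start_bp:,}-{s.end_bp:,} bp  "
          f"{s.n_outlier_snps} outlier SNPs  peak -log10(P) = {s.peak_neglogp:.1f}")
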
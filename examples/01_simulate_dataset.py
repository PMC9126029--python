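"""Generate a synthetic X-chromosome array dataset and write standard files.

The generator emulates an ovine-style X chromosome: a pseudo-autosomal
prefix where males are diploid, a hemizygous remainder, focal breeds plus a
small outgroup, and HD-chip-like genotyping noise.  A hard sweep can be
injected for power studies.
"""

import numpy as np

import xselscan as xs

params = xs.SimParams(seed=1)
gm, phased, truth = xs.simulate_neutral(params)
gm = xs.flag_par(gm, truth.par_boundary_bp)

xs.write_vcf(gm, "scratch/example_sim.vcf", haplotypes=phased)
xs.write_plink(gm, "scratch/example_sim")

male = gm.sample_mask(sex="male", species="focal")
print(f"SNPs: {gm.n_snps} ({int(gm.snps['in_par'].sum())} in the PAR)")
print(f"samples: {gm.n_samples} "
      f"({male.sum()} focal males, "
      f"{gm.sample_mask(sex='female', species='focal').sum()} focal females, "
      f"{gm.sample_mask(species='outgroup').sum()} outgroup)")
print(f"PAR boundary: {truth.par_boundary_bp:,} bp")
miss = (gm.calls == -1).mean()
print(f"missing-call fraction: {miss:.4f} (configured {params.missing_rate})")
# Male dosages outside the PAR are {0, 2} up to rare error-induced hets --
# the hemizygous signature that PAR detection and HRiD both rely on.
nonpar = ~gm.snps["in_par"].to_numpy()
het = ((gm.calls[:, male] == 1) & nonpar[:, None]).sum()
print(f"male heterozygous calls outside PAR (noise artifacts): {het}")
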
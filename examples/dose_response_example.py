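"""Fit a probit concentration-mortality line and estimate LC50 and RR.

Simulates a susceptible and a resistant strain assay (40 insects per
concentration, as in a typical leaf-dip bioassay), fits each line by
maximum likelihood, and prints slope, goodness of fit, LC50 with its 95%
confidence interval, and the resistance ratio.
"""
import numpy as np

from resistkit import (GeneticArchitecture, Genotype, estimate_lc,
                       fit_probit, resistance_ratio, simulate_bioassay)

arch = GeneticArchitecture.from_lc50s(lc50_ss=0.64, lc50_rr=3080.95,
                                      slope=1.5, d_stone=0.13)
sus = simulate_bioassay(arch, {Genotype.homozygous_s(1): 1.0},
                        np.geomspace(0.05, 8, 7), 40, seed=1, strain="Sus")
res = simulate_bioassay(arch, {Genotype.homozygous_r(1): 1.0},
                        np.geomspace(300, 30_000, 6), 40, seed=2,
                        strain="Bif-R")

lcs = {}
for sb in (sus, res):
    fit = fit_probit(sb.table)
    lc = estimate_lc(fit, 0.5)
    lcs[fit.strain] = lc
    print(f"{fit.strain:>6}: slope {fit.slope:.2f} ± {fit.slope_se:.2f}, "
          f"chi2 {fit.pearson_chi2:.2f} ({fit.df} df), "
          f"LC50 {lc.dose:.2f} ({lc.ci_low:.2f}–{lc.ci_high:.2f}) μg/mL")

rr = resistance_ratio(lcs["Bif-R"], lcs["Sus"])
print(f"resistance ratio: {rr.ratio:.2f} "
      f"(95% CI {rr.ci_low:.2f}–{rr.ci_high:.2f})")
print("The RR is the resistant strain's LC50 divided by the susceptible "
      "strain's;\nits CI treats the two fits as independent on the log10 "
      "scale.")
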
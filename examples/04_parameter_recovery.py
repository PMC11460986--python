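"""Simulate-and-recover: check the Bayesian regression recovers a known
exponent at the study's sample size.

One noiseless replicate (the posterior must collapse onto the truth), one
noisy replicate, then a 25-replicate study of interval coverage and bias.
"""

import warnings

from predprey import SyntheticConfig, run_recovery_suite, simulate_and_recover

warnings.filterwarnings("ignore")

noiseless = simulate_and_recover(true_logc=-1.7, true_k=0.75, true_sigma=0.0,
                                 n=15, seed=3)
print(f"noiseless replicate: recovered k = {noiseless.fit.k_mean:.4f} "
      f"(truth 0.75)")

noisy = simulate_and_recover(true_logc=-1.7, true_k=0.75, true_sigma=0.3,
                             n=15, seed=3)
lo, hi = noisy.fit.k_interval()
print(f"noisy replicate:     recovered k = {noisy.fit.k_mean:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f}, covers truth: {noisy.k_covered})\n")

table, summary = run_recovery_suite(SyntheticConfig(true_k=0.75),
                                    n_replicates=25, seed=0,
                                    include_margins=False)
print(f"{len(table)} replicates at n = 15, true k = 0.75:")
print(f"  95% interval coverage: {summary['k_coverage']:.2f}")
print(f"  median bias of k:      {summary['k_bias_median']:+.3f}")
print(f"  RMSE of k:             {summary['k_rmse']:.3f}")
print("\nCoverage near 0.95 and small bias mean the survey design (15 "
      "park-years) is informative enough to recover the scaling exponent.")
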
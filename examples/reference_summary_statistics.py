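"""Derive residual-table statistics from a published pooled summary.

Given only the pooled loading-residual variances, means and counts that
a study reports per model family, the integrity module reconstructs the
remaining rows of the usual summary table: SD, the 95% confidence
interval of the mean residual, the lower-tail F critical value, and the
±2 SD interpretation band.
"""

import woodftir as wf

# reported pooled summaries: (mean R, sample variance, n) per model family
pcr = wf.summary_from_moments(mean=0.06, variance=55.5, n=49)
pls = wf.summary_from_moments(mean=-0.49, variance=92.6, n=49)

for name, s in (("PCR", pcr), ("PLS", pls)):
    print(f"{name}: SD={s.sd:.2f} cm^-1, 95% CI = {s.mean:+.2f} ± "
          f"{s.ci_halfwidth:.1f} cm^-1, ±2 SD band = ±{s.two_sd_band:.1f} cm^-1")

res = wf.variance_f_test_from_summary(
    var_pls=pls.variance, var_pcr=pcr.variance, n_pls=pls.n, n_pcr=pcr.n
)
print(f"\nF (var_PCR/var_PLS) = {res.f_lower:.2f}, lower-tail critical value "
      f"at alpha=0.05 = {res.crit_lower:.2f}, one-tail p = {res.p_lower:.4f}")
print("F below the critical value -> the PLS residual variance is "
      "significantly larger: PCR loadings locate bands more precisely.")
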
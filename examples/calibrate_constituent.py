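"""Calibrate lignin content with PCR and PLS1 and compare diagnostics.

Uses the lignin modelling window (1800-800 cm^-1), a 31/6
calibration/validation split, and leave-one-out cross-validation to pick
the number of components, then prints r^2 (%), RMSEC/RMSEP (% w/w) and
RPD for both algorithms.  RPD > 4 is usually read as quantitative-grade.
"""

import woodftir as wf

spectra, compositions, _ = wf.generate_dataset(wf.GeneratorConfig(seed=1))
y = compositions["lignin"]

X = wf.select_window(spectra, *wf.DEFAULT_WINDOWS["lignin"])
(cal_sp, cal_c), (val_sp, val_c) = wf.split_samples(
    spectra, compositions, wf.SplitSpec(n_cal=31, n_val=6, seed=1)
)
X_cal = wf.select_window(cal_sp, *wf.DEFAULT_WINDOWS["lignin"])
X_val = wf.select_window(val_sp, *wf.DEFAULT_WINDOWS["lignin"])

for algorithm, fit in (("pcr", wf.fit_pcr), ("pls1", wf.fit_pls1)):
    table, k = wf.cross_validate(X, y.to_numpy(), algorithm, k_max=10)
    model = fit(X_cal, cal_c["lignin"].to_numpy(), k, constituent="lignin")
    d = wf.diagnostics(model, X_cal, cal_c["lignin"], X_val, val_c["lignin"])
    print(f"{algorithm.upper()}: k={k} (RMSECV-selected), r2={d.r2:.2f}%, "
          f"RMSEC={d.rmsec:.3f}, RMSEP={d.rmsep:.3f} % w/w, RPD={d.rpd:.1f}")

print("\nBoth models are essentially exact here because the synthetic spectra "
      "are linear in composition; on real spectra the diagnostics separate "
      "quantitative-grade from screening-grade models.")
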
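"""Run the full 60-leg simulation study end to end.

Generates the default calibrated cohort (30 subjects, both legs), fits the
anatomical frames, sweeps every leg through the 31 rotation positions, fits
the pooled patellar regression and the mixed models, and prints the
deviation table and the centralized-patella comparison.
"""

import tempfile

from rotalign.io import RunConfig, run_study
from rotalign.cohort import default_params

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(params=default_params(n_subjects=30, seed=1),
                       seed=1, output_dir=tmp)
    report = run_study(config)

    reg = report.regression
    print(f"legs: {report.n_legs}, measured positions: {report.n_positions}")
    print(f"pooled patellar regression: {reg.slope:.3f} mm/deg, "
          f"R^2 = {reg.r_squared:.3f}")
    for m in report.mixed:
        print(f"{m.parameter}: {m.per_degree_slope:+.3f} per degree "
              f"(conditional R^2 {m.conditional_r2:.2f})")

    print("\nDeviation from the neutral position by rotation angle:")
    print(report.table1.to_string())

    print("\nCentralized patella vs knee-forward orientation:")
    print(report.table2.round(2).to_string())

print("\nA change of about -0.9 mm per degree means a patellar shift between")
print("two radiographs of the same knee directly estimates the difference in")
print("limb rotation between the acquisitions.")
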
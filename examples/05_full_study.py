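"""The full train/test evaluation protocol with agreement analysis.

Trains the beat detector and all SBP models on one 26-minute session,
freezes them, scores the unseen second session, and summarizes agreement
(mean error +/- SD, MAE, RMSE, Bland-Altman limits, AAMI verdict).
"""

from armpulse import SyntheticConfig, generate_session, run_study
from armpulse.evaluation import AgreementStats

train = generate_session(SyntheticConfig(seed=41))
test = generate_session(SyntheticConfig(seed=42))
report = run_study(train, test)

print("detector:", report.detector_summary)
hr = report.hr_stats
print(f"windowed HR vs chest reference: MAE {hr.mae:.2f} BPM, RMSE {hr.rmse:.2f} BPM")

row = report.test_table.loc[10]
st = AgreementStats(n=13, me=row["ME"], std=row["STD"], mae=row["MAE"], rmse=row["RMSE"])
print(f"model 10 test: {st.me:.2f} +/- {st.std:.2f} mmHg (MAE {st.mae:.2f}, RMSE {st.rmse:.2f})")
print(f"Bland-Altman limits of agreement: [{st.loa_low:.2f}, {st.loa_high:.2f}] mmHg")
print(f"AAMI criterion (|ME| <= 5, SD <= 8 mmHg): "
      f"{'PASS' if report.aami[10] else 'FAIL'}")
print("(every fitted parameter was frozen before the test session was scored)")
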
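"""Score a single patient: DAS28-CRP, windowed AUC, improved area, index R.

Builds a small visit series by hand (components, not scores), a constant
8 mg/week dose schedule, and prints the response summary for the 0-3 and
0-6 month windows. The improved area is measured against the reference
trajectory pinned at DAS28 = 10 (area 30 over 0-3 months, 60 over 0-6);
index R divides it by the cumulative methotrexate dose, so larger values
mean more disease-activity reduction per milligram.
"""

from mtxresponse import DoseInterval, Patient, Visit, compute_response

patient = Patient(
    patient_id="example",
    visits=[
        # month, tender joints, swollen joints, VAS (0-100), CRP (mg/dL)
        Visit(0, t28=8, s28=6, vas=55, crp=2.1),
        Visit(1, t28=6, s28=5, vas=48, crp=1.5),
        Visit(2, t28=5, s28=3, vas=40, crp=1.1),
        Visit(3, t28=3, s28=2, vas=30, crp=0.8),
        Visit(4, t28=2, s28=2, vas=24, crp=0.5),
        Visit(5, t28=2, s28=1, vas=20, crp=0.4),
        Visit(6, t28=1, s28=1, vas=15, crp=0.3),
    ],
    doses=[DoseInterval(0, 12, 8.0)],  # 8 mg/week throughout
)

print("visit DAS28-CRP trajectory:")
for v in patient.visits:
    print(f"  month {v.month:>4.1f}: DAS28 = {v.das28:.2f}")

for window in ((0, 3), (0, 6)):
    s = compute_response(patient, window)
    print(f"\nwindow {window[0]}-{window[1]} months:")
    print(f"  cumulative MTX dose : {s.cumulative_dose_mg:7.1f} mg")
    print(f"  DAS28 AUC           : {s.das28_auc:7.2f} score-months")
    print(f"  improved DAS28 area : {s.improved_area:7.2f} score-months")
    print(f"  index R             : {s.index_r:7.4f} per mg")
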
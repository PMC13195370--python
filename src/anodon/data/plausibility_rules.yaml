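# Default per-category plausibility intervals.  A resting heart rate above
# 250 bpm is physiologically impossible: the interval is open at 20 and
# closed at 250, so 250 itself is still admissible.
resting_heart_rate: {low: 20, high: 250, low_inclusive: false}
blood_pressure_systolic: {low: 60, high: 260}
blood_pressure_diastolic: {low: 30, high: 160}
sleep_duration: {low: 0, high: 24}
steps: {low: 0, high: 200000}
lab_result: {low: -.inf, high: .inf}  # analyte-specific; no generic bound
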
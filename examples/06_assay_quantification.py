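"""Bench-assay quantification arithmetic used alongside the array analysis.

Comparative-Ct qPCR quantification (with the Ct >= 30 censoring rule),
dual-luciferase reporter normalisation, MTT relative viability and the
xenograft tumour-volume formula.
"""

from mirsynergy import (
    QPCRMeasurement,
    normalize_reporter,
    relative_expression_ddct,
    relative_viability,
    tumor_volume,
)

calibrator = QPCRMeasurement(ct_target=24.0, ct_reference=18.0)
sample = QPCRMeasurement(ct_target=22.0, ct_reference=18.0)
print("2^-ddCt relative expression:", relative_expression_ddct(sample, calibrator))

late = QPCRMeasurement(ct_target=31.0, ct_reference=18.0)
print("late amplification (Ct 31):", relative_expression_ddct(late, calibrator))

print("reporter activity vs scramble control:", normalize_reporter(10, 2, 20, 2))
print("relative viability:", relative_viability(0.4, 0.8))
print("tumour volume (w=5mm, l=10mm):", tumor_volume(5, 10), "mm^3")
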
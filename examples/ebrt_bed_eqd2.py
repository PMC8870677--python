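"""BED and EQD2 for the three palliative EBRT schedules.

Converts each fractionation schedule to its biologically effective dose
(BED) and its equieffective dose in 2 Gy fractions (EQD2), using the LQ
model with alpha/beta = 10 Gy. Higher dose per fraction means more
biological effect per physical Gy, which is why 8 Gy in 1 fraction has
BED 14.4 Gy rather than 8 Gy.
"""

from alphalq import EBRTSchedule, LQParameters, bed_ebrt, eqd2_from_bed, round_half_up

params = LQParameters()  # alpha/beta = 10 Gy, d_ref = 2 Gy
schedules = [
    EBRTSchedule(30.0, 10, "30 Gy in 10 fr"),
    EBRTSchedule(20.0, 5, "20 Gy in 5 fr"),
    EBRTSchedule(8.0, 1, "8 Gy in 1 fr"),
]

print(f"{'schedule':16s} {'d (Gy/fr)':>10s} {'BED (Gy)':>9s} {'EQD2 (Gy)':>10s}")
for s in schedules:
    bed = bed_ebrt(s, params)
    eqd2 = eqd2_from_bed(bed, params)
    print(
        f"{s.label:16s} {s.dose_per_fraction:10.1f} "
        f"{round_half_up(bed):9.1f} {round_half_up(eqd2):10.1f}"
    )
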
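"""Delta scores from the printed cohort means.

The postural-test delta score is the after-minus-before bed-rest change
(R+10 minus BDC-7) per group and posture.  Applied to the reference cohort's
printed group means, it reproduces the headline effects: a 17-mmHg fall in
supine systolic pressure in the untrained group, and a 5-7 mL stroke-volume
loss in every group and posture.
"""

import hdtcardio as hc
from hdtcardio import reference_cohort as ref

print("index  group  posture   before   after   delta")
for index, unit in [("SBP", "mmHg"), ("SV", "mL"), ("HR", "bpm"), ("TPR", "dyn.s.cm-5")]:
    for group in ("CTRL", "TRAIN"):
        for posture in ("supine", "sitting"):
            before = ref.cell_mean(index, "BDC-7", group, posture)
            after = ref.cell_mean(index, "R+10", group, posture)
            d = hc.delta_score(after, before)
            print(f"{index:5s}  {group:5s}  {posture:8s} {before:7.1f} {after:7.1f} "
                  f"{d:+7.1f} {unit}")
    print()

print("Negative deltas are declines from the pre-bed-rest baseline: the")
print("CTRL supine SBP delta of -17 mmHg is the post-bed-rest hypotension")
print("that the jump-training group does not show (-5.3 mmHg).")
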
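"""Agreement quantities from published summary statistics alone.

Bland-Altman limits of agreement and the standard error of measurement
need only the mean and SD of the between-tool differences, so reported
summaries can be checked without raw data.
"""

import math

from cmjagree import loa_from_bias_sd, round_half_up

cases = [
    ("flight time vs impulse-momentum", 1.33, 1.62),
    ("video vs impulse-momentum", -0.36, 1.61),
    ("observer 1 vs observer 2", 0.07, 0.31),
]
for label, bias, sd in cases:
    lo, hi = loa_from_bias_sd(bias, sd)
    sem = sd / math.sqrt(2)
    print(f"{label}:")
    print(f"  bias {bias:+.2f} cm, SD {sd:.2f} cm")
    print(f"  95% LoA ({round_half_up(lo, 2):+.2f}, {round_half_up(hi, 2):+.2f}) cm")
    print(f"  SEM {round_half_up(sem, 1):.1f} cm")
# LoA = bias +- 1.96 SD bracket where 95% of between-tool differences fall;
# SEM = SD/sqrt(2) expresses the same spread as a per-tool measurement error.
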
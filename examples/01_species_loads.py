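"""Applied knuckle-walking loads for the five study species.

Hominoid forelimbs carry roughly 40% of body weight in quadrupedal
stance, so one wrist sees 20% of body mass times gravity.  Printed
below: body mass (kg) and total applied load (N) per species.
"""

from carpofem import compute_total_load
from carpofem.study import TABLE1_MASSES

print(f"{'species':18s} {'mass kg':>8s} {'load N':>8s}")
for species, mass in TABLE1_MASSES.items():
    print(f"{species:18s} {mass:8.1f} {compute_total_load(mass):8.2f}")
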
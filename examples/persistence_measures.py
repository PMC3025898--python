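"""Contrast of the two persistence classifiers, including the quarterly
rule's non-monotonicity.

The gap rule (measure 1) asks whether any >90-day refill gap starts before
the horizon; the quarterly rule (measure 2) only counts claims per
index-anchored quarter.  Measure 2 is strictly more lenient at every
horizon, but it is not monotone over horizons: one claim per quarter
satisfies the 12-month rule while failing the 6-month one.
"""

import datetime as dt

from rxpersist import classify_measure1, classify_measure2

index = dt.date(2003, 1, 1)

patients = {
    "steady (every 30 days)": [index + dt.timedelta(days=30 * k)
                               for k in range(14)],
    "one late refill (Apr 11)": [index, dt.date(2003, 4, 11)],
    "one claim per quarter": [index, dt.date(2003, 6, 20),
                              dt.date(2003, 9, 10), dt.date(2003, 12, 10)],
}

header = f"{'patient':28s}" + "".join(
    f"  m1@{h:<3d} m2@{h:<3d}" for h in (3, 6, 12)
)
print(header)
for name, fills in patients.items():
    cells = []
    for h in (3, 6, 12):
        m1 = classify_measure1(fills, index, h).persistent
        m2 = classify_measure2(fills, index, h).persistent
        cells.append(f"  {'yes' if m1 else 'no ':5s} {'yes' if m2 else 'no ':5s}")
    print(f"{name:28s}" + "".join(cells))
print("\nNote the last patient: persistent at 12 months by measure 2 but not"
      "\nat 6 — only two claims fall in the first seven months.")
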
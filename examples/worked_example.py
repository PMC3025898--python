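"""The refill-gap rule on a four-fill patient, step by step.

A patient starts mealtime insulin on 2003-01-01 and refills on Mar 15,
May 1 and Jul 15, then never again.  The gap detector finds no interval
over 90 days among the fills, but the terminal residue (Jul 15 to the end
of the 15-month observation window) is a gap, so the patient is persistent
at 3 and 6 months and non-persistent at 12 — with discontinuation dated at
the last fill before the gap.
"""

import datetime as dt

from rxpersist import classify_measure1, detect_gaps, refill_intervals

index = dt.date(2003, 1, 1)
fills = [index, dt.date(2003, 3, 15), dt.date(2003, 5, 1), dt.date(2003, 7, 15)]

intervals = refill_intervals(fills, index, 12)
print(f"refill intervals (days): {intervals.intervals}  "
      f"mean {intervals.mean:.1f}, median {intervals.median:.0f}")

analysis = detect_gaps(fills, index)
for gap in analysis.gaps:
    kind = "terminal" if gap.terminal else "internal"
    print(f"{kind} gap of {gap.gap_length_days} days starting {gap.gap_start}")

for horizon in (3, 6, 12):
    status = classify_measure1(fills, index, horizon)
    verdict = "persistent" if status.persistent else \
        f"NOT persistent (discontinued {status.discontinuation_date})"
    print(f"measure 1 at {horizon:>2} months: {verdict}")
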
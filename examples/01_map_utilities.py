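"""Map SF-36 domain scores to EQ-5D utilities.

Builds three visits for one patient and maps each through the published
linear algorithm.  The printed utilities are on the EQ-5D scale (1 = full
health); the month-8 visit shows the modest improvement a lifestyle
program aims for.
"""

from masld_cua import SF36_DOMAINS, SF36Visit, build_utility_series, map_sf36_to_eq5d

visits = [
    SF36Visit("CB01", month=0, pf=70, rp=75, bp=62, gh=60, vt=55, sf=75, re=80, mh=68),
    SF36Visit("CB01", month=4, pf=75, rp=75, bp=68, gh=62, vt=58, sf=78, re=80, mh=72),
    SF36Visit("CB01", month=8, pf=82, rp=70, bp=74, gh=66, vt=60, sf=82, re=85, mh=76),
]

for v in visits:
    print(f"month {v.month:>2.0f}: utility {map_sf36_to_eq5d(v):.4f}")

(series,) = build_utility_series(visits)
gain = series.utilities[-1] - series.utilities[0]
print(f"utility change over follow-up: {gain:+.4f}")
print("A positive change means better health-related quality of life;")
print("sustained for a year it counts as the same number of QALYs.")
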
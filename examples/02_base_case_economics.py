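"""Base-case cost-utility arithmetic.

Costs the supervised program from its monthly components, then computes
the ICER against a no-program comparator and the net monetary benefit at
the usual European willingness-to-pay thresholds.
"""

from masld_cua import (
    CostModel,
    EconomicInputs,
    ThresholdSet,
    compute_icer,
    compute_nmb,
    total_program_cost,
)

model = CostModel()  # gym 30 + supervision 60 + management 20 + insurance 10 EUR/mo
annual_cost = total_program_cost(model)
print(f"annual program cost: EUR {annual_cost:.0f}")

qaly_gain = 0.081  # mean utility gain over the 8-month follow-up, held for 1 year
icer = compute_icer(EconomicInputs(c1=annual_cost, e1=qaly_gain))
print(f"ICER: EUR {icer.value:,.0f} per QALY gained")

for wtp in ThresholdSet().wtp:
    nmb = compute_nmb(qaly_gain, wtp, annual_cost)
    print(f"NMB at EUR {wtp:,.0f}/QALY: EUR {nmb:,.0f}")

print("A positive NMB means the health gained is worth more, at that")
print("threshold, than the program costs; the ICER is the threshold at")
print("which the NMB crosses zero.")
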
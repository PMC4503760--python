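"""Per-patient treatment costs by phase, and the national bill.

Computes discounted pre-transplant, admission and 10-year post-transplant
costs for cohorts listed in Year 1 (2014) and Year 20 (2033), then scales by
forecast demand.
"""

from liverecon import SimulationClock, load_parameters, phase_costs, project_new_listings
from liverecon.parameters import MeldCategory as M

params = load_parameters("table1_baseline")
clock = SimulationClock()

for year in (1, 20):
    pc = phase_costs(params, year)
    print(f"Year {year:>2}: pre-LT (weighted) ${pc.pre_lt_weighted:>9,.0f}   "
          f"admission ${pc.admission:>9,.0f}   post-LT ${pc.post_lt_10yr:>9,.0f}   "
          f"total ${pc.total_per_patient:>11,.0f}")
# Escalation (4.9%/yr) net of discounting (3%/yr) compounds to x1.415 over
# 19 years, which is exactly the admission and post-LT growth.

pc1, pc20 = phase_costs(params, 1), phase_costs(params, 20)
print(f"sickest category (MELD >40) pre-LT: ${pc1.pre_lt_by_meld[M.GT40]:,.0f} -> "
      f"${pc20.pre_lt_by_meld[M.GT40]:,.0f}")
# 12 months of $51,085/month: the severe-illness costing rule.

for year in (1, 20):
    demand = project_new_listings(params, clock, year)
    total = phase_costs(params, year).total_per_patient * demand
    print(f"potential national expenditure, Year {year:>2}: ${total / 1e9:.1f}B "
          f"({demand:,.0f} patients)")
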
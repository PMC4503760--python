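"""Catalog-price cost of bioengineering an autologous liver graft.

Prices every cell needed to seed a whole (or partial) liver from
iPSC-derived lines at current cryovial catalog prices, plus a one-time
reprogramming charge.
"""

from liverecon import build_cost, price_decline_scenario
from liverecon.bioliver import DEFAULT_CELL_LINES

for fraction in (1.0, 0.35, 0.15):
    b = build_cost(fraction=fraction)
    print(f"{fraction * 100:3.0f}% of a liver: ${b.total:>12,.0f} "
          f"(cells ${b.cell_cost:,.0f} + reprogramming ${b.reprogramming_cost:,.0f})")
# 35% of a liver may sustain critical metabolic function (auxiliary
# transplantation); reprogramming does not scale with graft size.

whole = build_cost()
print(f"hepatocyte share of cell cost: "
      f"{whole.line_costs['hepatocytes'] / whole.cell_cost * 100:.0f}% "
      f"({whole.vials['hepatocytes']:,.0f} vials)")

# Manufacturing scale-up scenario: all vial prices fall by 90%.
scaled = price_decline_scenario(DEFAULT_CELL_LINES, {l.name: 0.1 for l in DEFAULT_CELL_LINES})
print(f"whole liver at 10% of catalog prices: ${scaled.total:,.0f}")
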
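"""Value the genetic gains: producer benefits, BCR, rations, surplus.

Applies the cumulative gain series to the published annual area sown to
program varieties and real 2016 USD prices, compares discounted benefits
with program costs, and converts the extra kilograms into per-person
annual wheat rations (60.9 kg each).  Expected output: total producer
benefits near $106.4 million (2016 USD), an undiscounted benefit-cost
ratio near 5.1, and roughly 253,000 additional rations per year on
average over 1992-2015.
"""

from wheatgains import datasets, economics, genetic_gain

ref = datasets.load_reference_coefficients()
econ = datasets.load_econ_series()
costs = datasets.load_program_costs()

gains = {
    wt: genetic_gain.cumulative_gain(
        float(ref.loc[wt, "jp_yield"]),
        int(ref.loc[wt, "first_release_year"]),
        2015,
        wheat_type=wt,
    )
    for wt in datasets.ECON_TYPES
}

benefits = economics.producer_benefits(econ, gains)
print(f"total producer benefits 1992-2015: ${benefits.total:,.0f} (2016 USD)")
print(f"average annual benefit:            ${benefits.average:,.0f}")

for r in (0.0, 0.1025):
    bcr = economics.benefit_cost_ratio(benefits.per_year["total"], costs, r=r)
    print(f"benefit-cost ratio at r={r:.4f}:    {bcr:.2f}")

addkg = economics.additional_production_kg(econ, gains)
rat = economics.rations(addkg, per_capita=60.9)
print(f"additional wheat in 1993:          {addkg.loc[1993]:,.0f} kg "
      f"({rat.rounded.loc[1993]:,} rations)")
print(f"average annual additional rations: {rat.average:,.0f}")

params = economics.SurplusParams()  # -0.22 demand, 0.68 supply, K=0.51%
s = economics.surplus(P=300.0, Q=1_800_000, params=params)
print(f"\nsurplus example (P=$300/t, Q=1.8M t, K={params.supply_shift:.2%}): "
      f"dCS=${s.consumer:,.0f}, dPS=${s.producer:,.0f}, net=${s.net:,.0f}")
print(f"consumer/|producer| incidence ratio = "
      f"{s.consumer/abs(s.producer):.4f} (= supply/demand elasticity)")
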
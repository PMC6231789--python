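"""Costing rules: unit prices, friction cap, presenteeism, perspectives."""

from trialcea import costing as co
from trialcea import trial_data as td

prices = co.default_price_table()
friction = co.FrictionParams()  # 85 calendar days -> 60 workdays cap

use = td.ResourceUse(
    gp_visits=2, psychologist=1, drug_days_depression=30,
    informal_care_hours=10, absenteeism_days=70, presenteeism_days=10,
    presenteeism_efficiency=0.5,
)
hc, pf = co.price_resources(use, prices)
print(f"health-care lines: GP 2x -> EUR {hc['gp_visits']:.0f}, "
      f"psychologist -> EUR {hc['psychologist']:.0f}, "
      f"30 antidepressant days -> EUR {hc['medication']:.0f}")
print(f"informal care 10 h at domestic-help proxy wage -> EUR "
      f"{pf['informal_care_hours']:.0f}")

absent = co.absenteeism_cost(use.absenteeism_days, friction)
capped = co.absenteeism_cost(200, friction)
print(f"absenteeism 70 days -> EUR {absent:.0f} "
      f"(friction cap: 200 days costs the same EUR {capped:.0f})")
print(f"presenteeism 10 days at 50% efficiency -> EUR "
      f"{co.presenteeism_cost(10, 0.5, friction.daily_wage):.0f}")

iv = co.intervention_cost(19_500, 5_000)
iv_opp = co.intervention_cost(19_500, 5_000, include_opportunity=True,
                              participant_hours=3.5, wage=14.0)
print(f"intervention: EUR {iv:.2f} platform share per account, "
      f"EUR {iv_opp:.1f} including participant time")
# Beyond the friction period an absent worker is assumed replaced, so
# additional absence days carry no further productivity loss.
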
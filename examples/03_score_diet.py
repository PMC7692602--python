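"""Score the Canadian Healthy Eating Index 2010 for one intake profile.

Eight adequacy components (0-60 points, more is better) plus three
moderation components (0-40, less is better) give a total on 0-100.
"""

from gxecohort import DietRecord, score_hei

record = DietRecord(
    fruit_and_vegetables=5.1,   # servings/day, standard is 7.5
    whole_fruit=1.3,
    greens_and_beans=0.5,
    whole_grains=0.4,
    dairy=1.7,
    total_protein=1.3,
    seafood_plant_protein=0.2,
    refined_grains=2.2,
    fatty_acid_ratio=1.3,        # (PUFA+MUFA)/SFA, full points at 2.5
    sodium=2164.0,               # mg/day
    empty_calorie_pct=27.1,      # full points at <=19% of energy
    total_energy=1716.0,
)
res = score_hei(record, age=55, sex="female")
print(f"total HEI-C: {res.total:.1f} / 100 "
      f"(adequacy {res.adequacy:.1f}/60, moderation {res.moderation:.1f}/40)")
for name, pts in res.components.items():
    print(f"  {name:22s} {pts:5.1f}")
# This profile resembles a lowest-quartile diet: every adequacy intake is
# below its standard and empty calories exceed the 19% best threshold, so
# the total lands well below the cohort-typical ~58 points.
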
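"""Build smoothed in-store retail exposures from a weekly marketing panel.

Four indicators per food category (variety, regular price per serving,
discount frequency, display share) are summarised as vegetable:soft-drink
ratios per quarter, then collapsed per FSA with exponential smoothing that
up-weights recent quarters.
"""

from gxecohort import SimulationConfig, build_exposures, healthfulness_ratio
from gxecohort.simulate import simulate_retail_panel

panel = simulate_retail_panel(SimulationConfig(n_subjects=10, n_fsa=6, seed=4),
                              seed=4)
exposures = build_exposures(panel, decay=0.3)
print(exposures.round(3).to_string())

fsa = exposures.index[0]
for ind, col in [("display_share", "display_ratio"),
                 ("regular_price_per_serving", "price_ratio")]:
    val = exposures.loc[fsa, col]
    _, flag = healthfulness_ratio(val, 1.0, ind)
    print(f"{fsa} {col} = {val:.2f} -> {flag}")
# A display ratio above 1 means vegetables are displayed more than soft
# drinks (healthful); a price ratio above 1 means vegetables cost more per
# serving than soft drinks (unhealthful).
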
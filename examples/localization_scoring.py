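"""Score localization responses and normalize them by chance level.

Responses are scored as lateral error, quadrant-error rate (circular polar
error > 90 deg) and local polar error (non-confused trials only); a virtual
experiment with fully randomized responses provides the chance reference,
so observed/chance ratios near 1 flag chance-level performance.
"""

from loombias import chance_simulation, score_trials
from loombias.synth import SyntheticConfig, default_target_grid, gen_localization_responses

targets = default_target_grid()

# a reasonably accurate listener vs one with many rear confusions
good = SyntheticConfig(loc_gain=0.95, loc_scatter_pol=15.0, loc_confusion_rate=0.03, loc_trials=2000)
poor = SyntheticConfig(loc_gain=0.6, loc_scatter_pol=40.0, loc_confusion_rate=0.3, loc_trials=2000)

for name, cfg in (("good listener", good), ("poor listener", poor)):
    resp = gen_localization_responses(targets, cfg, seed=3)
    obs = score_trials(resp)
    ref = chance_simulation(resp[["target_lat", "target_pol"]], n_sim=100, seed=4, observed=obs)
    print(f"{name}:")
    print(
        f"  lateral error  {obs.lateral_error:5.1f} deg  (chance {ref.lateral_error:5.1f}, "
        f"ratio {ref.ratios['lateral_error']:.2f})"
    )
    print(
        f"  local polar    {obs.local_polar_error:5.1f} deg  (chance {ref.local_polar_error:5.1f}, "
        f"ratio {ref.ratios['local_polar_error']:.2f})"
    )
    print(
        f"  quadrant err   {obs.quadrant_error_rate:5.1f} %    (chance {ref.quadrant_error_rate:5.1f}, "
        f"ratio {ref.ratios['quadrant_error_rate']:.2f})"
    )
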
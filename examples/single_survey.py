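"""Run one simulated survey and classify the recovered sex ratio.

A 10 x 10 grid holds 400 individuals (200 males, 200 females). After a
100-step burn-in, both sampling methods run for 100 days on the same
population: fixed trap transects record every arrival, and a fresh random
transect is actively searched each day with 50% detectability per sex.
The chi-square test then asks whether each method's unique captures are
consistent with the true 1:1 sex ratio.
"""

from sexratiosim import make_fixture, run_replicate

config = make_fixture("small")
result = run_replicate(config, replicate_index=0)

print(f"population: {config.n_individuals} individuals on a "
      f"{config.grid_resolution} x {config.grid_resolution} grid (true sex ratio 1:1)")
for method, outcome in (("passive traps", result.passive), ("active search", result.active)):
    print(
        f"{method:>14}: {outcome.male_captures} males, {outcome.female_captures} females "
        f"captured; chi2 = {outcome.statistic:.2f}, p = {outcome.p_value:.3f} "
        f"-> {outcome.classification}"
    )
print("With symmetric movement and detectability, both methods should be "
      "classified 'unbiased' in almost every replicate.")
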
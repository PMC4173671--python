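"""Generate a synthetic lake dataset and look at what it contains.

Builds 40 years of daily water temperature, weekly spawner catches,
zooplankton counts and yearly covariates with recruits, the way the
analysis expects its inputs.
"""

from phenomatch import LakeConfig, TemperatureConfig, simulate_dataset

cfg = LakeConfig(temperature=TemperatureConfig(start_year=1969, end_year=2008))
tables = simulate_dataset(cfg, seed=1)

yearly = tables["yearly"]
print(yearly.head(5).to_string(index=False))
print(f"\nyears simulated: {len(yearly)}")
print(f"recruit range: {yearly['recruits'].min():,.0f} .. {yearly['recruits'].max():,.0f}")

# Recruit counts span orders of magnitude because log-recruitment responds
# to phenological mismatch, spawner numbers and density dependence.
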
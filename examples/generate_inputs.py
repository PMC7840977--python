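"""Generate a synthetic country input bundle and summarise it.

The bundle plays the role of a national dataset: population pyramid,
smoking prevalences and transition probabilities, COPD burden,
mortality and relative risks, all by sex and single year of age.
"""

from tobaccohia import SyntheticParams, generate_bundle, validate_bundle
from tobaccohia.synthetic import period_life_expectancy

bundle = generate_bundle(SyntheticParams(seed=1))
print("validation violations:", validate_bundle(bundle) or "none")

pop = bundle.demographics.counts
print(f"population: {pop.sum():,.0f} persons, share aged 40+: {pop[:, 40:].sum() / pop.sum():.1%}")

cur = float((pop * bundle.smoking.p_current).sum() / pop.sum())
copd = float((pop * bundle.disease.copd_prevalence).sum() / pop.sum())
inc = float((pop * bundle.disease.copd_incidence).sum() / pop.sum())
print(f"overall current smoking: {100 * cur:.1f}%  (2018 European country range: 10.6-17.5%)")
print(f"overall COPD prevalence: {100 * copd:.2f}%  (observed range 0.9-1.3%)")
print(f"overall COPD incidence: {1000 * inc:.2f} per 1,000 person-years (observed 1.5-1.7)")

for sx, sex in enumerate(("male", "female")):
    le = period_life_expectancy(bundle.mortality.all_cause[sx])
    peak = int(bundle.smoking.p_current[sx].argmax())
    print(f"{sex}: period life expectancy {le:.1f} y; current smoking peaks at age {peak}")
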
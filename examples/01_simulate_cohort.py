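"""Generate a synthetic radiogenomic GBM cohort and inspect its marginals.

The 'paper-like' preset emulates a 142-patient cohort: log-normal tumor
volumes with median ~30,000 mm^3, a noisy 2D diameter surrogate, ages around
60, KPS concentrated at 100, and exponential survival with median 20 months
for VAK-A-like and 12 months for VAK-B-like patients.
"""

from scipy import stats

from vakgbm import generate_clinical, scenario_preset, with_overrides

params = with_overrides(scenario_preset("paper-like"), seed=7)
cohort, truth = generate_clinical(params)
df = cohort.to_frame()

r2 = stats.linregress(df["diameter_mm"], df["volume_mm3"]).rvalue ** 2
print(f"patients:                {len(df)}")
print(f"median volume (mm^3):    {df['volume_mm3'].median():,.0f}")
print(f"median age (years):      {df['age_years'].median():.1f}")
print(f"KPS = 100 fraction:      {(df['kps'] == 100).mean():.2f}")
print(f"diameter-volume R^2:     {r2:.2f}")
print(f"event (death) fraction:  {df['event'].mean():.2f}")
print(f"latent class counts:     {truth['latent_class'].value_counts().to_dict()}")

# The R^2 near 0.8 is why a 2D diameter reading can stand in for volumetry;
# the latent class is the VAK class of the generated covariates and drives
# each patient's exponential survival time.
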
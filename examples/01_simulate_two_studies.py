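"""Generate a two-study synthetic LC-MS dataset with known ground truth.

The generator emulates a pair of case-control metabolomics studies:
lognormal feature intensities, per-feature left censoring at the limit of
detection, daily-batch effects, partially overlapping feature sets, and a
few co-eluting adduct clusters.
"""

from hrmwas import SimConfig, generate_two_studies

cfg = SimConfig(seed=1, n_features=300, frac_affected=0.02, effect_size=0.3)
table1, table2, samples, truth = generate_two_studies(cfg)

print(f"study 1: {table1.intensities.shape[0]} features x {table1.intensities.shape[1]} samples")
print(f"study 2: {table2.intensities.shape[0]} features x {table2.intensities.shape[1]} samples")
print(f"shared features (incl. adduct clusters): {len(truth.shared_feature_ids)}")
print(f"features with a true diagnosis effect:   {truth.affected_feature_ids}")
print(f"mean non-detect fraction, study 1:       {table1.intensities.isna().mean().mean():.3f}")
print(f"example per-feature LOD (lowest detected intensity): {table1.lod.iloc[0]:.1f}")

# Each affected feature's log intensity is shifted by +0.3 in AD vs NC;
# non-detects are values that fell below the feature's detection limit.
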
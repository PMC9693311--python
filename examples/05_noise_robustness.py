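"""Noise-robustness sweep: rank-1 identification rate versus sensor noise.

The morphable model is built once from a noiseless rendering of the
population; gallery and probes are then regenerated at increasing isotropic
noise (expressed as a fraction of the bounding-box diagonal) and re-run
through enroll → identify.
"""

from earmorph import PopulationConfig, noise_sweep

config = PopulationConfig(n_subjects=8, samples_per_subject=2, seed=7)
table = noise_sweep(config, noise_levels=[0.0, 0.01, 0.05], metric="SP", rounds=2)

print("noise level (fraction of bbox diagonal)  rank-1 (%)")
for level, rate in table:
    print(f"  {level:<38g} {rate:6.1f}")
print("Identification degrades as within-subject noise approaches the")
print("between-subject shape variation; small sensor noise is harmless.")
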
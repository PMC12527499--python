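"""Generate a synthetic case-control study and inspect its planted structure.

Builds the full input bundle — bilateral 68-region parcellation, structural
and functional connectomes, control/patient thickness with covariates,
clinical scores and drug-use variables — and prints what was planted so you
can see what downstream analyses are expected to recover.
"""

import numpy as np

from netatrophy import SimulationConfig, simulate_study

config = SimulationConfig(seed=7)
scheme, connectomes, cohort, truth = simulate_study(config)

print(f"regions: {scheme.n_regions}  "
      f"controls: {(~cohort.is_patient).sum()}  patients: {cohort.is_patient.sum()}")
print(f"SC density: {(connectomes.sc > 0).sum() / (68 * 67):.3f}  "
      f"(fraction of possible edges)")
print(f"planted epicenters: {[scheme.names[i] for i in truth.epicenters]}")
print(f"peak atrophy effect: {truth.beta.max():.3f} mm per unit severity")
print(f"severity: mean {truth.severity.mean():.2f}, sd {truth.severity.std():.2f} "
      f"(biotype 1 n={np.sum(truth.biotype == 1)}, biotype 2 n={np.sum(truth.biotype == 2)})")
pat = cohort.subjects.loc[cohort.is_patient]
print(f"median drug use: {pat['duration'].median():.0f} months, "
      f"dose {pat['dose'].median():.0f} units")
# The atrophy effect beta is largest at the epicenters and decays along the
# structural connectome; patient thickness = baseline - severity * beta + noise.
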
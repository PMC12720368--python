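"""Subtype patients with consensus max-margin polytope clustering.

Patients are separated from controls by K margin hyperplanes; the
cross-validated adjusted Rand index across folds selects K, and consensus
over random initializations stabilizes the final labels.
"""

import numpy as np

from mindsubtypes.hydra import HydraConfig, adjusted_rand_index, fit_subtypes
from mindsubtypes.mindnet import mind_matrix, regional_strength
from mindsubtypes.synthcohort import CohortConfig, generate_cohort

bundle = generate_cohort(CohortConfig(n_hc=30, n_sub1=15, n_sub2=15,
                                      n_regions=40, n_vertices=120, seed=7))
strengths = np.array([regional_strength(mind_matrix(bundle.features[i]))
                      for i in range(bundle.n_subjects)])
y = bundle.covariates["diagnosis"].to_numpy()

cfg = HydraConfig(k_range=(2, 3, 4), c_reg=0.25, n_consensus=20,
                  n_folds=10, seed=0)
sol = fit_subtypes(strengths, y, cfg)

print("cross-validated ARI by K:",
      {k: round(v, 3) for k, v in sol.cv_ari_by_k.items()})
print(f"chosen K = {sol.chosen_k}")
truth = bundle.true_subtype[bundle.true_subtype > 0]
print(f"ARI(labels, planted truth) = "
      f"{adjusted_rand_index(sol.labels, truth):.3f}")
print(f"cluster sizes: {np.bincount(sol.labels)[1:]}")
# An ARI near 1 means the consensus labels recover the planted subtypes;
# the CV-ARI profile peaking at K=2 reproduces the model-selection logic.
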
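"""Decompose a paired miRNA/mRNA cohort into shared latent components.

Generates a synthetic cohort with three planted non-Gaussian components,
preprocesses both views, picks the dimension by the random-matrix bound,
fits the joint ICA with stability scoring, and reports how well the planted
components were recovered.
"""

import numpy as np

import mirmix as mm
from mirmix import jointica, preprocess

bundle = mm.generate_joint_dataset(mm.SyntheticConfig(seed=1))

mrna = preprocess.log2_with_pseudo(
    preprocess.filter_cv_outliers(preprocess.filter_low_abundance(bundle.E_m))
)
mirna = preprocess.log2_with_pseudo(
    preprocess.filter_cv_outliers(preprocess.filter_low_abundance(bundle.E_mi))
)
print(f"after filtering: {mrna.n_features} genes, {mirna.n_features} miRNA strands, "
      f"{mrna.n_samples} samples")

n_comp = mm.choose_joint_dimension(mrna, mirna)
print(f"random-matrix dimension estimate: {n_comp} components")

model = mm.stability_analysis(mrna, mirna, n_comp, runs=10, base_seed=7)
print("per-component stability over 10 restarts:",
      np.round(model.stability, 4))

truth_m = bundle.truth.C_m.loc[mrna.feature_ids].to_numpy()
match = jointica.abs_spearman_matrix(truth_m, model.C_m.to_numpy()).max(axis=1)
print("matched |Spearman| between planted and recovered gene weights:",
      np.round(match, 3))
# Stability near 1 means every restart found the same component; matched
# correlations near 1 mean the planted transcriptional programs were recovered.
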
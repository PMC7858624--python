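"""Generate a small multi-cohort corpus with a planted similarity hierarchy.

Builds a 4-cohort dataset whose cohorts form two planted pairs, prints the
planted tree, the slide manifest, and the noisy-label bookkeeping of one
positive slide.
"""

import numpy as np

import supercohort as sc
from supercohort.synthetic import GenerationConfig, manifest

# two planted pairs: (0,1) merge low, (2,3) merge low, pairs join at the root
tree = ((0, 1, 0.1), (2, 3, 0.1), 3.0)
hierarchy = sc.generate_planted_hierarchy(4, tree, seed=0)
print("planted hierarchy (newick):", hierarchy.to_newick())
print("ground-truth grouping at S=2:", hierarchy.partition_at(2))

config = GenerationConfig(n_pos_slides=6, n_neg_slides=6, patches_per_slide=10,
                          tumor_fraction=0.7, patch_size=16)
dataset = sc.generate_dataset(hierarchy, config, seed=42)

man = manifest(dataset)
print(f"\n{len(man)} slides across {dataset.n_cohorts} cohorts:")
print(man.groupby(["cohort_id", "label"]).size().unstack())

# noisy labels: every patch of a positive slide is labeled positive, but only
# round(tumor_fraction * patches_per_slide) patches are latent cancer
slide = dataset.slides(0, label=1)[0]
n_cancer = sum(p.latent_state == "cancer" for p in slide.patches)
print(f"\nslide {slide.slide_id}: {len(slide.patches)} patches, "
      f"all labeled {slide.patches[0].assigned_label}, "
      f"{n_cancer} latent-cancer ({slide.tumor_fraction:.0%} tumor fraction)")

# parameter distances follow the planted tree
theta = np.stack([p.theta for p in dataset.params])
d_pair = np.linalg.norm(theta[0] - theta[1])
d_cross = np.linalg.norm(theta[0] - theta[2])
print(f"\n|theta_0 - theta_1| = {d_pair:.2f} (planted pair)")
print(f"|theta_0 - theta_2| = {d_cross:.2f} (across the root)")
print("closer in the tree -> closer texture parameters")
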
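"""Reconstruct a designed single-box angle distribution from couplings.

Synthetic couplings are computed as the average over all conformers in
a 15x15-degree box (plus 1% Gaussian noise), the adequate ensemble size
is chosen by 20% free-RDC cross-validation, and the recovered basin
population is compared with the truth.
"""

import numpy as np

from rdcsel import (
    BasinSpec,
    GAConfig,
    SyntheticTarget,
    default_angle_grid,
    default_rdc_keys,
    generate_hinge_pool,
    make_toy_structure,
    precompute_pool_rdcs,
    reconstruct_and_score,
)

structure, domains = make_toy_structure()
pool = generate_hinge_pool(
    structure, domains, default_angle_grid(25, 25), jitter=0.7, rng_seed=1
)
precompute_pool_rdcs(pool, default_rdc_keys(structure))

box = BasinSpec("target", (52.5, 67.5), (117.5, 132.5))
target = SyntheticTarget((box,), (1.0,), noise_pct=1.0, rng_seed=1)

dist, errors, n_star, pops = reconstruct_and_score(
    pool, target, GAConfig.scaled(rng_seed=1), sizes=(1, 2, 4, 8, 16),
)
print(f"selected ensemble size N* = {n_star} "
      "(smallest N whose held-out Q_free has plateaued)")
print(f"recovered population in the target basin: {pops['target']:.2f} "
      f"(truth 1.00, error {errors['target']:.2f})")
print("  -> the single-state target is recovered as a concentrated basin")
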
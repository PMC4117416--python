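"""Predict a steric alignment tensor and back-calculate N-H couplings.

Builds the synthetic three-domain test protein in its open state,
predicts its alignment tensor from shape alone (planar-barrier
obstruction model), back-calculates the amide couplings, and verifies
that an SVD tensor fit to those couplings recovers the predictor's
tensor (Q ~ 0: the two routes agree).
"""

import numpy as np

from rdcsel import (
    StericConfig,
    back_calculate,
    coarse_grain,
    default_rdc_keys,
    fit_tensor_svd,
    make_toy_structure,
    predict_tensor,
)

structure, domains = make_toy_structure(preset="open")
tensor = predict_tensor(coarse_grain(structure, "residue"), StericConfig())
w = tensor.eigenvalues
print(f"predicted tensor eigenvalues (x, y, z): {w[0]:+.5f} {w[1]:+.5f} {w[2]:+.5f}")
print("  -> the molecule's shape induces this degree/direction of alignment")

keys = default_rdc_keys(structure)
calc = back_calculate(structure, tensor, keys)
print(f"back-calculated {len(calc)} N-H couplings, "
      f"range {calc.values.min():.0f} to {calc.values.max():.0f} Hz "
      "(arbitrary overall scale; refit against experiment downstream)")

refit, q = fit_tensor_svd(structure, calc)
print(f"SVD refit of the tensor from those couplings: Q = {q:.2e}")
print("  -> a single rigid structure under one tensor is self-consistent")
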
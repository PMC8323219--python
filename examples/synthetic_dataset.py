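"""Generate a synthetic correlated-label fundus dataset and validate it.

Samples annotations from the default three-profile mixture (whose pairwise
conditional probabilities have a closed form), renders label-encoding
images, and compares the empirical conditionals estimated from the sample
against the generator's exact ones.
"""

import tempfile
from pathlib import Path

import numpy as np

from fundusgcn import (RenderSpec, conditional_probabilities,
                       cooccurrence_counts, default_mixture, generate_dataset,
                       sample_labels, true_conditional_probabilities)

mix = default_mixture()
print("labels:", mix.labels)
print("mixture marginal prevalences:",
      np.round(mix.marginals, 3))

with tempfile.TemporaryDirectory() as td:
    manifest = generate_dataset(20, mix, RenderSpec(size=64), td, seed=11)
    n_files = len(list((Path(td) / "images").glob("*.png")))
    print(f"\nwrote {n_files} PNG images and a manifest with "
          f"{len(manifest)} rows")
    print(manifest.iloc[0].to_dict())

Y = sample_labels(20_000, mix, seed=11)
P_hat = conditional_probabilities(cooccurrence_counts(Y))
P_true = true_conditional_probabilities(mix)
err = np.abs(P_hat - P_true).max()
print(f"\nmax |empirical - closed-form| conditional probability at "
      f"n=20000: {err:.4f}")
print("The generator's label dependence is analytically known, so the"
      "\ngraph-construction pipeline can be validated against exact values.")
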
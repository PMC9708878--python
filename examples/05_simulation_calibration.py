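"""Simulate case-control corpora with known truth and check the pipeline.

The generator draws control genotypes from Hardy-Weinberg proportions and
case genotypes from odds-ratio-reweighted proportions with a Normal(0, tau2)
study-level shift — the model random-effects pooling assumes — so pooled
estimates can be compared against ground truth.
"""

import math

import numpy as np

from snpmeta import (
    Contrast,
    SyntheticConfig,
    expected_allele_log_or,
    meta_analyze,
    simulate_corpus,
)

cfg = SyntheticConfig(
    k=50, q=0.3, or_het=1.5, or_hom=2.25, tau2=0.05,
    n_case_range=(500, 500), n_control_range=(500, 500), seed=42,
)
truth = expected_allele_log_or(cfg)
print(f"true allele-contrast OR: {math.exp(truth):.3f} (log {truth:.4f})")

est = []
for rep in range(50):
    corpus = simulate_corpus(SyntheticConfig(**{**cfg.__dict__, "seed": 42 + rep}))
    est.append(meta_analyze(corpus, Contrast.ALLELE, model="re",
                            apply_filter=False).log_or)
print(f"mean DL estimate over 50 corpora: OR {math.exp(np.mean(est)):.3f} "
      f"(bias {np.mean(est) - truth:+.4f} on the log scale)")

null = SyntheticConfig(k=15, q=0.3, n_case_range=(300, 300),
                       n_control_range=(300, 300))
rejections = 0
for rep in range(200):
    corpus = simulate_corpus(SyntheticConfig(**{**null.__dict__, "seed": 1000 + rep}))
    rejections += meta_analyze(corpus, Contrast.ALLELE,
                               apply_filter=False).p < 0.05
print(f"type-I error under the global null: {rejections / 200:.3f} (nominal 0.05)")

print(
    "\nSmall bias and near-nominal rejection rate show the pooling pipeline"
    "\nis calibrated under its own model assumptions."
)
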
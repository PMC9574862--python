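"""The BRlogD/TPSA solubility classifier: fixed rule and refit tree.

The fixed rule classifies a degrader high when TPSA >= 289.31 Å², low when
(below that) BRlogD >= 2.58, and intermediate otherwise. A CART learner
refit on rule-labelled points recovers the same two splits; 10-fold
cross-validation reports how well the classes are predicted from the
descriptors on a synthetic panel."""

import numpy as np

from protacsol import (
    GeneratorConfig,
    classify_solubility_rule,
    cross_validate,
    generate_dataset,
    learn_tree,
)

for tpsa, brlogd in ((300.0, 5.0), (200.0, 3.0), (200.0, 2.0)):
    cls = classify_solubility_rule(tpsa, brlogd)
    print(f"TPSA = {tpsa:5.1f}, BRlogD = {brlogd:3.1f}  ->  {cls.value}")

rng = np.random.default_rng(0)
tpsa = rng.uniform(150, 400, 400)
brlogd = rng.uniform(0, 6, 400)
labels = [classify_solubility_rule(t, b) for t, b in zip(tpsa, brlogd)]
tree = learn_tree(np.column_stack([tpsa, brlogd]), labels, ["tpsa", "brlogd"])
print(f"refit splits: {[(f, round(t, 2)) for f, t in tree.splits()]}")

ds = generate_dataset(GeneratorConfig(n_compounds=200, seed=0))
feats = ["tpsa", "brlogd", "log_kw_iam"]
X = np.array([[getattr(ds.descriptors[c.id], f) for f in feats] for c in ds.compounds])
y = [ds.solubility[c.id].gsk_class for c in ds.compounds]
acc, cm = cross_validate(X, y, feats, k=10, seed=0, max_depth=3)
print(f"10-fold CV accuracy on a synthetic panel: {100 * acc:.1f}%")
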
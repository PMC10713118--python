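"""Detect synthetic malignant cells and recover their cell of origin.

Trains the base hierarchy model, then a pancreas cancer model that
separates ductal-derived tumor cells from normal ductal/acinar epithelium.
A mixed query (held-out normals plus tumors derived from an independent
draw) is annotated, gated to epithelial-predicted cells, and scored. The
cell of origin is simply the retained base prediction of each cancer cell,
so a correct value means tumors were first routed to their source type.
"""

import numpy as np
import pandas as pd
import scipy.sparse as sp

import census as cs

ref, _, _ = cs.generate(cs.GeneratorSpec(seed=1))
rng = np.random.default_rng(7)
idx = rng.permutation(ref.matrix.n_cells)
n_train = int(0.7 * len(idx))
train = ref.subset_cells(np.sort(idx[:n_train]))
test = ref.subset_cells(np.sort(idx[n_train:]))
config = cs.RunConfig(seed=11)
model = cs.train_census(train, config)

epithelium = train.subset_cells(
    np.flatnonzero(pd.Series(train.labels).isin(["ductal", "acinar"]).values)
)
tumor_train = cs.make_tumor(train, "ductal", n_cells=300, replace=True, seed=5)
cancer_model = cs.train_cancer_model(tumor_train, epithelium, "pancreas", config)
print(f"cancer model ({cancer_model.organ}): training AUC "
      f"{cancer_model.training_auc:.3f}")

# query tumors come from an independent generator draw so their rows are
# distinct from the query's normal cells (duplicated rows distort UMAP)
other, _, _ = cs.generate(cs.GeneratorSpec(seed=101))
tumor_query = cs.make_tumor(other, "ductal", n_cells=150, seed=9)
query = cs.CountMatrix(
    sp.vstack([test.matrix.counts, tumor_query.counts]),
    test.matrix.gene_ids,
    np.concatenate([test.matrix.cell_ids, tumor_query.cell_ids]),
)
is_tumor = np.r_[np.zeros(test.matrix.n_cells, bool), np.ones(150, bool)]

base = cs.annotate(model, query, config)
calls = cs.detect_cancer(base, cancer_model, query, base.embedding, config)
called = calls["is_cancer"].values
true_epi = pd.Series(np.asarray(test.labels)).isin(["ductal", "acinar"]).values
print(f"sensitivity on tumor cells: {called[is_tumor].mean():.3f}")
print(f"specificity on normal epithelium: "
      f"{1 - called[:test.matrix.n_cells][true_epi].mean():.3f}")
origins = calls.loc[is_tumor & called, "cell_of_origin"].value_counts()
print("predicted cells of origin:", {k: int(v) for k, v in origins.items()})
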
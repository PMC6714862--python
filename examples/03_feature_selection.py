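"""Two-stage feature selection: significance-test filter, then greedy
sequential backward selection.

The filter picks one two-sample test for all columns (t-test if most
column-halves look normal, else Kolmogorov-Smirnov) and keeps columns
with p < alpha.  SBS then greedily eliminates features, scoring each
candidate subset with an SVM, down to a single feature.
"""

import numpy as np

from eegemo import generate_feature_table, sbs, significance_filter
from eegemo.classify import apply_normalizer, fit_normalizer, train_svm_rbf

# 8 subjects x 20 trials, 5 informative columns of 30 (mean shift 2.0)
fm = generate_feature_table(n_subjects=8, n_trials=20, n_features=30,
                            n_informative=5, delta=2.0, subject_sd=0.3,
                            seed=21)

result = significance_filter(fm, alpha=0.05)
print(f"test chosen: {result.test_used}")
print(f"retained {result.retained_count} of {fm.n_features} columns:")
print(" ", result.filtered.column_names)


def training_accuracy(cols):
    X = result.filtered.values[:, list(cols)]
    norm = fit_normalizer(X)
    clf = train_svm_rbf(apply_normalizer(norm, X), fm.labels)
    return float((clf.predict(apply_normalizer(norm, X)) == fm.labels).mean())


trace = sbs(result.filtered.column_names, training_accuracy)
print(f"SBS visited subset sizes {trace.subset_sizes}")
print(f"accuracy per subset       {[round(a, 3) for a in trace.subset_accuracy]}")
print(f"best subset: {trace.best_subset}")
# the informative columns are f000-f004; the filter should retain them
# and SBS should keep a subset of them
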
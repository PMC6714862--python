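"""Compare the filter + SBS + SVM reference against standard baselines on
identical leave-one-subject-out folds.

Differences are reported in percentage points of mean LOSO accuracy
(reference minus baseline); a positive difference means the reference is
better.  The same aggregation applied to published per-method differences
reproduces published averages.
"""

from eegemo import ComparisonReport, compare_methods, generate_feature_table

fm = generate_feature_table(n_subjects=6, n_trials=20, n_features=30,
                            n_informative=5, delta=1.2, subject_sd=0.5,
                            seed=17)

report = compare_methods(fm, methods=["svm", "knn", "rf"], random_state=0)
print("mean LOSO accuracy per method:")
for method, acc in report.accuracies.items():
    print(f"  {method:10s} {acc:.3f}")
print("difference from reference (percentage points):")
for method, diff in report.differences_pct.items():
    print(f"  {method:10s} {diff:+.1f}")
print(f"average difference: {report.average_difference_pct:+.1f}")

# aggregation sanity check on externally supplied differences
published = ComparisonReport.from_differences(
    "st_sbssvm", {"svm": 17, "pca_svm": 17, "sbs": -0.42, "knn": 10,
                  "pca_knn": 11, "rf": 20})
print(f"published-differences average: "
      f"{published.average_difference_pct:+.1f}")
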
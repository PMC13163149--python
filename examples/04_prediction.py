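"""Benchmark CRS-R regression and outcome classification on a synthetic cohort.

Trains the four regression families (nested cross-validation) and the three
outcome pipelines (LOOCV selection inside a stratified 70/30 split), then
scores a single held-out-style subject with the fitted random forest.
"""

from respvar import compare, predict, simulate

cohort = simulate.simulate_cohort(simulate.CohortSpec(seed=3, render=False))
features = simulate.cohort_feature_table(cohort)
subjects = compare.subjects_to_frame(simulate.cohort_subject_records(cohort))

fast = {"n_iter": 8, "inner_folds": 3, "selection_cv": 5,
        "regression": {"random_forest": {"model__n_estimators": [150]}},
        "classification": {"rf_direct": {"model__n_estimators": [150]}}}

X, y = predict.build_matrix(features, subjects, "crsr")
reg = predict.train_crsr_models(X, y, config=fast, seed=3)
print("CRS-R regression (outer-CV metrics):")
print(reg.to_frame().round(3).to_string())
print("\ntop 5 random-forest features:",
      [name for name, _ in reg.importances[:5]])

Xo, yo = predict.build_matrix(features, subjects, "outcome")
clf = predict.train_outcome_models(Xo, yo, config=fast, seed=3)
print("\noutcome classification (validation metrics):")
print(clf.to_frame().round(3).to_string())

bundle = predict.make_bundle(reg.models["random_forest"], reg.feature_names, "crsr")
pred = predict.predict_single(bundle, X.iloc[0].to_dict())
print(f"\nsingle-subject CRS-R prediction: {pred:.1f} (actual {y[0]:.0f})")
# Lower MSE/RMSE/MAE and higher R^2 are better; AUC near 0.5 means no skill.
# On this synthetic cohort the links are weak-to-moderate by design, so
# absolute numbers describe the simulation, not any clinical population.
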
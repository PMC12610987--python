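"""Cohort-level analysis: group statistics, consensus feature selection, and
diagnosis / bronchodilator-response models.

A synthetic asthma/COPD/control cohort is generated with planted VOC effects.
Clinical biomarkers are compared across groups with the routed tests, VOC
features are ranked by stability selection (resampled XGBoost importances) in
each breathing maneuver, the per-maneuver top-30 lists are intersected, and two
models are evaluated: asthma vs control on a 70/30 held-out split, and BDR
(asthma+COPD only, VOCs + clinical biomarkers) by leave-one-out CV. Metrics are
computed at a 0.5 probability threshold.
"""

from breathsig import (
    compare_groups, consensus_features, evaluate, filter_model_features,
    resample_importance, split_data, tune_and_fit,
)
from breathsig.pipeline import run_bdr_pipeline
from breathsig.synthetic import CohortSimConfig, simulate_cohort

cfg = CohortSimConfig(n_per_group={"asthma": 40, "copd": 35, "control": 50},
                      n_noise_features=100, seed=5)
cohort, matrices = simulate_cohort(cfg)
print(f"cohort: {cohort.group.value_counts().to_dict()}, "
      f"BDR+ among patients: {(cohort[cohort.group != 'control'].bdr == 'positive').mean():.0%}")

for var in ("feno_ppb", "eos_10e9_l", "ige_iu_ml"):
    r = compare_groups(cohort, var, groups=("asthma", "copd"))
    print(f"  {var:12s} asthma vs copd: {r.test_used:12s} p = {r.p_value:.2e}")

# stability selection per maneuver on the training split, then intersection
sub = cohort[cohort.group.isin(["asthma", "control"])]
y = (sub.group == "asthma").astype(int)
train, test = split_data(sub.index.to_numpy(), sub.group.to_numpy(), 0.7, seed=1)
imps = {}
for maneuver in ("forced", "tidal"):
    X = filter_model_features(matrices[maneuver]).values.loc[train]
    imps[maneuver] = resample_importance(X, y.loc[train], n_iter=200, seed=1)
sel = consensus_features(imps["forced"], imps["tidal"], top_k=30)
print(f"\nconsensus features ({len(sel.consensus_features)} of top-30 x top-30):")
print("  " + ", ".join(f"{f:.3f}" for f in sel.consensus_features[:10]) + " ...")

for maneuver in ("forced", "tidal"):
    X = filter_model_features(matrices[maneuver]).values
    model = tune_and_fit(X.loc[train, sel.consensus_features], y.loc[train], seed=1)
    rep = evaluate(model, X.loc[test, sel.consensus_features], y.loc[test],
                   n_train=len(train))
    print(f"asthma vs control [{maneuver}]: AUC {rep.auc:.3f}, "
          f"sens {rep.sensitivity:.2f}, spec {rep.specificity:.2f} at 0.5")

bdr = run_bdr_pipeline(cohort, matrices, n_iter=200, seed=2)
for maneuver, rep in bdr["reports"].items():
    print(f"BDR [{maneuver}, LOO, n={bdr['n_subjects']}]: AUC {rep.auc:.3f}, "
          f"sens {rep.sensitivity:.2f}, spec {rep.specificity:.2f}, "
          f"PPV {rep.ppv:.2f}, NPV {rep.npv:.2f}")
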
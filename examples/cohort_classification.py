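"""Build a small labelled cohort, cross-validate the autocorrelation
univariate model and the backward-selected multivariate model.

Run:  python examples/cohort_classification.py
"""

import warnings

import ppgaf as pg

records = pg.simulate_cohort(40, 40, seed=11)
table = pg.cohort_feature_table(records)
X, y = pg.modeling_frame(table)
print(f"{len(X)} analyzable windows ({int(y.sum())} AF)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ac = pg.kfold_cv(X[["AC"]], y, k=10, seed=11)
    multi = pg.kfold_cv(X, y, k=10, seed=11, select_alpha=0.157)

for name, rep in (("AC univariate", ac), ("multivariate", multi)):
    a = rep.averaged
    print(f"{name:14s} AUC {a['auc']:.3f}  sens {a['sensitivity']:.1f}%  "
          f"spec {a['specificity']:.1f}%  acc {a['accuracy']:.1f}%")

print(
    "\nThe AC feature alone separates AF from SR almost perfectly without any"
    "\npulse detection; adding interval-based features nudges performance higher."
)
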
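"""Kernel-mean radiomics end to end for one centre.

Trains a local model, extracts one feature per convolution kernel, filters
with the Mann-Whitney U test, reduces with mRMR and classifies with the
sparse Bayesian ELM; prints the feature counts at each stage and the final
held-out AUC.
"""

from fedrad.cohort import CentreSpec, generate_cohort
from fedrad.evalstats import ScoredSet, roc_auc
from fedrad.model import TrainConfig, build_local_model, prepare_inputs, small_config, train_local
from fedrad.model import count_conv_kernels
from fedrad.radiomics import extract_features, mann_whitney_filter, mrmr_select, FeatureMatrix
from fedrad.sbelm import SBELM

spec = CentreSpec("demo", 40, 40, 40, 40, seed=1)
train, test = generate_cohort(spec, patch_size=32)

config = small_config()
model = build_local_model(config, seed=0)
train_local(model, train, TrainConfig(epochs=15, learning_rate=1e-3, optimizer="rmsprop", seed=0))

Xtr, ytr = prepare_inputs(train, config.input_size)
Xte, yte = prepare_inputs(test, config.input_size)
feats_tr = extract_features(model, Xtr, labels=ytr)
feats_te = extract_features(model, Xte, labels=yte)
print(f"extracted {feats_tr.values.shape[1]} kernel-mean features "
      f"(= {count_conv_kernels(config)} convolution kernels in this model)")

mw = mann_whitney_filter(feats_tr, ytr, alpha=0.05)
print(f"Mann-Whitney filter keeps {len(mw.kept_ids)} class-discriminative features")

idx = [feats_tr.feature_ids.index(i) for i in mw.kept_ids]
sub = FeatureMatrix(values=feats_tr.values[:, idx], feature_ids=mw.kept_ids, labels=ytr)
sel = mrmr_select(sub, ytr, k=20)
print(f"mRMR retains the {len(sel.kept_ids)} most valuable features")

cols = [feats_tr.feature_ids.index(i) for i in sel.kept_ids]
clf = SBELM(n_hidden=30, seed=0).fit(feats_tr.values[:, cols], ytr)
scores = clf.predict_proba(feats_te.values[:, cols])
_, auc = roc_auc(ScoredSet(scores=scores, labels=yte))
pruned = clf.model_.pruned_mask.mean()
print(f"SBELM held-out AUC {auc:.3f} with {pruned:.0%} of output weights pruned")
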
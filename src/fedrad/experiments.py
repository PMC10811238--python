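"""Desk-scale experiment protocols over the synthetic four-centre cohort.

The full published cohort (641 patients, 64x64 patches, a 4449-kernel
model) is too heavy to train repeatedly on one CPU, so the simulation
experiments run a scaled-down mirror of the same study design: four centres
whose class imbalance follows the published per-centre training fractions,
the same non-IID shift structure, ~40 patients per centre, 32x32 inputs and
a small CBAM ResNet.  Methods and comparisons are unchanged — only the
problem size shrinks.
"""

from __future__ import annotations

import numpy as np

from .cohort import CentreSpec, Cohort, generate_cohort, reference_cohort_specs
from .evalstats import ScoredSet, permutation_robustness, roc_auc
from .federation import FederationConfig, run_federation
from .model import TrainConfig, predict_proba, prepare_inputs, small_config
from .radiomics import extract_features, select_features
from .sbelm import SBELM

__all__ = [
    "scaled_specs",
    "scaled_cohorts",
    "evaluate_models",
    "personalized_vs_fedavg",
    "permutation_experiment",
    "radiomics_pipeline_scores",
    "EXPERIMENT_TRAIN",
]

#: Local-training settings for the scaled-down experiments: RMSprop, which
#: optimizes the small un-normalized CBAM network far more reliably across
#: initializations than momentum SGD at this scale.
EXPERIMENT_TRAIN = TrainConfig(epochs=1, batch_size=16, learning_rate=1e-3,
                               optimizer="rmsprop", seed=0)

_PATCH_SIZE = 32


def scaled_specs(n_per_centre: int = 40, seed: int = 0) -> list[CentreSpec]:
    """The four published centres scaled to ``n_per_centre`` training
    patients each, preserving class imbalance fractions and centre shifts."""
    specs = []
    for i, ref in enumerate(reference_cohort_specs()):
        frac = ref.n_train_pos / (ref.n_train_pos + ref.n_train_neg)
        npos = max(3, int(round(n_per_centre * frac)))
        nneg = n_per_centre - npos
        specs.append(
            CentreSpec(
                centre_id=ref.centre_id,
                n_train_pos=npos,
                n_train_neg=nneg,
                n_test_pos=npos,
                n_test_neg=nneg,
                intensity_offset=ref.intensity_offset,
                noise_sigma=ref.noise_sigma,
                texture_freq=ref.texture_freq,
                seed=seed * 100 + i,
                clinical=ref.clinical,
            )
        )
    return specs


def scaled_cohorts(n_per_centre: int = 40, seed: int = 0) -> tuple[list[Cohort], list[Cohort]]:
    trains, tests = [], []
    for spec in scaled_specs(n_per_centre, seed):
        tr, te = generate_cohort(spec, _PATCH_SIZE)
        trains.append(tr)
        tests.append(te)
    return trains, tests


def evaluate_models(models, test_cohorts) -> np.ndarray:
    """Per-centre test AUC of each client's model on its own centre."""
    aucs = []
    for m, te in zip(models, test_cohorts):
        X, y = prepare_inputs(te, m.config.input_size)
        _, auc = roc_auc(ScoredSet(scores=predict_proba(m, X), labels=y))
        aucs.append(auc)
    return np.array(aucs)


def _run(trains, fed_cfg: FederationConfig):
    tc = TrainConfig(
        epochs=1,
        batch_size=EXPERIMENT_TRAIN.batch_size,
        learning_rate=EXPERIMENT_TRAIN.learning_rate,
        optimizer=EXPERIMENT_TRAIN.optimizer,
        seed=fed_cfg.seed,
    )
    return run_federation(trains, fed_cfg, train_config=tc)


def personalized_vs_fedavg(
    seeds=(1, 2, 3, 4, 5),
    n_per_centre: int = 40,
    n_rounds: int = 3,
    local_epochs: int = 5,
) -> dict:
    """Paired-seed comparison of the personalized scheme against FedAvg.

    For each seed, both methods federate the same cohorts from the same
    initialization; reports per-seed per-centre AUCs and the paired means.
    """
    personalized_aucs, fedavg_aucs = [], []
    for seed in seeds:
        trains, tests = scaled_cohorts(n_per_centre, seed)
        res_r = _run(trains, FederationConfig(n_rounds=n_rounds, local_epochs=local_epochs, seed=seed))
        res_f = _run(
            trains,
            FederationConfig(n_rounds=n_rounds, local_epochs=local_epochs, gcn=False, gan=False, seed=seed),
        )
        personalized_aucs.append(evaluate_models(res_r.models, tests))
        fedavg_aucs.append(evaluate_models(res_f.models, tests))
    personalized_aucs = np.array(personalized_aucs)
    fedavg_aucs = np.array(fedavg_aucs)
    return {
        "seeds": list(seeds),
        "personalized_aucs": personalized_aucs,
        "fedavg_aucs": fedavg_aucs,
        "personalized_mean": float(personalized_aucs.mean()),
        "fedavg_mean": float(fedavg_aucs.mean()),
    }


def permutation_experiment(
    n_per_centre: int = 40,
    n_perms: int = 5,
    n_rounds: int = 3,
    local_epochs: int = 5,
    seed: int = 0,
) -> dict:
    """Robustness to redistributing training patients among centres."""
    trains, tests = scaled_cohorts(n_per_centre, seed)

    def pipeline(shuffled_trains, test_cohorts, run_seed):
        res = _run(
            shuffled_trains,
            FederationConfig(n_rounds=n_rounds, local_epochs=local_epochs, seed=int(run_seed) % (2**31)),
        )
        return evaluate_models(res.models, test_cohorts)

    return permutation_robustness(trains, tests, pipeline, n_perms=n_perms, seed=seed)


def radiomics_pipeline_scores(
    model, train_cohort: Cohort, test_cohort: Cohort, k: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Classification through the full radiomic chain for one centre:
    kernel-mean features -> Mann-Whitney + mRMR -> SBELM -> test scores."""
    Xtr, ytr = prepare_inputs(train_cohort, model.config.input_size)
    Xte, yte = prepare_inputs(test_cohort, model.config.input_size)
    ftr = extract_features(model, Xtr, labels=ytr)
    fte = extract_features(model, Xte, labels=yte)
    sel = select_features(ftr, ytr, k=k)
    idx = [ftr.feature_ids.index(i) for i in sel.kept_ids]
    clf = SBELM(n_hidden=min(50, max(10, len(idx))), seed=seed)
    clf.fit(ftr.values[:, idx], ytr)
    return clf.predict_proba(fte.values[:, idx]), yte
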
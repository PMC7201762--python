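"""End-to-end recovery benchmarks on synthetic studies.

Each run generates a fresh planted study, executes the relevant pipeline
stages, and measures how much of the planted structure is recovered.
These power both the test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .corr_network import DCSConfig, correlate_probes_genes, dcs_select
from .deep_select import DeepSelectConfig, DeepSelectPLS
from .prescreen import prescreen_probes
from .simulate import SimulationConfig, generate_study

__all__ = ["signature_recovery_run", "dcs_recovery_run"]


def signature_recovery_run(seed: int) -> dict:
    """Prescreen + deep-select on a 70/30 cohort with 50 planted probes.

    Returns planted-probe recall of the selected signature, the
    cross-validated accuracy, and the accuracy on a held-out cohort drawn
    from the same probe-level laws with fresh sampling noise.
    """
    cfg = SimulationConfig(
        n_current=70, n_never=30, n_probes=2000, n_genes=50,
        n_signature=50, delta_beta=0.25, n_dcs_pairs=0, rng_seed=seed,
    )
    study = generate_study(cfg, include_validation=True)
    pres = prescreen_probes(study.methylation, study.metadata, q=0.05)
    survivors = pres.selected_probes
    model = DeepSelectPLS.from_dataframes(
        study.methylation.loc[survivors], study.metadata
    )
    res = model.fit(DeepSelectConfig(random_state=seed % 2**31))
    truth = study.truth_signature_probes
    recall = len(set(res.signature) & truth) / len(truth)

    X_val = study.validation_methylation.T
    y_val = np.where(
        study.validation_metadata.loc[X_val.index, "smoking_status"] == "current",
        1,
        -1,
    )
    holdout = res.evaluate(X_val, y_val)
    return {
        "recall": recall,
        "cv_acc": res.cv_metrics.acc,
        "holdout_acc": holdout.acc,
        "n_signature": len(res.signature),
        "n_prescreened": len(survivors),
    }


def dcs_recovery_run(seed: int, method: str = "bicor") -> dict:
    """Differential-correlation recovery on the default 102/43 cohort.

    25 planted probe–gene pairs (coupled at |r| ~ 0.9 in one smoking
    group, independent in the other) among 50 signature probes x 1000
    genes. Reports the fraction of planted pairs recovered at
    TS1=0.3/TS2=0.6 and the false-pair rate per 10^4 null pairs.
    """
    cfg = SimulationConfig(rng_seed=seed)  # defaults: 102/43, 2000x1000, 25 pairs
    study = generate_study(cfg, include_validation=False)
    sig = sorted(study.truth_signature_probes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = correlate_probes_genes(
            study.methylation.loc[sig], study.expression, study.metadata,
            method=method,
        )
    selected, _ = dcs_select(table, DCSConfig(ts1=0.3, ts2=0.6))
    got = set(zip(selected["probe_id"], selected["gene_id"]))
    truth = study.truth_dcs_pairs
    n_null = len(table) - len(truth)
    n_false = len(got - truth)
    return {
        "pair_recall": len(got & truth) / len(truth),
        "false_pairs_per_10k": 1e4 * n_false / n_null,
        "n_selected": len(got),
    }
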
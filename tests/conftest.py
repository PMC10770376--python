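import dataclasses

import numpy as np
import pytest

from gspgcn import chebnet, connectivity, preprocess
from gspgcn.montage import generate_montage
from gspgcn.pipeline import RunConfig, TrainConfig, VoteConfig, run_pipeline
from gspgcn.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def montage64():
    return generate_montage(64)


@pytest.fixture(scope="session")
def strong_cohort(montage64):
    """Separable study condition: p2_effect = 2.5, 20 subjects per group,
    100 trials.  Computed once; several analyses reuse it."""
    cfg = CohortConfig(n_subjects_per_group=20, n_trials=100, p2_effect=2.5, seed=5)
    epoch_sets, labels = simulate_cohort(cfg, montage64)
    return cfg, epoch_sets, np.asarray(labels)


@pytest.fixture(scope="session")
def strong_graphs(montage64, strong_cohort):
    """Preprocessed connectivity graphs for the separable cohort."""
    _, epoch_sets, labels = strong_cohort
    graphs = [
        connectivity.build_graph(preprocess.preprocess_epochs(es, montage64).epochs)
        for es in epoch_sets
    ]
    return graphs, labels


@pytest.fixture(scope="session")
def strong_inputs(strong_graphs):
    graphs, labels = strong_graphs
    inputs = [
        chebnet.prepare_subject(g.A2, g.W, K1=3, K2=3, subject_id=g.subject_id)
        for g in graphs
    ]
    return inputs, labels


@pytest.fixture(scope="session")
def small_cohort(montage64):
    """A fast cohort for smoke-level checks."""
    cfg = CohortConfig(n_subjects_per_group=4, n_trials=20, p2_effect=2.5, seed=3)
    epoch_sets, labels = simulate_cohort(cfg, montage64)
    return cfg, epoch_sets, np.asarray(labels)


@pytest.fixture(scope="session")
def strong_trial_sets(strong_graphs, strong_cohort):
    """Per-trial connectivity stacks for the separable cohort, packaged for
    trial-level training on each subject's multi-hop graph."""
    graphs, labels = strong_graphs
    _, epoch_sets, _ = strong_cohort
    montage = generate_montage(64)
    sets = []
    for g, es in zip(graphs, epoch_sets):
        clean = preprocess.preprocess_epochs(es, montage).epochs
        tw = connectivity.pcc_matrix(connectivity.narrowband(clean), aggregate="trial")
        tmpl = chebnet.prepare_subject(g.A2, g.W, K1=3, K2=3, subject_id=g.subject_id)
        sets.append(
            chebnet.TrialSet(template=tmpl, X=tw, label=int(g.group_label),
                             subject_id=g.subject_id)
        )
    return sets, labels


@pytest.fixture(scope="session")
def sparse_common_graph(montage64, strong_cohort):
    """Common sparse self-expressive adjacency fitted on the separable
    cohort's trial-averaged ERPs (the GSP stage's convolution graph)."""
    from gspgcn import sparse_graph

    _, epoch_sets, labels = strong_cohort
    signals = np.stack(
        [preprocess.preprocess_epochs(es, montage64).erp.data for es in epoch_sets]
    )
    models = sparse_graph.fit_all_electrodes(
        signals, groups=labels, tol=1e-5, max_iter=100
    )
    return sparse_graph.apply_sparse_graph(models, signals.shape[1])


def tiny_run_config(seed=5, gsp=True):
    """A minimal full-pipeline configuration used by the determinism and
    ablation checks."""
    cfg = RunConfig(
        seed=seed,
        cohort=CohortConfig(n_subjects_per_group=4, n_trials=16),
        train=TrainConfig(folds=2, epochs=8),
        vote=VoteConfig(repeats=10, draw=10),
    )
    cfg.stages.gsp = gsp
    cfg.sparse = dataclasses.replace(cfg.sparse, max_iter=15)
    cfg.microstates = dataclasses.replace(cfg.microstates, k_max=4, n_init=5)
    return cfg


@pytest.fixture(scope="session")
def tiny_manifests():
    """Two identical tiny runs plus one without the GSP stage."""
    m1 = run_pipeline(tiny_run_config(seed=5))
    m2 = run_pipeline(tiny_run_config(seed=5))
    m3 = run_pipeline(tiny_run_config(seed=5, gsp=False))
    return m1, m2, m3


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    A = rng.random((n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return A
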
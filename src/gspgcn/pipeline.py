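"""End-to-end orchestration: one reproducible run from a config.

A single global seed fans out to stage-specific seeds by stable hashing of
the stage name, so re-running with the same config reproduces every artifact
hash bit-for-bit, and toggling one stage does not perturb another's draws.

The graph-signal-processing (GSP) stage — network alignment plus the sparse
self-expressive reweighting — is executed per cross-validation fold using
group information from the training split only, so no label information
leaks into held-out subjects.  With the stage disabled the classifier runs
directly on each subject's own multi-hop connectivity graph (the ablation
mirroring the with/without-GSP model comparison).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import alignment, chebnet, connectivity, interpret, microstates, preprocess, sparse_graph, voting
from .containers import ERP
from .errors import InvalidArgumentError
from .montage import generate_montage
from .synthetic import CohortConfig, p2_target_channels, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ablation_report", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _hash_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(np.asarray(a, float))
        h.update(str(a.shape).encode())
        h.update(np.round(a, 10).tobytes())
    return h.hexdigest()


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (1.0, 20.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    p2p_threshold: float | None = None


@dataclass
class ConnectivityConfig:
    method: str = "pcc"
    band: tuple[float, float] = (4.0, 12.0)
    k1: int = 1
    k2: int = 8


@dataclass
class AlignConfig:
    alpha: float = 0.5
    tol: float = 1e-8
    max_iter: int = 10_000


@dataclass
class SparseConfig:
    lambdas: tuple[float, float, float, float] = (0.1, 0.01, 0.1, 0.01)
    tol: float = 1e-5
    max_iter: int = 100


@dataclass
class TrainConfig:
    K1: int = 3
    K2: int = 3
    folds: int = 5
    lr: float = 1e-3
    epochs: int = 60
    dropout: float = 0.35
    weight_decay: float = 1e-3


@dataclass
class MicrostateConfig:
    k_min: int = 2
    k_max: int = 10
    n_init: int = 50
    min_duration_ms: float = 10.0


@dataclass
class VoteConfig:
    repeats: int = 100
    draw: int = 10


@dataclass
class StageToggles:
    gsp: bool = True
    saliency: bool = True
    microstates: bool = True
    vote: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    sparse: SparseConfig = field(default_factory=SparseConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    microstates: MicrostateConfig = field(default_factory=MicrostateConfig)
    vote: VoteConfig = field(default_factory=VoteConfig)
    stages: StageToggles = field(default_factory=StageToggles)

    # -- strict (de)serialization --------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _dataclass_from_dict(cls, d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_plain(self.to_dict()), f, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _dataclass_from_dict(cls, d: dict):
    if not isinstance(d, dict):
        raise InvalidArgumentError(f"expected a mapping for {cls.__name__}, got {type(d).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise InvalidArgumentError(
            f"unknown key(s) {sorted(unknown)} for {cls.__name__}; "
            f"valid keys: {sorted(fields)}"
        )
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        target = _nested_dataclass(cls, name)
        if target is not None:
            kwargs[name] = _dataclass_from_dict(target, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


_NESTED = {
    "cohort": CohortConfig,
    "preprocess": PreprocessConfig,
    "connectivity": ConnectivityConfig,
    "align": AlignConfig,
    "sparse": SparseConfig,
    "train": TrainConfig,
    "microstates": MicrostateConfig,
    "vote": VoteConfig,
    "stages": StageToggles,
}


def _nested_dataclass(cls, name: str):
    if cls is RunConfig:
        return _NESTED.get(name)
    return None


# ---------------------------------------------------------------------------
# pipeline


def _fold_gsp(
    graphs, erps, train_idx, cfg: RunConfig
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Per-fold GSP: iNEAT alignment with a training-split prior, then the
    sparse-graph common adjacency fitted on training subjects.

    Returns (per-subject permutations, common adjacency, reorganized Ws).
    """
    labels = np.array([g.group_label for g in graphs])
    tr_mask = np.zeros(len(graphs), bool)
    tr_mask[train_idx] = True
    mean0 = np.mean([graphs[i].A2 for i in train_idx if labels[i] == 0], axis=0)
    mean1 = np.mean([graphs[i].A2 for i in train_idx if labels[i] == 1], axis=0)
    _, h = alignment.build_prior(mean0, mean1)
    perms, Ws = [], []
    for g in graphs:
        res = alignment.align_graphs(
            g.A1, g.A2, h, alpha=cfg.align.alpha, tol=cfg.align.tol,
            max_iter=cfg.align.max_iter,
        )
        perms.append(res.P)
        Ws.append(alignment.reorganize_channels(g.W, res.P))
    n_ch = graphs[0].W.shape[0]
    # sparse fit runs on the training subjects' aligned trial-averaged signals
    signals = np.stack([perms[i] @ erps[i].data for i in train_idx])
    models = sparse_graph.fit_all_electrodes(
        signals,
        lambdas=cfg.sparse.lambdas,
        groups=labels[train_idx],
        tol=cfg.sparse.tol,
        max_iter=cfg.sparse.max_iter,
    )
    common_A = sparse_graph.apply_sparse_graph(models, n_ch)
    if common_A.max() == 0.0:
        logger.warning("sparse graph pruned every edge; falling back to mean adjacency")
        common_A = np.mean([graphs[i].A2 for i in train_idx], axis=0)
    return perms, common_A, Ws


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages; returns the run manifest."""
    t_start = time.time()
    manifest: dict = {
        "config": _plain(cfg.to_dict()),
        "seed": cfg.seed,
        "stages": {},
        "hashes": {},
        "metrics": {},
    }
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _record(stage: str, t0: float, **hashes) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        manifest["hashes"].update(hashes)

    # -- simulate -------------------------------------------------------
    t0 = time.time()
    montage = generate_montage(64)
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=stage_seed(cfg.seed, "simulate"))
    epoch_sets, labels = simulate_cohort(cohort_cfg, montage)
    _record("simulate", t0, cohort=_hash_array(*[e.data for e in epoch_sets]))

    # -- preprocess -----------------------------------------------------
    t0 = time.time()
    results = [
        preprocess.preprocess_epochs(
            es, montage, band=cfg.preprocess.band,
            baseline_window_ms=cfg.preprocess.baseline_window_ms,
            p2p_threshold=cfg.preprocess.p2p_threshold,
        )
        for es in epoch_sets
    ]
    clean = [r.epochs for r in results]
    erps = [r.erp for r in results]
    _record("preprocess", t0, erps=_hash_array(*[e.data for e in erps]))

    # -- connectivity ---------------------------------------------------
    t0 = time.time()
    graphs = [
        connectivity.build_graph(
            es, method=cfg.connectivity.method, band=cfg.connectivity.band,
            k1=cfg.connectivity.k1, k2=cfg.connectivity.k2,
        )
        for es in clean
    ]
    trial_ws = [
        connectivity.pcc_matrix(
            connectivity.narrowband(es, cfg.connectivity.band), aggregate="trial"
        )
        if cfg.connectivity.method == "pcc"
        else connectivity.plv_matrix(
            connectivity.narrowband(es, cfg.connectivity.band), aggregate="trial"
        )
        for es in clean
    ]
    _record("connectivity", t0, connectivity=_hash_array(*[g.W for g in graphs]))

    # -- cross-validated training (GSP folded inside) -------------------
    t0 = time.time()
    from sklearn.model_selection import StratifiedKFold

    tr_seed = stage_seed(cfg.seed, "train")
    skf = StratifiedKFold(n_splits=cfg.train.folds, shuffle=True, random_state=tr_seed)
    fold_metrics = []
    fold_rows = []
    node_saliency = []
    trial_label_pools: dict[str, np.ndarray] = {}
    mean_A2 = np.mean([g.A2 for g in graphs], axis=0)
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        if cfg.stages.gsp:
            perms, conv_A, _ = _fold_gsp(graphs, erps, tr, cfg)
        else:
            perms = [np.eye(graphs[0].W.shape[0])] * len(graphs)
            conv_A = None
        trial_sets = []
        for i, g in enumerate(graphs):
            A_i = conv_A if conv_A is not None else g.A2
            tmpl = chebnet.prepare_subject(
                A_i, g.W, cfg.train.K1, cfg.train.K2, subject_id=g.subject_id
            )
            X_t = np.einsum("nm,tmp,qp->tnq", perms[i], trial_ws[i], perms[i])
            trial_sets.append(
                chebnet.TrialSet(template=tmpl, X=X_t, label=int(labels[i]),
                                 subject_id=g.subject_id)
            )
        if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
            raise InvalidArgumentError(f"fold {fold_i} lost a class")
        scaler = chebnet.TrialScaler.fit([trial_sets[i] for i in tr])
        model, _ = chebnet.train_trial_model(
            [trial_sets[i] for i in tr],
            K1=cfg.train.K1, K2=cfg.train.K2, lr=cfg.train.lr,
            epochs=cfg.train.epochs, dropout=cfg.train.dropout,
            weight_decay=cfg.train.weight_decay, scaler=scaler,
            seed=tr_seed + fold_i,
        )
        te_probs = np.stack(
            [chebnet.predict_subject_proba(model, trial_sets[i], scaler)[0]
             for i in te]
        )
        m = chebnet.evaluate(te_probs, labels[te])
        fold_metrics.append(m)
        fold_rows.append(
            {k: m[k] for k in ("ACC", "AUC", "sensitivity", "specificity")}
        )
        # per-trial hard labels for the held-out subjects (voting pool)
        if cfg.stages.vote:
            for i in te:
                _, tls = chebnet.predict_subject_proba(model, trial_sets[i], scaler)
                trial_label_pools[graphs[i].subject_id] = tls
        if cfg.stages.saliency:
            sal_inputs = [
                dataclasses.replace(
                    trial_sets[i].template,
                    X=scaler.transform(trial_sets[i].X).mean(axis=0),
                )
                for i in te
            ]
            sal = interpret.cohort_saliency(
                model, sal_inputs, labels[te],
                adjacency=conv_A if conv_A is not None else mean_A2,
                class_index=0,
            )
            node_saliency.append(sal.node_scores)
    acc = np.array([m["ACC"] for m in fold_metrics])
    manifest["metrics"]["cv"] = {
        "per_fold": fold_rows,
        "mean_ACC": float(acc.mean()),
        "mean_AUC": float(np.mean([m["AUC"] for m in fold_metrics])),
        "mean_sensitivity": float(np.mean([m["sensitivity"] for m in fold_metrics])),
        "mean_specificity": float(np.mean([m["specificity"] for m in fold_metrics])),
    }
    _record("train", t0, cv_acc=_hash_array(acc))

    # -- saliency -------------------------------------------------------
    if cfg.stages.saliency:
        t0 = time.time()
        mean_sal = np.mean(node_saliency, axis=0)
        if mean_sal.max() > 0:
            mean_sal = mean_sal / mean_sal.max()
        manifest["metrics"]["saliency"] = {
            "top_nodes": [int(i) for i in np.argsort(-mean_sal)[:10]],
            "planted_channels": [int(i) for i in p2_target_channels(montage)],
        }
        _record("saliency", t0, saliency=_hash_array(mean_sal))
        if out_dir:
            interpret.plot_topomap(mean_sal, montage.positions, str(out_dir / "saliency.png"))

    # -- microstates ----------------------------------------------------
    if cfg.stages.microstates:
        t0 = time.time()
        grand: list[ERP] = []
        for grp in (0, 1):
            members = [e for e, lab in zip(erps, labels) if lab == grp]
            grand.append(
                ERP(
                    data=np.mean([e.data for e in members], axis=0),
                    fs=members[0].fs,
                    window_ms=members[0].window_ms,
                    n_trials_used=len(members),
                    channel_labels=members[0].channel_labels,
                    subject_id=f"grand_group{grp}",
                    group_label=grp,
                )
            )
        ms = microstates.microstate_analysis(
            grand,
            k_range=(cfg.microstates.k_min, cfg.microstates.k_max),
            n_init=cfg.microstates.n_init,
            seed=stage_seed(cfg.seed, "microstates"),
            min_duration_ms=cfg.microstates.min_duration_ms,
        )
        manifest["metrics"]["microstates"] = {
            "chosen_k": ms.chosen_k,
            "coverage_group0": _plain(ms.coverage_per_erp[0]),
            "coverage_group1": _plain(ms.coverage_per_erp[1]),
        }
        _record("microstates", t0, microstate_templates=_hash_array(ms.templates))

    # -- posterior voting ----------------------------------------------
    if cfg.stages.vote:
        t0 = time.time()
        sids = [g.subject_id for g in graphs]
        pools = [trial_label_pools[s] for s in sids]
        vote_res = voting.posterior_verify(
            pools, labels, repeats=cfg.vote.repeats, draw=cfg.vote.draw,
            seed=stage_seed(cfg.seed, "vote"),
        )
        manifest["metrics"]["vote"] = {
            "mean_accuracy": vote_res["mean_accuracy"],
            "var_accuracy": vote_res["var_accuracy"],
        }
        _record("vote", t0, vote=_hash_array(vote_res["per_repetition"]))

    manifest["wall_seconds"] = round(time.time() - t_start, 3)
    if out_dir:
        with open(out_dir / "manifest.json", "w") as f:
            json.dump(_plain(manifest), f, indent=2)
    return manifest


def ablation_report(manifest_with: dict, manifest_without: dict) -> dict:
    """Metric deltas (with-GSP minus without) plus Mann-Whitney p-values on
    the per-fold distributions, Bonferroni-corrected across metrics."""
    cv_a, cv_b = manifest_with["metrics"]["cv"], manifest_without["metrics"]["cv"]
    if len(cv_a["per_fold"]) != len(cv_b["per_fold"]):
        raise InvalidArgumentError("fold counts differ between the two runs")
    metrics = ("ACC", "AUC", "sensitivity", "specificity")
    report: dict = {"delta": {}, "p_value": {}}
    from scipy import stats

    for met in metrics:
        va = np.array([f[met] for f in cv_a["per_fold"]])
        vb = np.array([f[met] for f in cv_b["per_fold"]])
        report["delta"][met] = float(va.mean() - vb.mean())
        if np.array_equal(va, vb):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        report["p_value"][met] = min(1.0, p * len(metrics))
    return report
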
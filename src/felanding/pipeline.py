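"""End-to-end orchestration: simulate -> preprocess -> inverse dynamics ->
PCA -> train -> LRP -> metrics.

The pipeline mirrors the two-branch study design.  Branch one runs PCA on the
normalized GRF and joint-angle curves per height and variable, reconstructs
the principal waveforms and extracts the endpoint (maximum-elbow-flexion)
values — the hand-off table a structural analysis would consume.  Branch two
runs inverse dynamics to complete the angle+moment trial rows, assembles the
per-height matrices and the labeled adjacent-height pairs, trains one
classifier per pair, evaluates it, and explains it with layer-wise relevance
propagation.

Everything is a pure function of the config: one global seed derives the
generator, initialization and shuffle seeds, and the run manifest records a
SHA-256 hash of every numeric artifact so reruns can be compared byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from . import signal_prep, synthetic
from .dnn import NetworkConfig, TrainConfig, TrainedNetwork, predict, scaled_down_config, split_dataset, train
from .exceptions import ConfigurationError, FelandingError
from .inverse_dynamics import moments_to_trajectories, trial_joint_loads
from .lrp import RelevanceMap, relevance_analysis
from .metrics import compute_metrics, from_predictions
from .pca_waveform import principal_waveform
from .signal_prep import (HeightDataset, NormalizedTrial, PRE_DYNAMICS_CURVES,
                          build_height_dataset, build_pair_dataset)
from .synthetic import GeneratorConfig, generate_cohort, planted_truth


@dataclass(frozen=True)
class PipelineConfig:
    """Nested per-stage configuration plus a single global seed.

    The global seed overrides the per-stage seeds at run time (generator seed,
    weight-initialization seed, split/shuffle seed), so a run is reproducible
    from this object alone.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grf_filter: signal_prep.FilterSpec = signal_prep.GRF_FILTER
    angle_filter: signal_prep.FilterSpec = signal_prep.ANGLE_FILTER
    pca_threshold: float = 0.90
    network: NetworkConfig = field(default_factory=scaled_down_config)
    training: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=300))
    lrp_top_k: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pca_threshold <= 1:
            raise ConfigurationError("pca_threshold must lie in (0, 1]")
        if self.lrp_top_k <= 0:
            raise ConfigurationError("lrp_top_k must be positive")


@dataclass
class PairResult:
    pair_id: str
    heights: tuple[int, int]
    network: TrainedNetwork
    test_metrics: dict
    confusion: tuple[int, int, int, int]
    relevance: RelevanceMap


@dataclass
class PipelineResult:
    config: PipelineConfig
    height_datasets: dict[int, HeightDataset]
    pca_endpoints: dict[int, dict[str, float]]
    pca_first_component: dict[int, dict[str, float]]
    pairs: dict[str, PairResult]
    manifest: dict


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def derive_seeds(seed: int) -> dict[str, int]:
    """Three independent 31-bit sub-seeds from the global seed."""
    children = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    return {"generator": int(children[0]), "init": int(children[1]),
            "shuffle": int(children[2])}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute both branches; abort with the stage name on any failure."""
    seeds = derive_seeds(config.seed)
    gen_cfg = replace(config.generator, seed=seeds["generator"])
    manifest: dict = {"seed": config.seed, "sub_seeds": seeds, "stages": {}}

    def stage(name):
        manifest["stages"][name] = entry = {"t_start": time.time()}
        return entry

    def fail(name, err):
        raise FelandingError(f"pipeline stage '{name}' failed: {err}") from err

    # --- simulate ---------------------------------------------------------
    entry = stage("simulate")
    try:
        cohort = generate_cohort(gen_cfg)
    except FelandingError as err:
        fail("simulate", err)
    entry["n_trials"] = {h: len(ts) for h, ts in cohort.items()}
    entry["planted_truth"] = {f"{a}-{b}": w for (a, b), w in planted_truth(gen_cfg).items()}

    # --- preprocess + inverse dynamics ------------------------------------
    entry = stage("preprocess+inverse_dynamics")
    height_datasets: dict[int, HeightDataset] = {}
    pre_dynamics: dict[int, list[NormalizedTrial]] = {}
    try:
        for h, trials in cohort.items():
            normalized_rows = []
            pre_dynamics[h] = []
            for tr in trials:
                trimmed, norm_pre = signal_prep.preprocess_trial(
                    tr, config.grf_filter, config.angle_filter)
                pre_dynamics[h].append(norm_pre)
                loads = trial_joint_loads(trimmed)
                curves = {k: norm_pre.curves[k] for k in
                          ("wrist_angle", "elbow_angle", "shoulder_angle")}
                curves.update(moments_to_trajectories(loads))
                normalized_rows.append(NormalizedTrial(
                    cat_id=tr.cat_id, height_cm=h, trial_index=tr.trial_index,
                    curves=curves))
            height_datasets[h] = build_height_dataset(normalized_rows, h)
    except FelandingError as err:
        fail("preprocess+inverse_dynamics", err)
    entry["dataset_hashes"] = {h: _hash(ds.matrix) for h, ds in height_datasets.items()}
    entry["dataset_shapes"] = {h: list(ds.matrix.shape) for h, ds in height_datasets.items()}

    # --- PCA branch --------------------------------------------------------
    entry = stage("pca")
    endpoints: dict[int, dict[str, float]] = {}
    g1: dict[int, dict[str, float]] = {}
    try:
        for h in gen_cfg.heights:
            endpoints[h] = {}
            g1[h] = {}
            for var in PRE_DYNAMICS_CURVES:
                # phase points as observations (n=100 rows), trials as columns
                X = np.column_stack([nt.curves[var] for nt in pre_dynamics[h]])
                wf, result, m = principal_waveform(X, config.pca_threshold)
                endpoints[h][var] = wf.endpoint
                g1[h][var] = float(result.contribution[0])
    except FelandingError as err:
        fail("pca", err)
    entry["endpoints"] = {h: dict(v) for h, v in endpoints.items()}
    entry["first_pc_contribution"] = {h: dict(v) for h, v in g1.items()}

    # --- pairs: train, evaluate, explain -----------------------------------
    pairs: dict[str, PairResult] = {}
    heights = gen_cfg.heights
    for i, (lo, hi) in enumerate(zip(heights, heights[1:]), start=1):
        pair_id = f"M{i}"
        entry = stage(f"pair_{pair_id}")
        try:
            pair = build_pair_dataset(height_datasets[lo], height_datasets[hi], pair_id)
            ncfg = replace(config.network, init_seed=seeds["init"] + i)
            tcfg = replace(config.training, shuffle_seed=seeds["shuffle"] + i)
            train_idx, test_idx = split_dataset(pair, tcfg)
            net = train(pair, ncfg, tcfg, train_idx, test_idx)
            X_test, y_test = pair.matrix[test_idx], pair.labels[test_idx]
            pred, correct = predict(net, X_test, y_test)
            cm = from_predictions(y_test, pred, positive=1)
            bundle = compute_metrics(cm)
            # relevance is aggregated over every correctly classified trial of
            # the pair, not just the held-out ones: the attribution describes
            # the fitted decision function, and more trials stabilize the map
            rel = relevance_analysis(net, pair.matrix, pair.labels,
                                     pair_id=pair_id, k=config.lrp_top_k)
        except FelandingError as err:
            fail(f"pair_{pair_id}", err)
        pairs[pair_id] = PairResult(
            pair_id=pair_id, heights=(lo, hi), network=net,
            test_metrics={k: getattr(bundle, k) for k in
                          ("accuracy", "sensitivity", "specificity", "precision",
                           "f1", "tpr", "fpr", "auc", "mcc")},
            confusion=(cm.tp, cm.fn, cm.tn, cm.fp), relevance=rel)
        entry.update({
            "heights": [lo, hi],
            "confusion": [cm.tp, cm.fn, cm.tn, cm.fp],
            "accuracy": bundle.accuracy,
            "weight_hash": _hash(np.concatenate([w.ravel() for w in net.weights])),
            "trajectory_pct": pairs[pair_id].relevance.trajectory_pct,
            "joint_pct": pairs[pair_id].relevance.joint_pct,
        })

    for e in manifest["stages"].values():
        e["wall_s"] = round(time.time() - e.pop("t_start"), 3)
    return PipelineResult(config=config, height_datasets=height_datasets,
                          pca_endpoints=endpoints, pca_first_component=g1,
                          pairs=pairs, manifest=manifest)


def manifest_fingerprint(manifest: dict) -> str:
    """Hash of the manifest's numeric content (wall times excluded)."""

    def scrub(obj):
        if isinstance(obj, dict):
            return {k: scrub(v) for k, v in sorted(obj.items()) if k != "wall_s"}
        if isinstance(obj, (list, tuple)):
            return [scrub(v) for v in obj]
        if isinstance(obj, float):
            return repr(obj)
        return obj

    blob = json.dumps(scrub(manifest), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_result(result: PipelineResult, out_dir) -> None:
    """Persist the run: height-dataset CSVs, endpoint table, per-pair metrics,
    relevance tables and the manifest (with a frozen config echo)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for h, ds in result.height_datasets.items():
        signal_prep.write_height_dataset(ds, out / f"height_{h}cm.csv")
    with open(out / "pca_endpoints.json", "w") as fh:
        json.dump({"endpoint_at_max_elbow_flexion": result.pca_endpoints,
                   "first_pc_contribution": result.pca_first_component}, fh, indent=2)
    pair_summary = {}
    for pid, pr in result.pairs.items():
        pair_summary[pid] = {
            "heights": list(pr.heights),
            "confusion_tp_fn_tn_fp": list(pr.confusion),
            "metrics": pr.test_metrics,
            "relevance": pr.relevance.summary(),
        }
        np.savetxt(out / f"relevance_{pid}.csv",
                   np.column_stack([pr.relevance.aggregated, pr.relevance.smoothed,
                                    pr.relevance.rescaled, pr.relevance.top_mask]),
                   delimiter=",", header="aggregated,smoothed,rescaled,top100",
                   comments="")
    with open(out / "pairs.json", "w") as fh:
        json.dump(pair_summary, fh, indent=2)
    cfg = asdict(result.config)
    cfg["generator"]["effect_profile"] = {
        f"{a}-{b}": list(w)
        for (a, b), w in result.config.generator.pair_effect_profile().items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cfg, "manifest": result.manifest,
                   "fingerprint": manifest_fingerprint(result.manifest)}, fh, indent=2)
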
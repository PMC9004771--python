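"""End-to-end pipeline wiring: config validation, staging, reports.

Stage order follows the block design of the method: (preprocessed) ROI
time series -> CorrTF features -> t-test selection -> SVM evaluation,
plus the group-level network edge report. The runner is deliberately
thin: every stage is a call into the corresponding module, and all
outputs are deterministic given the config (the metrics JSON is
byte-identical across reruns with the same seed).
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

from . import __version__
from .classify import CLASS_ORDER, crossvalidate
from .features import (
    ConnectivityFeatureMatrix,
    cohort_features,
    write_cohort_features_tsv,
)
from .network import (
    count_network_pairs,
    export_edge_list,
    group_mean_matrix,
    load_network_mapping,
    threshold_edges,
)
from .selection import rank_discriminative, ttest_connections
from .simulate import default_cohort_config, generate_cohort
from .timeseries import write_labels_tsv, write_timeseries_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated knobs for the one-command pipeline run.

    Defaults match the method's stated operating point: 10 discarded
    volumes, 0.01-0.08 Hz passband, p < 0.05 selection, strength
    threshold 0.1, 10 CV folds.
    """

    out_dir: str = "corrtf_out"
    n_per_class: int = 40
    n_rois: int = 16
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    noise_sd: float = 0.1
    passband: tuple = (0.01, 0.08)
    discard_initial: int = 10
    alpha: float = 0.05
    edge_threshold: float = 0.1
    folds: int = 10
    seed: int = 42
    scheme: str = "both"  # hierarchical | flat | both
    svm_c: float = 1.0
    svm_kernel: str = "linear"
    top_k: int = 20
    rank_groups: tuple = ("NC", "AD")

    def __post_init__(self):
        self.passband = tuple(self.passband)
        self.rank_groups = tuple(self.rank_groups)
        low, high = self.passband
        nyq = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < low < high < nyq):
            raise ValueError(
                f"passband {self.passband} invalid for TR={self.tr_seconds}s "
                f"(Nyquist {nyq:.4g} Hz)"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be >= 0")
        if self.scheme not in ("hierarchical", "flat", "both"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for g in self.rank_groups:
            if g not in CLASS_ORDER:
                raise ValueError(f"unknown group {g!r} in rank_groups")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["passband"] = list(self.passband)
        d["rank_groups"] = list(self.rank_groups)
        return d

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> features -> evaluate -> network report; returns the bundle.

    Writes, under ``config.out_dir``: per-subject time-series TSVs, a
    labels TSV, the cohort feature table, metrics.json, pooled confusion
    matrices, the top-k discriminative-edge table, and per-group network
    edge counts plus node/edge lists.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    sim = default_cohort_config(
        n_per_class=config.n_per_class,
        n_rois=config.n_rois,
        n_timepoints=config.n_timepoints,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    cohort = generate_cohort(sim)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    labels = {}
    for sid, label, ts in cohort.subjects:
        write_timeseries_tsv(ts, ts_dir / f"{sid}.tsv")
        labels[sid] = label
    write_labels_tsv(labels, out / "labels.tsv")
    logger.info("simulated %d subjects in %.1fs", len(labels), time.perf_counter() - t0)

    t1 = time.perf_counter()
    ts_list = [ts for _, _, ts in cohort.subjects]
    X, edge_index, roi_ids = cohort_features(ts_list)
    y = np.array([label for _, label, _ in cohort.subjects], dtype=object)
    write_cohort_features_tsv(X, edge_index, list(labels), out / "features.tsv")
    logger.info("CorrTF features %s in %.1fs", X.shape, time.perf_counter() - t1)

    results = {
        "version": __version__,
        "config_hash": config.digest(),
        "config": config.to_dict(),
        "n_subjects": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "schemes": {},
    }
    schemes = ["hierarchical", "flat"] if config.scheme == "both" else [config.scheme]
    for scheme in schemes:
        t2 = time.perf_counter()
        cm, report = crossvalidate(
            X, y, scheme=scheme, k=config.folds, seed=config.seed,
            alpha=config.alpha, C=config.svm_c, kernel=config.svm_kernel,
        )
        cm.to_dataframe().to_csv(out / f"confusion_{scheme}.tsv", sep="\t")
        results["schemes"][scheme] = {
            "pooled_confusion": cm.counts.tolist(),
            "pooled_accuracy": float(np.trace(cm.counts) / cm.total),
            "fold_mean": report.mean,
            "fold_sd": report.sd,
        }
        logger.info("%s CV done in %.1fs", scheme, time.perf_counter() - t2)

    a, b = config.rank_groups
    pvals = ttest_connections(X[y == a], X[y == b], group_a=a, group_b=b)
    pvals.roi_ids = roi_ids
    ranked = rank_discriminative(pvals, k=config.top_k)
    ranked.to_csv(out / f"top_edges_{a}_vs_{b}.tsv", sep="\t", index=False)

    mapping = None
    if config.n_rois == 116:
        mapping = load_network_mapping()
    network_counts = {}
    for group in CLASS_ORDER:
        members = [i for i, lab in enumerate(y) if lab == group]
        if not members:
            continue
        mats = []
        R = config.n_rois
        for i in members:
            m = np.zeros((R, R))
            m[~np.eye(R, dtype=bool)] = X[i]
            mats.append(ConnectivityFeatureMatrix(m, roi_ids=list(roi_ids)))
        gmean = group_mean_matrix(mats)
        edges = threshold_edges(gmean, threshold=config.edge_threshold)
        export_edge_list(
            edges, out / f"nodes_{group}.tsv", out / f"edges_{group}.tsv",
            mapping=mapping,
        )
        network_counts[group] = len(edges)
        if mapping is not None:
            count_network_pairs(edges, mapping).to_csv(
                out / f"network_counts_{group}.tsv", sep="\t"
            )
    results["edges_above_threshold"] = network_counts

    with open(out / "metrics.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return results
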
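"""Experiment orchestration: splits, baselines, ablations and aggregation.

A full run sweeps network models × effective infection rates (multiples of
the per-network threshold λc) × influential fractions f.  For each dataset
it repeats a stratified 70/30 split, runs the two-phase selection on the
training part, and evaluates a linear SVM on the held-out part for:

* each single centrality on its own,
* ``All`` — the full feature set,
* ``Imbalanced`` — SVM-RFE-CV directly on the raw imbalanced training split,
* ``FFS-ReliefF`` — top-|F**| members of F* ranked by ReliefF weight,
* ``FFS-Weight`` — top-|F**| members of F* ranked by vote frequency,
* ``FFS-SFS`` — the two-phase subset F**,

plus two ablations: ``wo_SFS`` (evaluate F*) and ``wo_FFS`` (run the
redundancy-removal phase directly on the full feature set).  Repeat-level
subsets are aggregated by mode per network, and network-level modes are
voted per model.
"""

from __future__ import annotations

import time
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .centrality import TABLE_ORDER, CentralityConfig, compute_feature_table, canonical_sort
from .epidemic import EpidemicConfig, estimate_threshold, influence_scores, label_top_f
from .netgen import GeneratorSpec, from_spec
from .selection_initial import LabeledDataset, svm_rfe_cv
from .selection_secondary import (SelectionConfig, SelectionResult,
                                  relieff_weights, secondary_selection,
                                  two_phase_select)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ConfusionCounts", "split_dataset", "confusion_metrics",
           "evaluate_subset", "run_contrast", "run_ablation", "aggregate_mode",
           "build_dataset", "run_experiment"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class ExperimentConfig:
    """Sweep definition mirroring the study design.

    The ``full scale`` preset is N=1000, ⟨k⟩=6, 10 networks/model, 1000 SIR
    runs per node and 30 split repeats; the default here is a reduced
    profile (N=300, 5 networks, 200 runs, 10 repeats) that exercises the
    identical code path at a fraction of the cost.
    """

    models: list[str] = field(default_factory=lambda: ["BA", "ER", "WS"])
    n: int = 300
    avg_degree: float = 6.0
    rewire_p: float = 0.2
    lambda_multipliers: list[float] = field(default_factory=lambda: [0.5, 1.0, 1.5])
    f_values: list[float] = field(default_factory=lambda: [0.05, 0.10, 0.15, 0.20])
    train_fraction: float = 0.7
    repeats: int = 10
    n_networks: int = 5
    sir_runs: int = 200
    threshold_runs: int = 300
    master_seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    @classmethod
    def full_scale(cls, **overrides) -> "ExperimentConfig":
        base = dict(n=1000, repeats=30, n_networks=10, sir_runs=1000)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = SelectionConfig(**d["selection"])
        return cls(**d)


def split_dataset(
    data: LabeledDataset, train_fraction: float, rng: np.random.Generator
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split preserving the class ratio.

    Stratification matters at small f: an unstratified 30% test draw can
    lose every positive, leaving precision/recall undefined.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_neg, n_pos = np.sum(data.y == -1), np.sum(data.y == 1)
    if min(n_neg, n_pos) < 2:
        raise ValueError("each class needs >= 2 members to appear in both parts")
    idx_train, idx_test = train_test_split(
        np.arange(data.n), train_size=train_fraction, stratify=data.y,
        random_state=int(rng.integers(2**31)),
    )
    def take(idx):
        return LabeledDataset(data.X.iloc[idx].reset_index(drop=True),
                              data.y[idx], dict(data.provenance))
    return take(idx_train), take(idx_test)


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from confusion counts.

    Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean;
    an empty denominator yields 0 with a warning rather than NaN.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0 or tp + fn == 0:
        logger.warning("degenerate confusion counts %s; metric defined as 0", counts)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 / (1 / precision + 1 / recall) if precision > 0 and recall > 0 else 0.0
    return precision, recall, f1


def evaluate_subset(
    train: LabeledDataset,
    test: LabeledDataset,
    subset: list[str],
    C: float = 1.0,
    class_weight: str | None = "balanced",
) -> dict:
    """Fit a linear SVM on the training split restricted to *subset* and
    score the held-out split.

    Features are standardised with training statistics; the classifier is
    class-weighted by default to cope with the top-f imbalance of the raw
    split.  Returns confusion counts and precision/recall/F1.
    """
    subset = list(subset)
    if not subset or not set(subset) <= set(train.feature_names):
        raise ValueError(f"invalid feature subset {subset}")
    scaler = StandardScaler().fit(train.X[subset].to_numpy())
    clf = SVC(kernel="linear", C=C, class_weight=class_weight)
    clf.fit(scaler.transform(train.X[subset].to_numpy()), train.y)
    pred = clf.predict(scaler.transform(test.X[subset].to_numpy()))
    y = test.y
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == -1))),
        fn=int(np.sum((pred == -1) & (y == 1))),
        tn=int(np.sum((pred == -1) & (y == -1))),
    )
    precision, recall, f1 = confusion_metrics(counts)
    return {"subset": subset, "size": len(subset), "counts": asdict(counts),
            "precision": precision, "recall": recall, "f1": f1}


def run_contrast(
    train: LabeledDataset,
    test: LabeledDataset,
    selection: SelectionResult,
    cfg: SelectionConfig,
    rng: np.random.Generator,
) -> dict[str, dict]:
    """Evaluate the selected subset against the 13 contrast methods.

    The two phase-2 alternatives (ReliefF ranking, vote-frequency ranking)
    are truncated to |F**| so that only the selection criterion differs.
    """
    rows: dict[str, dict] = {}
    for feat in train.feature_names:
        rows[feat] = evaluate_subset(train, test, [feat], C=cfg.C)
    rows["All"] = evaluate_subset(train, test, train.feature_names, C=cfg.C)

    imb = svm_rfe_cv(train, folds=cfg.folds, C=cfg.C, rng=rng)
    rows["Imbalanced"] = evaluate_subset(train, test, imb.best_subset, C=cfg.C)

    f_star, f_dd = selection.f_star, selection.f_double_star
    target = max(1, len(f_dd))
    weights = (selection.relieff if selection.relieff is not None
               else relieff_weights(train, features=f_star, k_neighbors=cfg.relieff_k))
    order = {f: i for i, f in enumerate(TABLE_ORDER)}
    by_relieff = sorted(f_star, key=lambda f: (-weights[f], order.get(f, 99), f))[:target]
    freq = selection.vote.frequencies
    by_freq = sorted(f_star, key=lambda f: (-freq.get(f, 0.0), order.get(f, 99), f))[:target]
    rows["FFS-ReliefF"] = evaluate_subset(train, test, canonical_sort(by_relieff), C=cfg.C)
    rows["FFS-Weight"] = evaluate_subset(train, test, canonical_sort(by_freq), C=cfg.C)
    rows["FFS-SFS"] = evaluate_subset(train, test, f_dd, C=cfg.C)
    return rows


def run_ablation(
    train: LabeledDataset,
    test: LabeledDataset,
    selection: SelectionResult,
    cfg: SelectionConfig,
) -> dict[str, dict]:
    """Single-phase ablations: F* alone (wo_SFS) and the redundancy phase
    applied straight to the full feature set (wo_FFS)."""
    rows = {"wo_SFS": evaluate_subset(train, test, selection.f_star, C=cfg.C)}
    final, _, _, _ = secondary_selection(train, train.feature_names, cfg)
    rows["wo_FFS"] = evaluate_subset(train, test, final.f_double_star, C=cfg.C)
    return rows


def aggregate_mode(subsets: list[list[str]]) -> list[str]:
    """Most frequent subset; ties prefer the smaller, then the subset that
    sorts first in canonical column order."""
    if not subsets:
        raise ValueError("need at least one subset")
    order = {f: i for i, f in enumerate(TABLE_ORDER)}
    keys = [tuple(canonical_sort(s)) for s in subsets]
    counts: dict[tuple, int] = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    best = min(counts, key=lambda s: (-counts[s], len(s),
                                      tuple(order.get(f, 99) for f in s), s))
    return list(best)


def build_dataset(net, feature_table, labeled_scores) -> LabeledDataset:
    """Assemble the classification dataset from a feature table and labels."""
    return LabeledDataset(
        feature_table.values.reset_index(drop=True),
        labeled_scores.labels,
        {"network": net.name, "lambda": labeled_scores.lambda_used,
         "f": labeled_scores.f},
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full sweep; returns a JSON-serialisable report.

    The report holds, per model / network / (λ-multiplier, f): the λc scan
    result, per-repeat F** subsets and metrics for every method, the modal
    subset per network, and the across-network vote per model.  Everything
    is derived deterministically from ``config.master_seed``.
    """
    report: dict = {"config": _config_dict(config), "models": {}}
    for mi, model in enumerate(config.models):
        model_entry: dict = {"networks": [], "model_vote": {}}
        per_cell_modals: dict[str, list[list[str]]] = {}
        for ni in range(config.n_networks):
            t0 = time.time()
            spec = GeneratorSpec(model=model, n=config.n, avg_degree=config.avg_degree,
                                 rewire_p=config.rewire_p,
                                 seed=int(1_000_000 * mi + 1_000 * ni + config.master_seed))
            net = from_spec(spec)
            table = compute_feature_table(net, CentralityConfig())
            scan = estimate_threshold(net, runs_per_lambda=config.threshold_runs,
                                      master_seed=config.master_seed + ni)
            net_entry: dict = {"name": net.name, "n_nodes": net.n_nodes,
                               "n_edges": net.n_edges, "lambda_c": scan.lambda_c,
                               "dropped_features": table.dropped, "cells": {}}
            for li, mult in enumerate(config.lambda_multipliers):
                lam = min(mult * scan.lambda_c, 1.0)
                scores = influence_scores(net, lam, EpidemicConfig(
                    beta=lam, runs=config.sir_runs,
                    master_seed=config.master_seed + 7919 * li + ni))
                for fi, f in enumerate(config.f_values):
                    labeled = label_top_f(scores, f, net)
                    data = build_dataset(net, table, labeled)
                    cell_key = f"lambda={mult}x,f={f}"
                    cell: dict = {"lambda": lam, "f": f, "repeats": []}
                    subsets = []
                    for rep in range(config.repeats):
                        rng = np.random.default_rng(np.random.SeedSequence(
                            [config.master_seed, mi, ni, li, fi, rep]))
                        train, test = split_dataset(data, config.train_fraction, rng)
                        sel = two_phase_select(train, config.selection, rng)
                        contrast = run_contrast(train, test, sel, config.selection, rng)
                        ablation = run_ablation(train, test, sel, config.selection)
                        subsets.append(sel.f_double_star)
                        cell["repeats"].append({
                            "f_star": sel.f_star, "f_double_star": sel.f_double_star,
                            "contrast": contrast, "ablation": ablation,
                        })
                    cell["modal_subset"] = aggregate_mode(subsets)
                    per_cell_modals.setdefault(cell_key, []).append(cell["modal_subset"])
                    net_entry["cells"][cell_key] = cell
            model_entry["networks"].append(net_entry)
            logger.info("%s network %d/%d done in %.1fs", model, ni + 1,
                        config.n_networks, time.time() - t0)
        model_entry["model_vote"] = {cell: aggregate_mode(modals)
                                     for cell, modals in per_cell_modals.items()}
        report["models"][model] = model_entry
    return report


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return d
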
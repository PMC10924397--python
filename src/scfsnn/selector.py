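"""End-to-end backward feature selection with FDR control.

One run proceeds as follows: genes with too many zero counts are filtered;
cells are split (stratified) into 64% training, 16% validation, 20% test;
the normalization is fitted on training cells only; q = floor(p/2) surrogate
null features are injected; the training block is augmented with convex
pseudodata; a fully connected network is trained on all p + q features for
30 epochs; the null count p0 is estimated from the importance scores; then
the loop alternates between scoring features on the validation set,
estimating the FDR of the surviving original features, deleting the
lowest-scoring features, and training a few more epochs — until the
estimated FDR drops to the target eta_star.  A fresh final model is then
trained on the selected genes and evaluated once on the untouched test set.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import component_rng
from .augment import CpdConfig, cpd_augment
from .fdr import FdrState, elimination_count, estimate_fdr, estimate_p0, should_stop
from .importance import importance_scores
from .network import DenseClassifier, NetConfig
from .preprocess import (
    CountMatrix,
    Labels,
    apply_normalize,
    filter_genes,
    fit_normalize,
)
from .simulate import SimParams, empirical_fdr, empirical_power, simulate_counts
from .surrogate import attach_surrogates, default_q, make_surrogates

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SelectionResult", "split_data", "run_scfsnn", "benchmark"]


@dataclass
class RunConfig:
    """All knobs of one selection run, with the protocol defaults."""

    train_frac: float = 0.64
    val_frac: float = 0.16
    test_frac: float = 0.20
    max_zero_fraction: float = 0.8
    eta_star: float = 0.1
    epsilon: float = 0.1
    p0_mode: str = "estimated"  # or "equal_p"
    recompute_p0: bool = False
    q: int | None = None  # None -> floor(p / 2)
    surrogate_strategy: str = "pooled"
    net: NetConfig = field(default_factory=NetConfig)
    cpd: CpdConfig = field(default_factory=CpdConfig)
    max_steps: int | None = None  # None -> 10 * p
    final_max_epochs: int = 100
    final_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_frac, self.val_frac, self.test_frac)
        if min(fr) <= 0 or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.p0_mode not in ("estimated", "equal_p"):
            raise ValueError("p0_mode must be 'estimated' or 'equal_p'")
        if not 0 < self.eta_star < 1:
            raise ValueError("eta_star must be in (0, 1)")


@dataclass
class SelectionResult:
    selected_gene_ids: list[str]
    selected_scores: np.ndarray  # final importance scores of the selected genes
    trajectory: pd.DataFrame  # step, r, r0, p0_hat, eta_hat, n_deleted
    final_test_accuracy: float
    n_steps: int
    n_genes_input: int
    stopped_by_safeguard: bool
    config: RunConfig
    seed: int


def split_data(
    n: int,
    fractions: tuple[float, float, float],
    seed: int | np.random.Generator,
    labels: Labels,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified random partition into train/validation/test index arrays.

    Within each class, round(frac * n_class) cells go to validation and test
    and the remainder to training, so overall proportions match the requested
    fractions while every class is represented in every split.
    """
    if n < 3 or n != labels.y.shape[0]:
        raise ValueError("need n >= 3 matching the label vector")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tr, va, te = [], [], []
    for c in range(labels.n_classes):
        idx = np.flatnonzero(labels.y == c)
        idx = rng.permutation(idx)
        n_c = idx.size
        n_va = int(round(fractions[1] * n_c))
        n_te = int(round(fractions[2] * n_c))
        n_tr = n_c - n_va - n_te
        if n_tr < 1:
            raise ValueError(f"class {c} has no training cells under this split")
        if n_va < 1 or n_te < 1:
            raise ValueError(f"class {c} too small to appear in every split (size {n_c})")
        tr.append(idx[:n_tr])
        va.append(idx[n_tr : n_tr + n_va])
        te.append(idx[n_tr + n_va :])
    return (
        np.sort(np.concatenate(tr)),
        np.sort(np.concatenate(va)),
        np.sort(np.concatenate(te)),
    )


def _stratified_holdout(
    labels: Labels, holdout_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two-way stratified split; every class keeps >= 1 member on each side."""
    tr, ho = [], []
    for c in range(labels.n_classes):
        idx = rng.permutation(np.flatnonzero(labels.y == c))
        n_ho = int(round(holdout_frac * idx.size))
        n_ho = min(max(n_ho, 1), idx.size - 1)
        ho.append(idx[:n_ho])
        tr.append(idx[n_ho:])
    return np.sort(np.concatenate(tr)), np.sort(np.concatenate(ho))


def _train_with_early_stopping(
    model: DenseClassifier,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_va: np.ndarray,
    y_va: np.ndarray,
    max_epochs: int,
    patience: int,
) -> DenseClassifier:
    best_loss = math.inf
    best_state: tuple | None = None
    stale = 0
    for _ in range(max_epochs):
        model.fit_epochs(X_tr, y_tr, 1)
        loss = model.mean_loss(X_va, y_va)
        if loss < best_loss - 1e-6:
            best_loss = loss
            best_state = (copy.deepcopy(model.params), copy.deepcopy(model.bn))
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best_state is not None:
        model.params, model.bn = best_state
    return model


def run_scfsnn(counts: CountMatrix, labels: Labels, cfg: RunConfig) -> SelectionResult:
    """Execute the full selection procedure and report the selected genes."""
    seed = cfg.seed
    counts = filter_genes(counts, cfg.max_zero_fraction)

    tr_idx, va_idx, te_idx = split_data(
        counts.n_cells,
        (cfg.train_frac, cfg.val_frac, cfg.test_frac),
        component_rng(seed, "split"),
        labels,
    )
    y_tr, y_va, y_te = (labels.subset(i) for i in (tr_idx, va_idx, te_idx))

    fitted = fit_normalize(counts.subset_cells(tr_idx))
    if len(fitted.gene_ids) != counts.n_genes:  # zero-variance genes dropped during fit
        keep = np.isin(counts.gene_ids, fitted.gene_ids)
        counts = counts.subset_genes(np.flatnonzero(keep))
    X_tr = fitted.values
    X_va = apply_normalize(counts.subset_cells(va_idx), fitted)
    p = X_tr.shape[1]
    q = default_q(p) if cfg.q is None else cfg.q
    if q < 1:
        raise ValueError("need at least one surrogate feature")

    # one sampling run over train+val rows so validation cells have surrogate values
    X_tv = np.vstack([X_tr, X_va])
    S = make_surrogates(X_tv, q, component_rng(seed, "surrogate"), cfg.surrogate_strategy)
    panel_tr = attach_surrogates(X_tr, S[: len(tr_idx)])
    panel_va = attach_surrogates(X_va, S[len(tr_idx) :])
    is_surr = panel_tr.is_surrogate

    X_fit = panel_tr.matrix.astype(np.dtype(cfg.net.dtype))
    y_fit = y_tr
    if cfg.cpd.enabled:
        X_fit, y_fit = cpd_augment(X_fit, y_tr, cfg.cpd, component_rng(seed, "cpd"))
    X_score = panel_va.matrix.astype(np.dtype(cfg.net.dtype))

    model = DenseClassifier(p + q, labels.n_classes, cfg.net, component_rng(seed, "net_init"))
    model.fit_epochs(X_fit, y_fit.y, cfg.net.init_epochs)

    active = np.arange(p + q)
    scores = importance_scores(model, X_score, y_va.y)

    def _p0(sc, act) -> int:
        if cfg.p0_mode == "equal_p":
            return p
        orig = sc.scores[~is_surr[act]]
        surr = sc.scores[is_surr[act]]
        return estimate_p0(orig, surr, p)

    p0_hat = _p0(scores, active)

    max_steps = 10 * p if cfg.max_steps is None else cfg.max_steps
    rows: list[dict] = []
    step = 0
    safeguard = False
    while True:
        r = int(active.size)
        r0 = int(is_surr[active].sum())
        if cfg.recompute_p0 and step > 0:
            p0_hat = _p0(scores, active)
        state = FdrState(r, r0, q, p0_hat, eta_star=cfg.eta_star, epsilon=cfg.epsilon)
        eta_hat = estimate_fdr(state)
        row = {"step": step, "r": r, "r0": r0, "p0_hat": p0_hat, "eta_hat": eta_hat, "n_deleted": 0}
        if should_stop(eta_hat, cfg.eta_star):
            rows.append(row)
            break
        if step >= max_steps:
            safeguard = True
            logger.warning("elimination exceeded %d steps; aborting with current features", max_steps)
            rows.append(row)
            break

        k = elimination_count(eta_hat, cfg.eta_star, cfg.epsilon, r0)
        k = min(k, r - 1)
        order = np.lexsort((active, scores.scores))  # ascending score, ties by feature index
        delete_pos = order[:k]
        keep_pos = np.setdiff1d(np.arange(r), delete_pos)
        if not np.any(~is_surr[active[keep_pos]]):
            # cap: spare the highest-scoring original feature
            orig_pos = np.flatnonzero(~is_surr[active])
            spare = orig_pos[np.argmax(scores.scores[orig_pos])]
            delete_pos = delete_pos[delete_pos != spare]
            keep_pos = np.setdiff1d(np.arange(r), delete_pos)
        row["n_deleted"] = int(delete_pos.size)
        rows.append(row)

        active = active[keep_pos]
        model.drop_features(keep_pos)
        model.fit_epochs(X_fit[:, active], y_fit.y, cfg.net.step_epochs)
        scores = importance_scores(model, X_score[:, active], y_va.y)
        step += 1

    selected = active[~is_surr[active]]
    if selected.size == 0:
        raise RuntimeError("all original features were eliminated")
    selected_scores = scores.scores[~is_surr[active]]

    # final model: fresh net on the selected genes, train+val, internal early stopping
    final_rng = component_rng(seed, "final_model")
    X_tv_sel = np.vstack([X_tr, X_va])[:, selected]
    y_tv = Labels(np.concatenate([y_tr.y, y_va.y]), labels.n_classes)
    in_tr, in_va = _stratified_holdout(y_tv, 0.2, final_rng)
    Xf_tr, yf_tr = X_tv_sel[in_tr], y_tv.subset(in_tr)
    if cfg.cpd.enabled:
        Xf_tr, yf_tr = cpd_augment(
            Xf_tr.astype(np.dtype(cfg.net.dtype)), yf_tr, cfg.cpd, final_rng
        )
    final_model = DenseClassifier(selected.size, labels.n_classes, cfg.net, final_rng)
    _train_with_early_stopping(
        final_model,
        Xf_tr,
        yf_tr.y,
        X_tv_sel[in_va],
        y_tv.subset(in_va).y,
        cfg.final_max_epochs,
        cfg.final_patience,
    )

    # the test set is touched here for the first time, and exactly once
    X_te = apply_normalize(counts.subset_cells(te_idx), fitted)[:, selected]
    pred = final_model.predict_proba(X_te).argmax(axis=1)
    test_acc = float(np.mean(pred == y_te.y))

    return SelectionResult(
        selected_gene_ids=[str(g) for g in np.asarray(fitted.gene_ids)[selected]],
        selected_scores=selected_scores,
        trajectory=pd.DataFrame(rows),
        final_test_accuracy=test_acc,
        n_steps=step,
        n_genes_input=p,
        stopped_by_safeguard=safeguard,
        config=cfg,
        seed=seed,
    )


def benchmark(
    settings: Sequence[dict],
    n_replicates: int,
    cfg: RunConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run simulated replicates per setting and tabulate empirical FDR and power.

    Each entry of ``settings`` is a dict of SimParams overrides (e.g.
    ``{"n_cells": 2000, "n_genes": 10000, "de_prop": 0.05}``).  Means and
    standard errors over replicates are reported per setting, in the style of
    a simulation-study table.
    """
    cfg = cfg or RunConfig()
    records = []
    for si, setting in enumerate(settings):
        fdrs, powers, accs, n_sel = [], [], [], []
        for rep in range(n_replicates):
            sim_rng = component_rng(seed, "sim", extra=si * 10_000 + rep)
            truth = simulate_counts(SimParams(**setting), sim_rng)
            run_seed = int(
                np.random.SeedSequence(seed, spawn_key=(99, si, rep)).generate_state(1)[0]
                % 2**31
            )
            run_cfg = copy.deepcopy(cfg)
            run_cfg.seed = run_seed
            res = run_scfsnn(truth.counts, truth.labels, run_cfg)
            fdrs.append(empirical_fdr(res.selected_gene_ids, truth))
            powers.append(empirical_power(res.selected_gene_ids, truth))
            accs.append(res.final_test_accuracy)
            n_sel.append(len(res.selected_gene_ids))
        def _se(v):
            return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        records.append(
            {
                **setting,
                "n_replicates": n_replicates,
                "fdr_mean": float(np.mean(fdrs)),
                "fdr_se": _se(fdrs),
                "power_mean": float(np.mean(powers)),
                "power_se": _se(powers),
                "accuracy_mean": float(np.mean(accs)),
                "n_selected_mean": float(np.mean(n_sel)),
            }
        )
    return pd.DataFrame(records)
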
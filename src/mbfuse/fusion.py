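"""Multi-block low-level fusion, repeated double CV and permutation tests.

Low-level fusion concatenates data blocks row-wise after dividing each
(preprocessed) block by its own Frobenius norm,

    X_conc = [ X_mb / ‖X_mb‖_F   X_mg / ‖X_mg‖_F ],

so that no block dominates the joint PLS-DA model merely through its scale
or its number of variables.

Model validation follows the repeated double cross-validation (rDCV)
scheme: in every repetition the samples are split into stratified outer
folds; for each outer fold an inner cross-validation on the outer-training
data alone picks the number of latent variables (smallest inner mean
classification error, ties to the smaller model), and a model with that
complexity — with all preprocessing re-estimated inside the fold — predicts
the held-out fold.  Pooled out-of-fold predictions give one set of figures
of merit per repetition, reported as mean ± SD across repetitions.  Feature
stability is assessed through the VIP scores of one refit per repetition;
features with VIP >= 1.15 in at least half the repetitions (both
configurable) form the candidate biomarker set, to be confirmed by
univariate Mann-Whitney tests with Bonferroni correction.

Statistical significance of the figures of merit is established by a
permutation test: class labels are permuted and the whole rDCV figure-of-
merit computation is repeated (at a reduced number of repetitions) to build
the null distribution.  The fold structure and fold-wise preprocessing
depend only on the observed design, not on the permuted labels, and are
therefore computed once and reused across permutations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import (_nipals_pls1, classification_metrics,
                           encode_labels)
from .univariate import adjust_pvalues, mann_whitney

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Frobenius norm & block fusion
# ---------------------------------------------------------------------------

def frobenius_norm(X) -> float:
    """Square root of the sum of squared matrix entries."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix has non-finite entries")
    return float(np.sqrt((X ** 2).sum()))


def _block_matrix(block) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Coerce a block to (values, feature_names, sample_ids-or-None)."""
    if hasattr(block, "feature_ids"):            # FeatureTable
        return block.values, list(block.feature_ids), list(block.sample_ids)
    if isinstance(block, pd.DataFrame):
        return (block.to_numpy(dtype=float), [str(c) for c in block.columns],
                [str(i) for i in block.index])
    X = np.asarray(block, dtype=float)
    if X.ndim != 2:
        raise ValueError("each block must be a 2-D matrix")
    return X, [f"x{j}" for j in range(X.shape[1])], None


def _coerce_blocks(X) -> tuple[dict[str, np.ndarray], list[str],
                               dict[str, slice], list[str] | None]:
    """Normalize input to named blocks sharing an ordered sample index.

    Accepts a single matrix / DataFrame / FeatureTable, or a dict of them
    for multi-block input.  Returns (blocks, feature_names, block_slices,
    sample_ids).  Feature names are prefixed with the block name in the
    multi-block case so they stay unique after concatenation.
    """
    if not isinstance(X, dict):
        X = {"X": X}
    blocks: dict[str, np.ndarray] = {}
    feature_names: list[str] = []
    block_slices: dict[str, slice] = {}
    sample_ids: list[str] | None = None
    n_rows: int | None = None
    start = 0
    multi = len(X) > 1
    for name, blk in X.items():
        mat, feats, sids = _block_matrix(blk)
        if n_rows is None:
            n_rows = mat.shape[0]
        elif mat.shape[0] != n_rows:
            raise ValueError(f"block {name!r} has {mat.shape[0]} rows, expected {n_rows}")
        if sids is not None:
            if sample_ids is None:
                sample_ids = sids
            elif sids != sample_ids:
                raise ValueError(f"block {name!r} sample index differs from the others")
        blocks[name] = mat
        prefix = f"{name}:" if multi else ""
        feature_names.extend(prefix + f for f in feats)
        block_slices[name] = slice(start, start + mat.shape[1])
        start += mat.shape[1]
    return blocks, feature_names, block_slices, sample_ids


@dataclass
class FusedBlockSet:
    """Row-wise concatenation of Frobenius-normalized blocks."""

    X_conc: np.ndarray
    block_slices: dict[str, slice]
    norms: dict[str, float]
    feature_names: list[str]
    sample_ids: list[str] | None = None

    def block(self, name: str) -> np.ndarray:
        return self.X_conc[:, self.block_slices[name]]


def fuse_blocks(blocks: dict, preprocess: str | None = "autoscale") -> FusedBlockSet:
    """Low-level fusion of data blocks.

    Each block is optionally autoscaled (column-wise, within-block), divided
    by its own Frobenius norm, and the results are concatenated row-wise.
    Every scaled block has unit Frobenius norm; the block-to-column map is
    retained so downstream VIPs can be reported per source block.
    """
    if preprocess not in ("autoscale", None):
        raise ValueError(f"preprocess must be 'autoscale' or None, got {preprocess!r}")
    mats, feature_names, block_slices, sample_ids = _coerce_blocks(blocks)
    parts = []
    norms = {}
    for name, mat in mats.items():
        Z = mat
        if preprocess == "autoscale":
            mu = Z.mean(axis=0)
            sd = Z.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            Z = (Z - mu) / sd
        f = frobenius_norm(Z)
        if f == 0:
            raise ValueError(f"block {name!r} is zero after preprocessing")
        norms[name] = f
        parts.append(Z / f)
    return FusedBlockSet(np.hstack(parts), block_slices, norms,
                         feature_names, sample_ids)


# ---------------------------------------------------------------------------
# rDCV configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RDCVConfig:
    """Repeated double cross-validation settings.

    Defaults: 5 outer x 5 inner stratified folds, 20 repetitions, up to 10
    latent variables, VIP threshold 1.15 required in >= 50% of repetitions.
    """

    k_out: int = 5
    k_in: int = 5
    repeats: int = 20
    a_max: int = 10
    vip_threshold: float = 1.15
    vip_consistency: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_out < 2 or self.k_in < 2:
            raise ValueError("k_out and k_in must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.a_max < 1:
            raise ValueError("a_max must be >= 1")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be >= 0")
        if not 0 < self.vip_consistency <= 1:
            raise ValueError("vip_consistency must be in (0, 1]")


@dataclass
class RDCVResult:
    """Per-repetition figures of merit and VIP matrix from an rDCV run."""

    config: RDCVConfig
    classes: tuple
    feature_names: list[str]
    block_slices: dict[str, slice]
    accuracy: np.ndarray          # (R,) percent
    sensitivity: np.ndarray       # (R,)
    specificity: np.ndarray       # (R,)
    chosen_components: np.ndarray  # (R, k_out)
    refit_components: np.ndarray   # (R,)
    vip_matrix: np.ndarray         # (R, p)
    oof_dummy: np.ndarray          # (R, n) continuous out-of-fold predictions

    def mean_sd(self, metric: str) -> tuple[float, float]:
        v = getattr(self, metric)
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    def summary(self) -> dict[str, str]:
        """Figures of merit formatted as 'mean ± SD' percent strings."""
        out = {}
        for m in ("accuracy", "sensitivity", "specificity"):
            mean, sd = self.mean_sd(m)
            out[m] = f"{mean:.1f} ± {sd:.1f}"
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "figures_of_merit": {
                m: {"mean": self.mean_sd(m)[0], "sd": self.mean_sd(m)[1],
                    "per_repeat": getattr(self, m).tolist()}
                for m in ("accuracy", "sensitivity", "specificity")
            },
            "chosen_components": self.chosen_components.tolist(),
            "refit_components": self.refit_components.tolist(),
            "config": {k: getattr(self.config, k) for k in
                       ("k_out", "k_in", "repeats", "a_max", "vip_threshold",
                        "vip_consistency", "seed")},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# fold machinery
# ---------------------------------------------------------------------------

def stratified_fold_ids(labels, k: int, rng: np.random.Generator,
                        require_all_classes: bool = True) -> np.ndarray:
    """Assign samples to k folds, stratified by class label.

    Within each class the (shuffled) members are dealt to folds cyclically,
    so fold class proportions match the data as closely as integer counts
    allow.  With ``require_all_classes`` an error is raised when a class has
    fewer members than folds (some folds would miss it).
    """
    labels = np.asarray(labels)
    fold_ids = np.empty(labels.shape[0], dtype=int)
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if require_all_classes and len(idx) < k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than {k} folds")
        perm = rng.permutation(idx)
        fold_ids[perm] = np.arange(len(perm)) % k
    return fold_ids


def outer_fold_assignments(labels, config: RDCVConfig) -> np.ndarray:
    """Outer fold ids per repetition, (repeats, n) — the exact fold plan
    an :func:`rdcv` call with the same config and labels will use."""
    labels = np.asarray(labels).astype(str)
    children = np.random.SeedSequence(config.seed).spawn(config.repeats)
    out = np.empty((config.repeats, labels.shape[0]), dtype=int)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[r] = stratified_fold_ids(labels, config.k_out, rng)
    return out


def _scale_concat(blocks: dict[str, np.ndarray], train_idx: np.ndarray,
                  test_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold-local preprocessing: per block, autoscale on the training
    partition, divide by the training-partition Frobenius norm, concatenate.
    Test rows are transformed with the training parameters only."""
    tr_parts, te_parts = [], []
    for mat in blocks.values():
        Btr = mat[train_idx]
        mu = Btr.mean(axis=0)
        sd = Btr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)   # fold-constant columns become inert
        Ztr = (Btr - mu) / sd
        Zte = (mat[test_idx] - mu) / sd
        f = np.sqrt((Ztr ** 2).sum())
        if f == 0:
            f = 1.0
        tr_parts.append(Ztr / f)
        te_parts.append(Zte / f)
    return np.hstack(tr_parts), np.hstack(te_parts)


@dataclass
class _Fold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    Xtr: np.ndarray
    Xte: np.ndarray


@dataclass
class _RepeatPlan:
    outer: list[tuple[_Fold, list[_Fold]]]
    X_full: np.ndarray   # all samples, preprocessed on all samples


def _build_repeat_plan(blocks: dict[str, np.ndarray], labels: np.ndarray,
                       config: RDCVConfig, rng: np.random.Generator) -> _RepeatPlan:
    n = labels.shape[0]
    all_idx = np.arange(n)
    outer_ids = stratified_fold_ids(labels, config.k_out, rng)
    outer = []
    for f in range(config.k_out):
        test_idx = np.flatnonzero(outer_ids == f)
        train_idx = np.flatnonzero(outer_ids != f)
        Xtr, Xte = _scale_concat(blocks, train_idx, test_idx)
        fold = _Fold(train_idx, test_idx, Xtr, Xte)
        inner_ids = stratified_fold_ids(labels[train_idx], config.k_in, rng,
                                        require_all_classes=False)
        inner = []
        for g in range(config.k_in):
            ite = train_idx[inner_ids == g]
            itr = train_idx[inner_ids != g]
            iXtr, iXte = _scale_concat(blocks, itr, ite)
            inner.append(_Fold(itr, ite, iXtr, iXte))
        outer.append((fold, inner))
    X_full, _ = _scale_concat(blocks, all_idx, all_idx[:0])
    return _RepeatPlan(outer, X_full)


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _fit_predict_path(Xtr: np.ndarray, ytr01: np.ndarray, Xte: np.ndarray,
                      a_max: int) -> np.ndarray:
    """Predicted dummy on Xte after 1..a_max components (nested).

    If the training response is single-class (possible under permuted
    labels in small folds) the constant class value is predicted.  When the
    training matrix supports fewer than ``a_max`` components the last
    attainable prediction is carried forward, i.e. the model stops growing.
    """
    n_te = Xte.shape[0]
    if np.ptp(ytr01) == 0:
        return np.full((n_te, a_max), ytr01[0], dtype=float)
    W, P, q, _, _, y_mean, a_eff = _nipals_pls1(Xtr, ytr01, a_max)
    yhat = np.empty((n_te, a_max))
    Xr = Xte.copy()
    acc = np.full(n_te, y_mean)
    for a in range(a_eff):
        t = Xr @ W[:, a]
        Xr -= np.outer(t, P[:, a])
        acc = acc + q[a] * t
        yhat[:, a] = acc
    for a in range(a_eff, a_max):
        yhat[:, a] = yhat[:, a_eff - 1]
    return yhat


def _vip_from_fit(W: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    total = ssy.sum()
    if total <= 0:
        return np.zeros(p)
    wnorm2 = (W ** 2) / np.maximum((W ** 2).sum(axis=0), np.finfo(float).eps)
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def _run_repeat(plan: _RepeatPlan, y01: np.ndarray, a_max: int
                ) -> tuple[np.ndarray, list[int]]:
    """One rDCV repetition on prebuilt folds: returns (oof dummy, chosen A)."""
    oof = np.empty(y01.shape[0])
    chosen = []
    for fold, inner in plan.outer:
        err = np.zeros(a_max)
        n_eval = 0
        for inf in inner:
            if len(inf.test_idx) == 0:
                continue
            yhat = _fit_predict_path(inf.Xtr, y01[inf.train_idx], inf.Xte, a_max)
            pred = yhat >= 0.5
            err += (pred != (y01[inf.test_idx] >= 0.5)[:, None]).sum(axis=0)
            n_eval += len(inf.test_idx)
        a_best = int(np.argmin(err / max(n_eval, 1))) + 1  # ties -> smallest A
        chosen.append(a_best)
        yhat = _fit_predict_path(fold.Xtr, y01[fold.train_idx], fold.Xte, a_best)
        oof[fold.test_idx] = yhat[:, -1]
    return oof, chosen


# ---------------------------------------------------------------------------
# rDCV
# ---------------------------------------------------------------------------

def rdcv(X, labels, config: RDCVConfig | None = None, positive=None) -> RDCVResult:
    """Repeated double cross-validation of a (multi-block) PLS-DA classifier.

    Parameters
    ----------
    X:
        A samples x features matrix / DataFrame / FeatureTable, or a dict of
        named blocks for low-level fusion (each block preprocessed and
        Frobenius-scaled fold-locally).
    labels:
        Two-class label vector aligned with the rows of X.
    config:
        :class:`RDCVConfig`; defaults apply when omitted.
    positive:
        Class treated as positive for sensitivity (default: the
        lexicographically larger label).
    """
    config = config or RDCVConfig()
    blocks, feature_names, block_slices, _ = _coerce_blocks(X)
    labels = np.asarray(labels).astype(str)
    y01, classes = encode_labels(labels, positive)
    n = labels.shape[0]
    if n < 2 * config.k_out:
        raise ValueError(f"need at least {2 * config.k_out} samples for k_out={config.k_out}")
    R = config.repeats
    children = np.random.SeedSequence(config.seed).spawn(R)
    p = sum(m.shape[1] for m in blocks.values())
    acc = np.empty(R)
    sens = np.empty(R)
    spec = np.empty(R)
    chosen_all = np.empty((R, config.k_out), dtype=int)
    refit_A = np.empty(R, dtype=int)
    vips = np.empty((R, p))
    oof_all = np.empty((R, n))
    neg, pos = classes
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        plan = _build_repeat_plan(blocks, labels, config, rng)
        oof, chosen = _run_repeat(plan, y01, config.a_max)
        pred_labels = np.where(oof >= 0.5, pos, neg)
        fom = classification_metrics(labels, pred_labels, positive_class=pos)
        acc[r], sens[r], spec[r] = fom.accuracy, fom.sensitivity, fom.specificity
        chosen_all[r] = chosen
        oof_all[r] = oof
        a_med = max(1, int(np.median(chosen)))
        W, _, _, _, ssy, _, a_eff = _nipals_pls1(plan.X_full, y01, a_med)
        refit_A[r] = a_eff
        vips[r] = _vip_from_fit(W, ssy)
    return RDCVResult(config, classes, feature_names, block_slices,
                      acc, sens, spec, chosen_all, refit_A, vips, oof_all)


# ---------------------------------------------------------------------------
# VIP-consistency feature selection
# ---------------------------------------------------------------------------

def select_features_vip(result: RDCVResult, threshold: float | None = None,
                        consistency: float | None = None) -> pd.DataFrame:
    """Select features whose VIP clears the threshold consistently.

    A feature is selected iff VIP >= ``threshold`` in at least a
    ``consistency`` fraction of the rDCV repetitions.  The output is
    annotated with the source block of every feature.
    """
    if result.vip_matrix.size == 0:
        raise ValueError("empty VIP matrix")
    threshold = result.config.vip_threshold if threshold is None else threshold
    consistency = (result.config.vip_consistency if consistency is None
                   else consistency)
    if not 0 < consistency <= 1:
        raise ValueError("consistency must be in (0, 1]")
    V = result.vip_matrix
    frac = (V >= threshold).mean(axis=0)
    block_of = np.empty(V.shape[1], dtype=object)
    for name, sl in result.block_slices.items():
        block_of[sl] = name
    out = pd.DataFrame({
        "feature": result.feature_names,
        "block": block_of,
        "median_vip": np.median(V, axis=0),
        "mean_vip": V.mean(axis=0),
        "fraction_above": frac,
        "selected": frac >= consistency,
    })
    return out.sort_values("median_vip", ascending=False, kind="stable",
                           ignore_index=True)


def confirm_features(X, labels, selection: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Univariate confirmation of VIP-selected features.

    Runs a two-sided Mann-Whitney test per selected feature on the original
    (unfused) values and applies Bonferroni correction over the selected
    set; ``significant`` flags adjusted p <= ``alpha``.
    """
    blocks, feature_names, _, _ = _coerce_blocks(X)
    mat = np.hstack(list(blocks.values()))
    name_to_col = {f: j for j, f in enumerate(feature_names)}
    labels = np.asarray(labels).astype(str)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("confirmation requires exactly 2 groups")
    sel = selection[selection["selected"]].copy()
    if sel.empty:
        sel["U"] = []
        sel["p"] = []
        sel["p_bonferroni"] = []
        sel["significant"] = []
        return sel
    ps, us = [], []
    for f in sel["feature"]:
        col = mat[:, name_to_col[f]]
        u, pv = mann_whitney(col[labels == groups[0]], col[labels == groups[1]])
        us.append(u)
        ps.append(pv)
    sel["U"] = us
    sel["p"] = ps
    sel["p_bonferroni"] = adjust_pvalues(ps, method="bonferroni")
    sel["significant"] = sel["p_bonferroni"] <= alpha
    return sel


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed figures of merit against their label-permutation null."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_values: dict[str, float]
    n_permutations: int
    seed: int


def permutation_test(X, labels, config: RDCVConfig | None = None,
                     n_perm: int = 1000, null_repeats: int = 1,
                     positive=None) -> PermutationResult:
    """Permutation test of the rDCV figures of merit.

    Labels are permuted ``n_perm`` times; for each permutation the full
    rDCV figure-of-merit computation is repeated at ``null_repeats``
    repetitions to build the null distribution.  Observed and permuted
    statistics go through *identical* machinery: the fold structure
    (stratified by the observed labels) and the fold-local preprocessing
    depend only on the observed design, are computed once, and are reused
    for the observed labels and for every permutation — the requirement
    for the permutation p to be exact under label exchangeability.
    p-values use the add-one estimator
    (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or RDCVConfig()
    blocks, _, _, _ = _coerce_blocks(X)
    labels = np.asarray(labels).astype(str)
    y01, classes = encode_labels(labels, positive)
    neg, pos = classes
    null_cfg = replace(config, repeats=null_repeats)
    # the first `null_repeats` repeat-plans of an rdcv() run with this
    # config, plus an extra child stream for the permutations themselves
    root = np.random.SeedSequence(config.seed).spawn(null_repeats + 1)
    perm_rng = np.random.default_rng(root[-1])
    plans = []
    for child in root[:null_repeats]:
        rng = np.random.default_rng(child)
        plans.append(_build_repeat_plan(blocks, labels, null_cfg, rng))

    def figures(y: np.ndarray) -> dict[str, float]:
        true_labels = np.where(y >= 0.5, pos, neg)
        per_metric = {m: [] for m in ("accuracy", "sensitivity", "specificity")}
        for plan in plans:
            oof, _ = _run_repeat(plan, y, null_cfg.a_max)
            pred = np.where(oof >= 0.5, pos, neg)
            fom = classification_metrics(true_labels, pred, positive_class=pos)
            for m in per_metric:
                per_metric[m].append(getattr(fom, m))
        return {m: float(np.mean(v)) for m, v in per_metric.items()}

    observed = figures(y01)
    null = {m: np.empty(n_perm) for m in observed}
    for b in range(n_perm):
        fom = figures(perm_rng.permutation(y01))
        for m in null:
            null[m][b] = fom[m]

    p_values = {m: (1 + int(np.sum(null[m] >= observed[m] - 1e-12))) / (1 + n_perm)
                for m in observed}
    return PermutationResult(observed, null, p_values, n_perm, config.seed)
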
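"""Training protocol, splits, metrics and ablation harness.

The model is trained with an L1 (absolute-error) loss on the absorption
maximum, the Adam optimizer (learning rate 1e-4) for 1000 epochs, L2
weight decay 1e-5 and an additional L1 penalty with α = 1e-4 on the mean
absolute parameter value.  Records are split by *wild-type group* —
mutants always follow their parent into train or test, which prevents
leakage of near-identical sequences — with 10 wild-type groups held out
for testing.  Metrics are reported both in nanometers and electronvolts
(E = hc/λ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .graphs import MolecularGraph
from .nn import GraphBatch, LayerDims, ModelParams, forward, forward_tensor, init_params

logger = logging.getLogger(__name__)

#: hc in eV·nm (CODATA); E[eV] = HC_EV_NM / λ[nm].
HC_EV_NM = 1239.84198

LAMBDA_MIN_NM = 300.0
LAMBDA_MAX_NM = 800.0


# --------------------------------------------------------------------------
# units and loss
# --------------------------------------------------------------------------

def nm_to_ev(lambda_nm):
    """Photon energy in eV for a wavelength in nm (E = hc/λ)."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = HC_EV_NM / lam
    return float(out) if out.ndim == 0 else out


def ev_to_nm(energy_ev):
    """Wavelength in nm for a photon energy in eV (λ = hc/E)."""
    e = np.asarray(energy_ev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    out = HC_EV_NM / e
    return float(out) if out.ndim == 0 else out


def l1_loss(y, y0) -> float:
    """|y − y0|, averaged over the batch if arrays are given."""
    return float(np.mean(np.abs(np.asarray(y, float) - np.asarray(y0, float))))


# --------------------------------------------------------------------------
# dataset records and splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetRecord:
    """One sequence with its measured absorption maximum."""

    seq_id: str
    wt_group: str
    sequence: str
    lambda_max: float  # nm
    method: str = ""

    def __post_init__(self):
        if not (LAMBDA_MIN_NM <= self.lambda_max <= LAMBDA_MAX_NM):
            raise ValueError(
                f"record {self.seq_id!r}: λmax {self.lambda_max} nm outside "
                f"[{LAMBDA_MIN_NM:.0f}, {LAMBDA_MAX_NM:.0f}] nm"
            )


def load_dataset(csv_path) -> list[DatasetRecord]:
    """Read the dataset CSV (seq_id, wt_group, sequence, lambda_max_nm[, method])."""
    df = pd.read_csv(csv_path)
    required = {"seq_id", "wt_group", "sequence", "lambda_max_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    return [
        DatasetRecord(
            seq_id=str(r.seq_id),
            wt_group=str(r.wt_group),
            sequence=str(r.sequence),
            lambda_max=float(r.lambda_max_nm),
            method=str(getattr(r, "method", "")),
        )
        for r in df.itertuples()
    ]


def split_by_wildtype(
    records: list[DatasetRecord], n_test_wt: int = 10, seed: int = 0
) -> tuple[list[DatasetRecord], list[DatasetRecord]]:
    """Hold out ``n_test_wt`` whole wild-type groups (parents + all mutants).

    Groups are shuffled deterministically by ``seed``; no group ever spans
    both sides, so point mutants can never leak across the split.
    """
    groups = list(dict.fromkeys(r.wt_group for r in records))
    if len(groups) < n_test_wt + 1:
        raise ValueError(
            f"need at least {n_test_wt + 1} wild-type groups, got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    test_groups = {groups[i] for i in order[:n_test_wt]}
    train = [r for r in records if r.wt_group not in test_groups]
    test = [r for r in records if r.wt_group in test_groups]
    return train, test


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the published training recipe."""

    learning_rate: float = 1e-4
    epochs: int = 1000
    weight_decay_l2: float = 1e-5
    l1_alpha: float = 1e-4
    batch_size: int = 32
    seed: int = 0
    target_units: str = "nm"

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.weight_decay_l2 < 0 or self.l1_alpha < 0:
            raise ValueError("regularization strengths must be non-negative")
        if self.target_units not in ("nm", "eV"):
            raise ValueError("target_units must be 'nm' or 'eV'")


class TrainingDiverged(RuntimeError):
    pass


def train(
    graphs: list[MolecularGraph],
    labels: np.ndarray,
    config: TrainConfig,
    dims: LayerDims | None = None,
    attention: bool = True,
) -> tuple[ModelParams, list[float]]:
    """Fit the network; returns final parameters and the per-epoch loss history.

    ``labels`` are absorption maxima in nm; if ``config.target_units`` is
    'eV' they are converted before fitting and the model predicts eV.
    The output head's affine target scaling is frozen to the training
    labels' mean/std, so optimization happens near unit scale while the
    loss stays the plain L1 in the target unit.
    """
    if len(graphs) < 2:
        raise ValueError("training needs at least 2 graphs")
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (len(graphs),):
        raise ValueError("labels must align with graphs")
    y = nm_to_ev(labels) if config.target_units == "eV" else labels.copy()

    if dims is None:
        dims = LayerDims(f_in=graphs[0].node_features.shape[1])
    params = init_params(dims, seed=config.seed, attention=attention)
    params.label_mean = float(y.mean())
    std = float(y.std())
    params.label_std = std if std > 0 else 1.0
    params.meta.update({"seed": config.seed, "target_units": config.target_units})

    keys = params.trainable_keys()
    m = {k: np.zeros_like(params.arrays[k]) for k in keys}
    v = {k: np.zeros_like(params.arrays[k]) for k in keys}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n_params = sum(params.arrays[k].size for k in keys)

    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    step = 0
    n = len(graphs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = GraphBatch.from_graphs([graphs[i] for i in idx])
            leaves = {k: Tensor(params.arrays[k], requires_grad=True) for k in keys}
            pred = forward_tensor(batch, params, mode="train", leaves=leaves)
            data_loss = (pred - Tensor(y[idx])).abs().mean()
            reg = None
            for k in keys:
                term = leaves[k].abs().sum()
                reg = term if reg is None else reg + term
            loss = data_loss + reg * (config.l1_alpha / n_params)
            if not np.isfinite(loss.value):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, lr={config.learning_rate}"
                )
            loss.backward()
            step += 1
            for k in keys:
                g = leaves[k].grad + config.weight_decay_l2 * params.arrays[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                params.arrays[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += float(data_loss.value) * len(idx)
        history.append(epoch_loss / n)
    return params, history


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class Metrics:
    """Per-record absolute errors with aggregates in both nm and eV."""

    errors_nm: np.ndarray
    errors_ev: np.ndarray

    @property
    def median_nm(self) -> float:
        return float(np.median(self.errors_nm))

    @property
    def mean_nm(self) -> float:
        return float(np.mean(self.errors_nm))

    @property
    def std_nm(self) -> float:
        return float(np.std(self.errors_nm))

    @property
    def median_ev(self) -> float:
        return float(np.median(self.errors_ev))

    @property
    def mean_ev(self) -> float:
        return float(np.mean(self.errors_ev))

    @property
    def std_ev(self) -> float:
        return float(np.std(self.errors_ev))

    def as_dict(self) -> dict:
        return {
            "median_nm": self.median_nm, "mean_nm": self.mean_nm, "std_nm": self.std_nm,
            "median_ev": self.median_ev, "mean_ev": self.mean_ev, "std_ev": self.std_ev,
            "errors_nm": self.errors_nm.tolist(),
            "errors_ev": self.errors_ev.tolist(),
        }


def evaluate(
    params: ModelParams,
    graphs: list[MolecularGraph],
    labels_nm: np.ndarray,
) -> Metrics:
    """Absolute errors per record, in nm and eV.

    Predictions are made in the model's training unit; each predicted and
    true value is then converted record-wise to the other unit before the
    error is taken, so both unit systems see genuine per-record errors
    rather than converted aggregates.
    """
    labels_nm = np.asarray(labels_nm, dtype=float)
    preds = forward(graphs, params, mode="eval")
    unit = params.meta.get("target_units", "nm")
    if unit == "eV":
        pred_ev = preds
        pred_nm = ev_to_nm(np.maximum(preds, 1e-9))
    else:
        pred_nm = preds
        pred_ev = nm_to_ev(np.maximum(preds, 1e-9))
    errors_nm = np.abs(pred_nm - labels_nm)
    errors_ev = np.abs(pred_ev - nm_to_ev(labels_nm))
    return Metrics(errors_nm=errors_nm, errors_ev=errors_ev)


def ks_similarity(a, b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic sup_x |F_a(x) − F_b(x)|.

    Used as a train/test label-distribution similarity score (statistic
    only, no p-value): 0 for identical empirical distributions, 1 for
    disjoint supports.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_similarity: samples must be non-empty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


# --------------------------------------------------------------------------
# ablation protocols
# --------------------------------------------------------------------------

ABLATION_MODES = ("drop_one", "keep_one", "no_features")


def _select_columns(schema, mode: str, group: str | None) -> list[int]:
    all_cols = list(range(len(schema.column_names)))
    if mode == "drop_one":
        drop = set(schema.columns_of_group(group))
        return [c for c in all_cols if c not in drop]
    if mode == "keep_one":
        return schema.columns_of_group(group)
    raise ValueError(f"unknown ablation mode {mode!r}")


def ablate(
    train_set: list[tuple],
    test_set: list[tuple],
    schema,
    mode: str,
    config: TrainConfig,
    group: str | None = None,
    hidden: tuple[int, int, int] = (32, 32, 32),
    attention: bool = True,
    cutoff: float = 2.0,
) -> Metrics:
    """Retrain with a feature subset and return test metrics.

    ``train_set``/``test_set`` are lists of ``(pocket, FeatureMatrix,
    label_nm)`` triples.  Modes: ``drop_one`` removes one feature group
    before normalization, ``keep_one`` keeps only that group, and
    ``no_features`` replaces the features by a single constant so the
    prediction rests on the graph structure alone.
    """
    from .graphs import build_graph

    if mode not in ABLATION_MODES:
        raise ValueError(f"mode must be one of {ABLATION_MODES}")

    if mode == "no_features":
        def feats(fm):
            return np.ones((fm.values.shape[0], 1))
        train_graphs = [
            build_graph(p, feats(fm), cutoff=cutoff, label=y)
            for p, fm, y in train_set
        ]
        test_graphs = [
            build_graph(p, feats(fm), cutoff=cutoff, label=y)
            for p, fm, y in test_set
        ]
    else:
        cols = _select_columns(schema, mode, group)
        sub_train = [fm.values[:, cols] for _, fm, _ in train_set]
        pooled = np.vstack(sub_train)
        var = pooled.var(axis=0)
        retained = var >= 1e-12
        if not retained.any():
            raise ValueError(
                f"ablation {mode}/{group!r}: all selected columns are constant "
                "on the training set — empty feature set"
            )
        mean = pooled.mean(axis=0)[retained]
        std = pooled.std(axis=0)[retained]
        norm = lambda x: (x[:, retained] - mean) / std
        train_graphs = [
            build_graph(p, norm(fm.values[:, cols]), cutoff=cutoff, label=y)
            for p, fm, y in train_set
        ]
        test_graphs = [
            build_graph(p, norm(fm.values[:, cols]), cutoff=cutoff, label=y)
            for p, fm, y in test_set
        ]

    f_in = train_graphs[0].node_features.shape[1]
    dims = LayerDims(f_in, *hidden)
    y_train = np.array([y for _, _, y in train_set])
    y_test = np.array([y for _, _, y in test_set])
    params, _ = train(train_graphs, y_train, config, dims=dims, attention=attention)
    return evaluate(params, test_graphs, y_test)


def attention_off_variant(
    graphs: list[MolecularGraph],
    labels: np.ndarray,
    config: TrainConfig,
    dims: LayerDims | None = None,
) -> tuple[ModelParams, list[float]]:
    """Same training pipeline with the attention layers replaced by GCN."""
    return train(graphs, labels, config, dims=dims, attention=False)
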
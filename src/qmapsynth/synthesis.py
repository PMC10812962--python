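"""T2 -> T1rho map synthesis with a 2D U-Net and region-weighted loss.

The synthesis network maps single T2 map slices to T1rho map slices.
Training follows a subject-wise protocol: a 65:15:20 train/validation/test
split in which every subject's slices stay in exactly one subset, early
stopping on validation loss, optional 4-fold cross-validation over the
train+validation pool, and a grid hyperparameter search selected by
cartilage NMSE.

The training objective weights cartilage more heavily than the rest of the
slice:

    loss = w * MSE(pred[cartilage], truth[cartilage])
         + MAE(pred[background],   truth[background])

with w = 1.5 by default and "background" the complement of the cartilage
mask over the whole slice.  Both reductions are per-region means so the
weight stays scale-comparable across mask sizes.  Maps are clipped to
[0, 150] ms and divided by ``intensity_scale`` before entering the network;
the loss is applied on that normalized scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._unet import Adam, UNet2D
from .evaluation import nmse
from .phantom import CohortSubject
from .relaxometry import QuantMap, clip_map

logger = logging.getLogger("qmapsynth.synthesis")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthModelSpec:
    """U-Net architecture knobs.

    ``depth`` encoder levels plus a bottleneck and mirrored decoder give
    2*depth + 2 convolutional blocks; the default depth of 3 yields the
    8-convolution configuration.  The "tiny" preset (depth 3, 8 base
    channels, ~61k parameters) is intended for desk-scale experiments; the
    depth keeps the receptive field large enough to resolve which
    compartment a cartilage voxel belongs to from spatial context.
    """

    depth: int = 3
    base_channels: int = 16
    batch_norm: bool = True
    dtype: str = "float32"

    @staticmethod
    def tiny() -> "SynthModelSpec":
        return SynthModelSpec(depth=3, base_channels=8)


@dataclass(frozen=True)
class TrainConfig:
    split_fractions: Tuple[float, float, float] = (0.65, 0.15, 0.20)
    n_folds: int = 4
    learning_rate: float = 2e-3
    max_epochs: int = 130
    early_stop_patience: int = 25
    loss_weight_cartilage: float = 1.5
    clip_range: Tuple[float, float] = (0.0, 150.0)
    intensity_scale: float = 150.0
    batch_size: int = 8
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 6
    min_lr: float = 3e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.loss_weight_cartilage <= 0:
            raise ValueError("cartilage loss weight must be > 0")
        if self.early_stop_patience < 1:
            raise ValueError("early-stop patience must be >= 1")


@dataclass
class SlicePair:
    """One training example: a T2 slice, its T1rho target and cartilage mask."""

    t2_slice: np.ndarray
    t1rho_slice: np.ndarray
    cartilage_mask_slice: np.ndarray
    subject_id: str
    slice_index: int

    def __post_init__(self) -> None:
        if not (self.t2_slice.shape == self.t1rho_slice.shape == self.cartilage_mask_slice.shape):
            raise ValueError("slice shapes must agree")
        if not self.subject_id:
            raise ValueError("subject_id is required (split integrity depends on it)")


def make_slice_pairs(
    t2_map: QuantMap, t1rho_map: QuantMap, cartilage_mask: np.ndarray, subject_id: str
) -> List[SlicePair]:
    """Decompose a subject's volumes into per-slice training pairs."""
    return [
        SlicePair(
            t2_slice=t2_map.values_ms[k],
            t1rho_slice=t1rho_map.values_ms[k],
            cartilage_mask_slice=np.asarray(cartilage_mask[k], bool),
            subject_id=subject_id,
            slice_index=k,
        )
        for k in range(t2_map.shape[0])
    ]


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    subject_ids: Sequence[str],
    fractions: Tuple[float, float, float] = (0.65, 0.15, 0.20),
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Subject-level train/val/test partition.

    Sizes follow largest-remainder rounding of n * fraction so the subsets
    are as close to the nominal fractions as integer counts allow; the
    assignment itself is a seeded shuffle.  Every subject lands in exactly
    one subset.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")

    exact = [n * f for f in fractions]
    sizes = [math.floor(e) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for i in sorted(range(3), key=lambda i: (-remainders[i], i))[: n - sum(sizes)]:
        sizes[i] += 1
    if min(sizes) == 0:
        raise ValueError(f"a subset would be empty for n={n}, fractions={fractions}")

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    out = {
        "train": sorted(order[: sizes[0]]),
        "val": sorted(order[sizes[0] : sizes[0] + sizes[1]]),
        "test": sorted(order[sizes[0] + sizes[1] :]),
    }
    assert sorted(out["train"] + out["val"] + out["test"]) == sorted(ids)
    return out


def assert_split_integrity(split: Dict[str, List[str]], pairs: Iterable[SlicePair]) -> None:
    """Verify no subject's slices cross subset boundaries."""
    owner: Dict[str, str] = {}
    for name, ids in split.items():
        for sid in ids:
            if sid in owner:
                raise AssertionError(f"subject {sid} in both {owner[sid]} and {name}")
            owner[sid] = name
    for p in pairs:
        if p.subject_id not in owner:
            raise AssertionError(f"slice from unknown subject {p.subject_id}")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    cartilage_mask: np.ndarray,
    weight: float = 1.5,
) -> float:
    """Region-weighted objective: w*MSE over cartilage + MAE over the rest.

    Reductions are means over each region's own voxels.  A slice without
    cartilage contributes only the L1 term (the L2 term is defined as 0).
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    m = np.asarray(cartilage_mask, bool)
    if not (pred.shape == truth.shape == m.shape):
        raise ValueError("pred/truth/mask shapes must agree")
    err = pred - truth
    l2 = float(np.mean(err[m] ** 2)) if m.any() else 0.0
    bg = ~m
    l1 = float(np.mean(np.abs(err[bg]))) if bg.any() else 0.0
    return weight * l2 + l1


def _weighted_loss_and_grad(
    pred: np.ndarray, truth: np.ndarray, masks: np.ndarray, weight: float
) -> Tuple[float, np.ndarray]:
    """Batched loss (mean over slices) and its gradient w.r.t. pred.

    pred/truth: (N, 1, H, W); masks: (N, H, W) boolean.
    """
    N = pred.shape[0]
    err = pred[:, 0] - truth[:, 0]
    grad = np.zeros_like(err)
    total = 0.0
    for i in range(N):
        m = masks[i]
        bg = ~m
        nc = int(m.sum())
        nb = int(bg.sum())
        if nc:
            e = err[i][m]
            total += weight * float(np.mean(e**2))
            grad[i][m] += 2.0 * weight * e / nc
        if nb:
            e = err[i][bg]
            total += float(np.mean(np.abs(e)))
            grad[i][bg] += np.sign(e) / nb
    return total / N, (grad / N)[:, None]


# ---------------------------------------------------------------------------
# model construction and training
# ---------------------------------------------------------------------------

def build_model(spec: SynthModelSpec, seed: int = 0) -> UNet2D:
    """Instantiate a U-Net; two builds with the same seed are identical."""
    model = UNet2D(
        depth=spec.depth,
        base_channels=spec.base_channels,
        batch_norm=spec.batch_norm,
        seed=seed,
        dtype=np.dtype(spec.dtype),
    )
    logger.info(
        "built U-Net depth=%d base=%d: %d parameters",
        spec.depth, spec.base_channels, model.n_parameters(),
    )
    return model


def _prepare_arrays(
    pairs: Sequence[SlicePair], config: TrainConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = config.clip_range
    s = config.intensity_scale
    x = np.stack([np.clip(p.t2_slice, lo, hi) / s for p in pairs])[:, None]
    y = np.stack([np.clip(p.t1rho_slice, lo, hi) / s for p in pairs])[:, None]
    m = np.stack([p.cartilage_mask_slice for p in pairs])
    return x, y, m


@dataclass
class TrainResult:
    model: UNet2D
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _eval_loss(model: UNet2D, x, y, m, weight: float, batch: int = 16) -> float:
    losses = []
    for i in range(0, x.shape[0], batch):
        pred = model.forward(x[i : i + batch], train=False)
        loss, _ = _weighted_loss_and_grad(pred, y[i : i + batch], m[i : i + batch], weight)
        losses.append(loss * (min(i + batch, x.shape[0]) - i))
    return float(np.sum(losses) / x.shape[0])


def train(
    model: UNet2D,
    train_pairs: Sequence[SlicePair],
    val_pairs: Sequence[SlicePair],
    config: TrainConfig,
) -> TrainResult:
    """Optimize the network with Adam under the weighted loss.

    Stops when the validation loss has not improved for
    ``early_stop_patience`` epochs and returns the best-validation
    checkpoint.  The learning rate is halved (``lr_decay_factor``) whenever
    the validation loss plateaus for ``lr_decay_patience`` epochs, which
    Adam needs to converge to high precision.  Divergence (non-finite
    loss) aborts with a diagnostic.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("empty training or validation set")
    xt, yt, mt = _prepare_arrays(train_pairs, config)
    xv, yv, mv = _prepare_arrays(val_pairs, config)
    n_empty = int(sum(1 for p in train_pairs if not p.cartilage_mask_slice.any()))
    if n_empty:
        logger.info("%d training slices without cartilage (L1-only loss)", n_empty)

    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    w = config.loss_weight_cartilage

    best_val = np.inf
    best_state = model.state_dict()
    best_state = {k: v.copy() for k, v in best_state.items()}
    best_epoch = -1
    wait = 0
    lr_wait = 0
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(xt.shape[0])
        ep_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            model.zero_grad()
            pred = model.forward(xt[idx], train=True)
            loss, grad = _weighted_loss_and_grad(pred, yt[idx], mt[idx], w)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
        ep_loss /= len(order)
        val_loss = _eval_loss(model, xv, yv, mv, w)
        rows.append({"epoch": epoch, "train_loss": ep_loss, "val_loss": val_loss,
                     "lr": opt.lr})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            wait = 0
            lr_wait = 0
        else:
            wait += 1
            lr_wait += 1
            if wait >= config.early_stop_patience:
                break
            if lr_wait >= config.lr_decay_patience:
                opt.lr = max(opt.lr * config.lr_decay_factor, config.min_lr)
                lr_wait = 0
    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    logger.info("training stopped at epoch %d (best val %.3e at epoch %d)",
                len(rows) - 1, best_val, best_epoch)
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_loss=float(best_val))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_map(model: UNet2D, t2_map: QuantMap, config: TrainConfig) -> QuantMap:
    """Synthesize a T1rho map from a T2 map, slice by slice.

    The input is clipped and scaled exactly as in training; the output is
    mapped back to ms and clipped to the [0, 150] display window.
    Inference is deterministic (batch-norm uses running statistics).
    """
    lo, hi = config.clip_range
    x = np.clip(t2_map.values_ms, lo, hi) / config.intensity_scale
    pred = model.forward(x[:, None], train=False)[:, 0]
    out = QuantMap(pred * config.intensity_scale, kind="T1rho", spacing=t2_map.spacing)
    return clip_map(out, lo, hi)


def identity_baseline(
    t2_map: QuantMap, scale: float, clip: Tuple[float, float] = (0.0, 150.0)
) -> QuantMap:
    """Trivial baseline: predict T1rho as T2 rescaled by a constant factor
    (e.g. the cohort-level cartilage mean ratio)."""
    return clip_map(QuantMap(t2_map.values_ms * scale, kind="T1rho",
                             spacing=t2_map.spacing), *clip)


# ---------------------------------------------------------------------------
# cross-validation and hyperparameter search
# ---------------------------------------------------------------------------

def make_folds(subject_ids: Sequence[str], n_folds: int, seed: int = 0) -> List[List[str]]:
    """Seeded subject-level folds of near-equal size."""
    ids = list(subject_ids)
    if len(ids) < n_folds:
        raise ValueError(f"fewer subjects ({len(ids)}) than folds ({n_folds})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids)
    return [sorted(order[k::n_folds].tolist()) for k in range(n_folds)]


def cross_validate(
    pairs_by_subject: Dict[str, List[SlicePair]],
    model_spec: SynthModelSpec,
    config: TrainConfig,
) -> pd.DataFrame:
    """K-fold cross-validation over the train+val subject pool.

    Each subject serves as validation exactly once; per-fold cartilage NMSE
    on the held-out fold is reported together with the per-subject values
    used to compute it, so the fold means can be re-derived.
    """
    ids = sorted(pairs_by_subject)
    folds = make_folds(ids, config.n_folds, config.seed)
    rows = []
    for k, val_ids in enumerate(folds):
        train_ids = [s for s in ids if s not in val_ids]
        tp = [p for s in train_ids for p in pairs_by_subject[s]]
        vp = [p for s in val_ids for p in pairs_by_subject[s]]
        model = build_model(model_spec, seed=config.seed + k)
        result = train(model, tp, vp, config)
        for sid in val_ids:
            sp = pairs_by_subject[sid]
            truth = np.stack([p.t1rho_slice for p in sp])
            mask = np.stack([p.cartilage_mask_slice for p in sp])
            t2 = QuantMap(np.stack([p.t2_slice for p in sp]), kind="T2")
            pred = predict_map(result.model, t2, config)
            rows.append({
                "fold": k,
                "subject_id": sid,
                "cartilage_nmse_pct": nmse(pred.values_ms, truth, mask),
                "val_loss": result.best_val_loss,
            })
    return pd.DataFrame(rows)


def hyperparameter_search(
    grid: Sequence[Dict[str, object]],
    train_pairs: Sequence[SlicePair],
    val_pairs: Sequence[SlicePair],
    model_spec: SynthModelSpec,
    base_config: TrainConfig,
) -> Tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive search over configuration overrides.

    Each grid entry is a dict of ``TrainConfig`` field overrides (e.g.
    learning_rate, intensity_scale, loss_weight_cartilage).  The winner
    minimizes validation cartilage NMSE; the full leaderboard is returned
    sorted ascending.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    truth = np.stack([p.t1rho_slice for p in val_pairs])
    mask = np.stack([p.cartilage_mask_slice for p in val_pairs])
    t2 = QuantMap(np.stack([p.t2_slice for p in val_pairs]), kind="T2")
    rows = []
    configs = []
    for i, overrides in enumerate(grid):
        cfg = replace(base_config, **overrides)
        model = build_model(model_spec, seed=cfg.seed)
        result = train(model, train_pairs, val_pairs, cfg)
        pred = predict_map(result.model, t2, cfg)
        rows.append({
            "entry": i,
            **overrides,
            "val_cartilage_nmse_pct": nmse(pred.values_ms, truth, mask),
            "val_loss": result.best_val_loss,
        })
        configs.append(cfg)
    board = pd.DataFrame(rows).sort_values(
        "val_cartilage_nmse_pct", kind="stable"
    ).reset_index(drop=True)
    best = configs[int(board.loc[0, "entry"])]
    return best, board


# ---------------------------------------------------------------------------
# convenience: cohort -> pairs
# ---------------------------------------------------------------------------

def pairs_from_maps(
    maps: Dict[str, Tuple[QuantMap, QuantMap, np.ndarray]]
) -> Dict[str, List[SlicePair]]:
    """Build per-subject slice pairs from {id: (t2_map, t1rho_map, cart_mask)}."""
    return {
        sid: make_slice_pairs(t2, t1r, mask, sid)
        for sid, (t2, t1r, mask) in maps.items()
    }
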
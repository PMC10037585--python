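"""Training-scenario construction, BCE training loop, and volume prediction.

The source study probes training-set-size sensitivity with four scenarios
drawn from the training split of the cohort manifest:

* ``full`` — every training-split scan;
* ``TS1`` / ``TS2`` — a mouse-level bisection of the training split, balanced
  on test-retest pairs (pair counts differ by at most one) and scan counts;
* ``TSM`` — the scans of a single mouse, the one with the longest timeline.

Each coronal slice is an independent 2D training sample; batches are drawn
uniformly at random (with replacement) from all training slices, including
background-only slices.  The network minimises binary cross-entropy against
the reference masks, and the checkpoint with the best mean validation
Jaccard index is kept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import jaccard
from .nn import Adam, AttentionUNet, ModelConfig, Tensor, recalibrate_batchnorm
from .volume_io import (
    BinaryMask,
    ScanVolume,
    SliceStack,
    extract_coronal_slices,
    read_mhd,
    restack_slices,
)

__all__ = [
    "TrainingScenario",
    "TrainingConfig",
    "make_scenarios",
    "train",
    "predict_volume",
    "normalize_intensities",
    "load_slice_dataset",
]


@dataclass(frozen=True)
class TrainingScenario:
    name: str  # "full" | "TS1" | "TS2" | "TSM"
    scan_ids: tuple[str, ...]
    mouse_ids: tuple[str, ...]
    n_pairs: int

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the BCE training loop (defaults follow the
    full-scale protocol: batches of 40 slices, up to 120 epochs)."""

    batch_size: int = 40
    max_epochs: int = 120
    learning_rate: float = 1e-3
    base_filters: int = 16
    threshold: float = 0.5
    normalization_percentiles: tuple[float, float] = (1.0, 99.0)
    bn_recalibration: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def _mouse_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse scan/pair/timepoint counts for the training split."""
    train = manifest[manifest["split"] == "train"]
    rows = []
    for mouse, sub in train.groupby("mouse_id"):
        rows.append(
            {
                "mouse_id": mouse,
                "n_scans": len(sub),
                "n_pairs": sub.loc[sub["role"] == "test", "pair_id"].nunique(),
                "n_timepoints": sub["timepoint_days"].nunique(),
            }
        )
    return pd.DataFrame(rows).sort_values("mouse_id").reset_index(drop=True)


def _balanced_bisection(table: pd.DataFrame, seed: int) -> tuple[set, set]:
    """Split training mice into two halves balancing pairs (hard, diff <= 1)
    and scan counts (soft), via a seeded randomised search."""
    rng = np.random.default_rng(seed)
    mice = table["mouse_id"].to_numpy()
    pairs = table["n_pairs"].to_numpy()
    scans = table["n_scans"].to_numpy()
    n = len(mice)
    best, best_key = None, None
    for _ in range(4000):
        side = rng.random(n) < 0.5
        if side.all() or not side.any():
            continue
        pair_diff = abs(int(pairs[side].sum()) - int(pairs[~side].sum()))
        scan_diff = abs(int(scans[side].sum()) - int(scans[~side].sum()))
        mouse_diff = abs(int(side.sum()) - int((~side).sum()))
        key = (pair_diff, scan_diff, mouse_diff)
        if best_key is None or key < best_key:
            best_key, best = key, side.copy()
        if key == (0, min(scans.sum() % 2, 1), min(n % 2, 1)):
            break
    if best is None or best_key[0] > 1:
        raise ValueError("could not balance test-retest pairs across halves")
    return set(mice[best]), set(mice[~best])


def make_scenarios(
    manifest: pd.DataFrame, seed: int = 0
) -> dict[str, TrainingScenario]:
    """Build the four training scenarios from a cohort manifest.

    TS1/TS2 partition the training mice (never splitting a mouse across
    halves); TSM is the training mouse with the most timepoints, ties broken
    by pair count then lowest id.
    """
    table = _mouse_table(manifest)
    if len(table) < 2 or table["n_pairs"].sum() < 2:
        raise ValueError("training split needs >= 2 mice and >= 2 pairs")
    train = manifest[manifest["split"] == "train"]

    def scenario(name: str, mice: set[str]) -> TrainingScenario:
        sub = train[train["mouse_id"].isin(mice)]
        return TrainingScenario(
            name=name,
            scan_ids=tuple(sub["scan_id"]),
            mouse_ids=tuple(sorted(mice)),
            n_pairs=int(sub.loc[sub["role"] == "test", "pair_id"].nunique()),
        )

    half1, half2 = _balanced_bisection(table, seed)
    tsm_row = table.sort_values(
        ["n_timepoints", "n_pairs", "mouse_id"], ascending=[False, False, True]
    ).iloc[0]
    return {
        "full": scenario("full", set(table["mouse_id"])),
        "TS1": scenario("TS1", half1),
        "TS2": scenario("TS2", half2),
        "TSM": scenario("TSM", {tsm_row["mouse_id"]}),
    }


# ----------------------------------------------------------------------------
# data loading
# ----------------------------------------------------------------------------


def normalize_intensities(
    arr: np.ndarray, percentiles: tuple[float, float] = (1.0, 99.0)
) -> np.ndarray:
    """Per-volume robust rescale: the [p_low, p_high] window maps to [0, 1]."""
    lo, hi = np.percentile(arr, percentiles)
    if hi <= lo:
        return np.zeros_like(arr, dtype=np.float32)
    out = (arr.astype(np.float32) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def load_slice_dataset(
    manifest: pd.DataFrame,
    scan_ids,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all coronal slices of the given scans into (X, Y) arrays of
    shape (n_slices, 1, H, W); intensities normalised per volume."""
    sel = manifest.set_index("scan_id").loc[list(scan_ids)]
    xs, ys = [], []
    for _, row in sel.iterrows():
        vol = read_mhd(row["image_path"], as_mask=False)
        mask = read_mhd(row["mask_path_EA1"], as_mask=True)
        xs.append(
            normalize_intensities(vol.intensities, percentiles=percentiles)
        )
        ys.append(mask.labels.astype(np.float32))
    x = np.concatenate([_raw_stack(v) for v in xs])
    y = np.concatenate([_raw_stack(v) for v in ys])
    return x[:, None, :, :], y[:, None, :, :]


def _raw_stack(arr: np.ndarray) -> np.ndarray:
    """Coronal slices of a raw array (axis 1 -> leading axis)."""
    return np.moveaxis(arr, 1, 0)


# ----------------------------------------------------------------------------
# training
# ----------------------------------------------------------------------------


def train(
    scenario: TrainingScenario,
    config: TrainingConfig,
    manifest: pd.DataFrame,
) -> tuple[AttentionUNet, pd.DataFrame]:
    """Train an attention U-Net on a scenario's slices.

    Returns the checkpoint with the highest mean validation Jaccard (volume
    level, against the reference masks of the validation split) and the
    per-epoch history (mean training BCE, validation Jaccard).  Bit-for-bit
    reproducible for a fixed config seed.
    """
    if scenario.n_scans == 0:
        raise ValueError(f"scenario {scenario.name!r} has no scans")
    val = manifest[manifest["split"] == "val"]
    if len(val) == 0:
        raise ValueError("validation split is empty; cannot select a model")

    x, y = load_slice_dataset(
        manifest, scenario.scan_ids, config.normalization_percentiles
    )
    n_slices = x.shape[0]
    iters_per_epoch = max(1, int(np.ceil(n_slices / config.batch_size)))

    model = AttentionUNet(
        ModelConfig(base_filters=config.base_filters), seed=config.seed
    )
    # Start the head at the foreground-prevalence logit: with a sub-percent
    # foreground fraction this skips the long initial phase where BCE only
    # learns to suppress background.
    prev = float(np.clip(y.mean(), 1e-4, 1 - 1e-4))
    model.head.bias.data[:] = np.log(prev / (1.0 - prev))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB47C]))

    val_scans = [
        (read_mhd(r["image_path"], as_mask=False), read_mhd(r["mask_path_EA1"], as_mask=True))
        for _, r in val.iterrows()
    ]

    # fixed calibration batch for refreshing batch-norm statistics before
    # each evaluation (keeps inference consistent with the current weights)
    calib_idx = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xCA11])
    ).choice(n_slices, size=min(64, n_slices), replace=False)

    best_ji, best_state, history = -np.inf, None, []
    for epoch in range(config.max_epochs):
        model.train()
        losses = []
        for _ in range(iters_per_epoch):
            idx = rng.integers(0, n_slices, size=config.batch_size)
            opt.zero_grad()
            loss = model.forward_logits(Tensor(x[idx])).bce_with_logits(y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if config.bn_recalibration:
            recalibrate_batchnorm(model, x[calib_idx])
        model.eval()
        jis = []
        for vol, ref in val_scans:
            pred = predict_volume(model, vol, threshold=config.threshold,
                                  batch_size=config.batch_size)
            jis.append(
                jaccard(pred, ref) if pred.voxel_count > 0 else 0.0
            )
        val_ji = float(np.mean(jis))
        history.append(
            {"epoch": epoch, "train_bce": float(np.mean(losses)), "val_jaccard": val_ji}
        )
        if val_ji > best_ji:
            best_ji = val_ji
            best_state = (
                [p.data.copy() for p in model.parameters()],
                [b.copy() for b in model.buffers()],
            )

    params, buffers = best_state
    for p, d in zip(model.parameters(), params):
        p.data = d
    for b, d in zip(model.buffers(), buffers):
        b[...] = d
    model.eval()
    return model, pd.DataFrame(history)


def predict_volume(
    model: AttentionUNet,
    scan: ScanVolume,
    threshold: float = 0.5,
    batch_size: int = 40,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> BinaryMask:
    """Segment a 3D scan by per-slice forward passes.

    Slices are normalised, pushed through the network in evaluation mode, and
    thresholded (foreground iff p > threshold; p == threshold is background),
    then restacked into a mask on the scan's geometry.
    """
    model.eval()
    stack = extract_coronal_slices(scan)
    x = normalize_intensities(np.asarray(stack.slices), percentiles=percentiles)
    x = x[:, None, :, :]
    probs = np.concatenate(
        [model(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    )
    labels = (probs[:, 0] > threshold).astype(np.uint8)
    out_stack = SliceStack(
        slices=labels,
        slice_axis=stack.slice_axis,
        geometry=scan.geometry,
        is_mask=True,
    )
    return restack_slices(out_stack)
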
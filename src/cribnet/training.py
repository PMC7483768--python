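"""Augmentation, balanced batching, SGD training, ensembles and fold packing.

Training follows a fixed recipe: batches of 7 patches, one drawn from each
label's pool so every class is represented in every batch; on-the-fly
augmentation (flips, small rotations, scaling, translation, per-channel
intensity shifts and linear range rescaling); plain SGD with momentum 0.99
and learning rate 0.01 with per-iteration decay; no stopping criterion —
instead weights are checkpointed periodically and the checkpoint minimizing
the validation metric V(alpha) is selected afterwards.  Ensembles average
the probability maps of members that differ in training order (seed) and in
the alpha used for checkpoint selection.

Cross-validation folds are assigned by a two-pass bin-packing heuristic:
cribriform-bearing biopsies first (first-fit decreasing on cribriform region
count), then the rest so per-fold label tallies stay near uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .annotations import BiopsyRecord
from .labels import CRIBRIFORM, LabelSet
from .nn.model import NetworkConfig, SegmentationNetwork, build_network
from .objectives import LossConfig, dice_loss, specificity_loss
from .preprocess import PatchSample, pool_mask

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the on-the-fly augmentation draws."""

    flip_prob: float = 0.5                 # per axis
    translate_frac: float = 0.10           # +- fraction of image size
    rotate_deg: float = 5.0                # +- degrees about the center
    scale_range: tuple[float, float] = (0.9, 1.1)
    channel_shift: float = 0.05            # +- per-channel intensity shift
    range_min: tuple[float, float] = (0.0, 0.1)
    range_max: tuple[float, float] = (0.9, 1.0)
    fill_rgb: tuple[float, float, float] = (0.97, 0.96, 0.97)


def sample_augment_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    return {
        "flip_v": bool(rng.random() < cfg.flip_prob),
        "flip_h": bool(rng.random() < cfg.flip_prob),
        "angle_deg": float(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)),
        "scale": float(rng.uniform(*cfg.scale_range)),
        "translate": (float(rng.uniform(-cfg.translate_frac, cfg.translate_frac)),
                      float(rng.uniform(-cfg.translate_frac, cfg.translate_frac))),
        "channel_shift": tuple(rng.uniform(-cfg.channel_shift, cfg.channel_shift, 3)),
        "range_lo": float(rng.uniform(*cfg.range_min)),
        "range_hi": float(rng.uniform(*cfg.range_max)),
    }


def _affine_of(params: dict, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Output->input affine (matrix, offset) for the geometric draw.

    Forward order flip -> rotate -> scale -> translate, all about the image
    center; returns the inverse map used by ``ndimage.affine_transform``.
    """
    h, w = shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    f = np.diag([-1.0 if params["flip_v"] else 1.0,
                 -1.0 if params["flip_h"] else 1.0])
    th = np.deg2rad(params["angle_deg"])
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    s = params["scale"]
    lin = s * (r @ f)
    t = np.array([params["translate"][0] * h, params["translate"][1] * w])
    inv = np.linalg.inv(lin)
    offset = c - inv @ (c + t)
    return inv, offset


@njit(cache=True, fastmath=True)
def _warp_kernel(image, labelmap, matrix, offset, fill, fill_label,
                 out_img, out_lab):  # pragma: no cover - numba
    h, w, nc = image.shape
    m00, m01 = matrix[0, 0], matrix[0, 1]
    m10, m11 = matrix[1, 0], matrix[1, 1]
    o0, o1 = offset[0], offset[1]
    for i in range(h):
        for j in range(w):
            sr = m00 * i + m01 * j + o0
            sc = m10 * i + m11 * j + o1
            r0 = int(np.floor(sr))
            c0 = int(np.floor(sc))
            fr = sr - r0
            fc = sc - c0
            if r0 < -1 or c0 < -1 or r0 > h - 1 or c0 > w - 1:
                for ch in range(nc):
                    out_img[i, j, ch] = fill[ch]
            else:
                for ch in range(nc):
                    v = 0.0
                    for dr in range(2):
                        rr = r0 + dr
                        wr = (1.0 - fr) if dr == 0 else fr
                        for dc in range(2):
                            cc = c0 + dc
                            wc = (1.0 - fc) if dc == 0 else fc
                            if 0 <= rr < h and 0 <= cc < w:
                                v += wr * wc * image[rr, cc, ch]
                            else:
                                v += wr * wc * fill[ch]
                    out_img[i, j, ch] = v
            rn = int(np.floor(sr + 0.5))
            cn = int(np.floor(sc + 0.5))
            if 0 <= rn < h and 0 <= cn < w:
                out_lab[i, j] = labelmap[rn, cn]
            else:
                out_lab[i, j] = fill_label


def apply_geometric(params: dict, image: np.ndarray, y_full: np.ndarray,
                    cfg: AugmentConfig, non_labelled_index: int = 0,
                    labelmap: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one geometric draw to an image (bilinear) and masks (nearest)."""
    matrix, offset = _affine_of(params, image.shape[:2])
    if labelmap is None:
        labelmap = np.argmax(y_full, axis=0).astype(np.uint8)
    out = np.empty_like(image)
    warped = np.empty_like(labelmap)
    _warp_kernel(np.ascontiguousarray(image, dtype=np.float32), labelmap,
                 np.ascontiguousarray(matrix), np.ascontiguousarray(offset),
                 np.asarray(cfg.fill_rgb, dtype=np.float32),
                 np.uint8(non_labelled_index), out, warped)
    y_out = np.zeros_like(y_full)
    for l in range(y_full.shape[0]):
        y_out[l] = warped == l
    return out, y_out


def apply_photometric(params: dict, image: np.ndarray) -> np.ndarray:
    shifted = image + np.asarray(params["channel_shift"], dtype=image.dtype)
    lo, hi = params["range_lo"], params["range_hi"]
    return np.clip(lo + shifted * (hi - lo), 0.0, 1.0).astype(np.float32)


def augment(image: np.ndarray, y_full: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator, non_labelled_index: int = 0,
            labelmap: np.ndarray | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """One augmentation draw: geometry on image+masks, photometry on image only."""
    params = sample_augment_params(cfg, rng)
    img, y = apply_geometric(params, image, y_full, cfg, non_labelled_index,
                             labelmap)
    return apply_photometric(params, img), y


# --------------------------------------------------------------------------
# balanced batches

def balanced_batches(samples: list[PatchSample], labelset: LabelSet,
                     rng: np.random.Generator):
    """Infinite stream of batches with one patch drawn per label pool.

    A patch belongs to the pool of every label it contains; pools are sampled
    without replacement and reshuffled upon exhaustion, so each batch of
    size |L| contains every label at least once.
    """
    n_l = len(labelset)
    pools: dict[int, list[int]] = {l: [] for l in range(n_l)}
    for i, s in enumerate(samples):
        for l in s.labels_present:
            pools[l].append(i)
    for l in range(n_l):
        if not pools[l]:
            raise ValueError(
                f"no training patch contains label {labelset.labels[l]!r}")
    queues = {l: [] for l in range(n_l)}
    while True:
        batch = []
        for l in range(n_l):
            if not queues[l]:
                queues[l] = [pools[l][j] for j in rng.permutation(len(pools[l]))]
            batch.append(samples[queues[l].pop()])
        yield batch


# --------------------------------------------------------------------------
# SGD training with checkpoint selection

@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings."""

    learning_rate: float = 0.01
    decay: float = 5e-4
    decay_mode: str = "lr"           # "lr": lr_t = lr/(1+decay*t); "l2": weight decay
    momentum: float = 0.99
    iterations: int = 60000
    checkpoint_interval: int = 500
    alphas: tuple[float, ...] = (0.2, 0.3, 0.4, 1.0)
    epsilon: float = 1e-5
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum + 1, self.iterations + 1) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.decay_mode not in ("lr", "l2"):
            raise ValueError("decay_mode must be 'lr' or 'l2'")


@dataclass
class Checkpoint:
    iteration: int
    weights: dict[str, np.ndarray]
    dice: float
    specificity: float
    v: dict[float, float]


@dataclass
class TrainingRun:
    checkpoints: list[Checkpoint]
    log: list[dict]


class SGD:
    """SGD with classical momentum; decay either on the lr or as L2."""

    def __init__(self, net: SegmentationNetwork, cfg: TrainConfig) -> None:
        self.net = net
        self.cfg = cfg
        self.velocity = {k: np.zeros_like(v) for k, v in net.parameters().items()}

    def step(self, iteration: int) -> None:
        cfg = self.cfg
        lr = cfg.learning_rate
        if cfg.decay_mode == "lr":
            lr = lr / (1.0 + cfg.decay * iteration)
        params = self.net.parameters()
        grads = self.net.gradients()
        for k, p in params.items():
            g = grads[k]
            if g is None:
                continue
            if cfg.decay_mode == "l2":
                g = g + cfg.decay * p
            v = self.velocity[k]
            v *= cfg.momentum
            v -= lr * g.astype(v.dtype)
            p += v


def evaluate_losses(net: SegmentationNetwork, samples: list[PatchSample],
                    lcfg: LossConfig, pool_factor: int,
                    batch_size: int = 7) -> tuple[float, float]:
    """Mean Dice and specificity losses over a sample set (inference mode)."""
    tot_d = tot_s = 0.0
    n_tot = 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        x = np.stack([s.image for s in chunk])
        y = np.stack([s.y_pooled for s in chunk])
        p = net.forward(x, train=False)
        n = len(chunk)
        tot_d += dice_loss(y, p, lcfg) * n
        tot_s += specificity_loss(y, p, lcfg) * n
        n_tot += n
    return tot_d / n_tot, tot_s / n_tot


def _make_checkpoint(net: SegmentationNetwork, iteration: int,
                     val_samples: list[PatchSample], lcfg: LossConfig,
                     cfg: TrainConfig, pool_factor: int) -> Checkpoint:
    d, s = evaluate_losses(net, val_samples, lcfg, pool_factor)
    v = {a: a * d + (1.0 - a) * s for a in cfg.alphas}
    return Checkpoint(iteration=iteration, weights=net.get_weights(),
                      dice=d, specificity=s, v=v)


def train_one(net: SegmentationNetwork, train_samples: list[PatchSample],
              val_samples: list[PatchSample], cfg: TrainConfig,
              labelset: LabelSet) -> TrainingRun:
    """Train one network, checkpointing every ``checkpoint_interval`` iterations.

    The training loss is the weighted soft-Dice; V(alpha) is evaluated on the
    validation set at every checkpoint for each requested alpha.  Fully
    deterministic given (data, config, seed).
    """
    lcfg = LossConfig.from_labelset(labelset, epsilon=cfg.epsilon)
    pool_factor = net.config.input_size // net.config.output_size
    rng_batch = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rng_aug = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    batches = balanced_batches(train_samples, labelset, rng_batch)
    opt = SGD(net, cfg)
    checkpoints = [_make_checkpoint(net, 0, val_samples, lcfg, cfg, pool_factor)]
    log: list[dict] = []
    for t in range(1, cfg.iterations + 1):
        batch = next(batches)
        xs, ys = [], []
        for s in batch:
            lm = getattr(s, "_labelmap", None)
            if lm is None:
                lm = np.argmax(s.y_full, axis=0).astype(np.uint8)
                s._labelmap = lm
            img, y_full = augment(s.image, s.y_full, cfg.augment, rng_aug,
                                  labelset.non_labelled_index, labelmap=lm)
            xs.append(img)
            ys.append(pool_mask(y_full, pool_factor))
        x = np.stack(xs)
        y = np.stack(ys)
        probs = net.forward(x, train=True)
        loss, grad = dice_loss(y, probs, lcfg, return_grad=True)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {t}: loss={loss!r}")
        net.backward(grad.astype(net.dtype))
        opt.step(t - 1)
        log.append({"iteration": t, "loss": float(loss)})
        if t % cfg.checkpoint_interval == 0 or t == cfg.iterations:
            ck = _make_checkpoint(net, t, val_samples, lcfg, cfg, pool_factor)
            checkpoints.append(ck)
            logger.info("iter %d: train dice loss %.4f, val dice %.4f spec %.4f",
                        t, loss, ck.dice, ck.specificity)
    # drop duplicate final checkpoint if iterations is a multiple of interval
    seen = set()
    uniq = []
    for ck in checkpoints:
        if ck.iteration not in seen:
            uniq.append(ck)
            seen.add(ck.iteration)
    return TrainingRun(checkpoints=uniq, log=log)


def select_checkpoint(run: TrainingRun, alpha: float) -> Checkpoint:
    """Checkpoint minimizing V(alpha); ties resolved to the earliest."""
    if not run.checkpoints:
        raise ValueError("no checkpoints to select from")
    vs = [ck.v[alpha] for ck in run.checkpoints]
    return run.checkpoints[int(np.argmin(vs))]


# --------------------------------------------------------------------------
# ensembles

@dataclass
class EnsembleModel:
    """Arithmetic-mean ensemble of selected member networks."""

    config: NetworkConfig
    members: list[dict[str, np.ndarray]]
    member_info: list[dict] = field(default_factory=list)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Mean probability map over members for a patch batch (N, H, W, 3)."""
        net = SegmentationNetwork(self.config)
        acc = None
        for weights in self.members:
            net.set_weights(weights)
            p = net.forward(batch, train=False).astype(np.float64)
            acc = p if acc is None else acc + p
        return (acc / len(self.members)).astype(np.float32)

    def member_predict(self, index: int, batch: np.ndarray) -> np.ndarray:
        net = SegmentationNetwork(self.config)
        net.set_weights(self.members[index])
        return net.forward(batch, train=False)


def build_ensemble(train_samples: list[PatchSample],
                   val_samples: list[PatchSample],
                   net_config: NetworkConfig, train_config: TrainConfig,
                   labelset: LabelSet, n_repeats: int = 4,
                   alphas: tuple[float, ...] = (0.2, 0.3, 0.4, 1.0),
                   ) -> tuple[EnsembleModel, list[TrainingRun]]:
    """Train ``n_repeats`` networks and keep one checkpoint per (repeat, alpha).

    Member diversity comes from the seed-dependent training order and from
    the alpha-dependent checkpoint choice; the ensemble prediction is the
    arithmetic mean of the members' probability maps.
    """
    members: list[dict[str, np.ndarray]] = []
    info: list[dict] = []
    runs: list[TrainingRun] = []
    for r in range(n_repeats):
        seed_r = int(np.random.SeedSequence([train_config.seed, 11 + r])
                     .generate_state(1)[0] % (2 ** 31))
        cfg_r = replace(train_config, seed=seed_r,
                        alphas=tuple(sorted(set(alphas))))
        net = build_network(net_config, seed=seed_r)
        run = train_one(net, train_samples, val_samples, cfg_r, labelset)
        runs.append(run)
        for a in alphas:
            ck = select_checkpoint(run, a)
            members.append(ck.weights)
            info.append({"repeat": r, "alpha": a, "iteration": ck.iteration,
                         "v": ck.v[a]})
    return EnsembleModel(config=net_config, members=members, member_info=info), runs


# --------------------------------------------------------------------------
# fold assignment by bin packing

@dataclass
class FoldAssignment:
    """Partition of biopsies into k folds with per-fold per-label tallies."""

    folds: dict[str, int]                       # biopsy id -> fold (1..k)
    k: int
    tallies: dict[int, dict[str, int]]

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(bid for bid, f in self.folds.items() if f == fold)


def bin_pack_folds(records: list[BiopsyRecord], k: int = 8,
                   cribriform_label: str = CRIBRIFORM) -> FoldAssignment:
    """Assign biopsies to k folds, equalizing cribriform regions first.

    Pass 1: biopsies containing cribriform regions, first-fit decreasing by
    cribriform region count, always into the currently lightest fold.
    Pass 2: remaining biopsies, greedily minimizing the summed squared
    deviation of per-fold per-label region counts from the uniform targets.
    All ties break deterministically (lowest fold index, biopsy id order).
    """
    if k > len(records):
        raise ValueError(f"cannot split {len(records)} biopsies into {k} folds")
    labels = sorted({lab for r in records for lab in r.region_counts})
    totals = {lab: sum(r.count(lab) for r in records) for lab in labels}
    target = {lab: totals[lab] / k for lab in labels}
    tallies = {f: {lab: 0 for lab in labels} for f in range(1, k + 1)}
    counts_n = {f: 0 for f in range(1, k + 1)}
    folds: dict[str, int] = {}

    crib = [r for r in records if r.count(cribriform_label) > 0]
    rest = [r for r in records if r.count(cribriform_label) == 0]
    crib.sort(key=lambda r: (-r.count(cribriform_label), r.biopsy_id))
    for r in crib:
        f = min(tallies, key=lambda f_: (tallies[f_][cribriform_label], f_))
        folds[r.biopsy_id] = f
        for lab, c in r.region_counts.items():
            tallies[f][lab] += c
        counts_n[f] += 1

    rest.sort(key=lambda r: (-sum(r.region_counts.values()), r.biopsy_id))
    for r in rest:
        def cost(f_: int) -> float:
            return sum((tallies[f_][lab] + r.count(lab) - target[lab]) ** 2
                       for lab in labels) + 1e-3 * counts_n[f_]
        f = min(tallies, key=lambda f_: (cost(f_), f_))
        folds[r.biopsy_id] = f
        for lab, c in r.region_counts.items():
            tallies[f][lab] += c
        counts_n[f] += 1
    return FoldAssignment(folds=folds, k=k, tallies=tallies)
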
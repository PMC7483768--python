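"""End-to-end orchestration: data -> tiling -> training -> prediction -> curves.

The desk profile is the single-CPU counterpart of the full-scale study:
512x1536 canvases, 256-px patches (stride 128), a 3-block network with a
4x-coarse output grid, 2000 SGD iterations and a 4-member ensemble
(one repeat, four selection alphas).  The full profile keeps the original
geometry (1024-px patches, 6 blocks, 32x output) and is impractical without
GPU hardware; nothing in the code branches on the profile beyond these
configuration values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .labels import LabelSet
from .nn.model import NetworkConfig, SegmentationNetwork
from .preprocess import PatchSample, pool_mask, tile
from .evaluation import (EvaluationCurve, biopsy_roc, froc_sweep)
from .synthesis import (SynthesisConfig, SyntheticBiopsy, desk_config,
                        generate_biopsy, plan_presence)
from .training import (EnsembleModel, TrainConfig, build_ensemble)

logger = logging.getLogger(__name__)


@dataclass
class LoadedBiopsy:
    """A biopsy loaded from disk (image + rasterized masks)."""

    image: np.ndarray
    masks: np.ndarray
    biopsy_id: str = ""


@dataclass(frozen=True)
class Profile:
    """Scale-dependent defaults shared by the CLI and the study runner."""

    name: str
    patch: int
    stride: int
    network: NetworkConfig
    synthesis: SynthesisConfig
    iterations: int
    checkpoint_interval: int

    @property
    def pool_factor(self) -> int:
        return self.network.downsample_factor

    @property
    def output_pixel_um(self) -> float:
        return self.synthesis.pixel_size_um * self.pool_factor


def desk_profile(seed: int = 0) -> Profile:
    return Profile(
        name="desk", patch=256, stride=128,
        network=NetworkConfig(n_blocks=3, base_features=4, input_size=256,
                              se_reduction=4),
        synthesis=desk_config(seed=seed),
        iterations=2000, checkpoint_interval=500)


def full_profile(seed: int = 0) -> Profile:
    return Profile(
        name="full", patch=1024, stride=512,
        network=NetworkConfig(n_blocks=6, base_features=32, input_size=1024,
                              se_reduction=16),
        synthesis=SynthesisConfig(seed=seed),
        iterations=60000, checkpoint_interval=500)


def get_profile(name: str, seed: int = 0) -> Profile:
    if name == "desk":
        return desk_profile(seed)
    if name == "full":
        return full_profile(seed)
    raise ValueError(f"unknown profile {name!r} (expected 'desk' or 'full')")


# --------------------------------------------------------------------------
# in-memory dataset helpers

def subset_configs(n: int, base: SynthesisConfig, seed: int
                   ) -> list[SynthesisConfig]:
    """Per-biopsy synthesis configs with a deterministic presence plan."""
    presence = plan_presence(n, base.archetypes, seed)
    out = []
    for i in range(n):
        specs = tuple(
            replace(spec, count_range=spec.count_range if presence[i][spec.label]
                    else (0, 0))
            for spec in base.archetypes)
        child = int(np.random.SeedSequence([seed, 7919 + i]).generate_state(1)[0]
                    % (2 ** 31))
        out.append(replace(base, seed=child, archetypes=specs))
    return out


def render_subset(n: int, base: SynthesisConfig, seed: int,
                  labelset: LabelSet) -> list[SyntheticBiopsy]:
    return [generate_biopsy(cfg, labelset)
            for cfg in subset_configs(n, base, seed)]


def tile_biopsies(biopsies: list[SyntheticBiopsy], profile: Profile
                  ) -> list[PatchSample]:
    samples: list[PatchSample] = []
    for b in biopsies:
        s, _ = tile(b.image, b.masks, patch=profile.patch, stride=profile.stride,
                    pool_factor=profile.pool_factor)
        samples.extend(s)
    return samples


# --------------------------------------------------------------------------
# prediction

def predict_probability_map(net_or_weights, config: NetworkConfig,
                            image: np.ndarray, profile: Profile) -> np.ndarray:
    """Tile a biopsy, run one network, reassemble the coarse probability map.

    Discarded all-background patches contribute a non-labelled one-hot fill.
    """
    if isinstance(net_or_weights, SegmentationNetwork):
        net = net_or_weights
    else:
        net = SegmentationNetwork(config)
        net.set_weights(net_or_weights)
    h, w = image.shape[:2]
    dummy = np.zeros((config.n_classes, h, w), dtype=np.uint8)
    dummy[0] = 1
    samples, report = tile(image, dummy, patch=profile.patch,
                           stride=profile.stride,
                           pool_factor=profile.pool_factor)
    preds = []
    for i in range(0, len(samples), 7):
        chunk = samples[i:i + 7]
        batch = np.stack([s.image for s in chunk])
        p = net.forward(batch, train=False)
        preds.extend((s.origin, p[j]) for j, s in enumerate(chunk))
    fill = np.zeros(config.n_classes, dtype=np.float32)
    fill[0] = 1.0
    if not preds:   # fully background biopsy
        gh = -(-h // profile.pool_factor)
        gw = -(-w // profile.pool_factor)
        out = np.zeros((config.n_classes, gh, gw), dtype=np.float32)
        out[0] = 1.0
        return out
    from .preprocess import reassemble
    return reassemble(preds, report, fill=fill)


def ensemble_maps(ensemble: EnsembleModel, biopsies: list[SyntheticBiopsy],
                  profile: Profile, ids: list[str] | None = None
                  ) -> tuple[dict[str, np.ndarray], list[dict[str, np.ndarray]]]:
    """Per-member and mean probability maps for each biopsy.

    The ensemble map is the arithmetic mean of the member maps (reassembly is
    linear, so averaging maps equals averaging patch predictions).
    """
    ids = ids or [f"biopsy_{i:03d}" for i in range(len(biopsies))]
    member_maps: list[dict[str, np.ndarray]] = [dict() for _ in ensemble.members]
    mean_maps: dict[str, np.ndarray] = {}
    net = SegmentationNetwork(ensemble.config)
    for bid, b in zip(ids, biopsies):
        acc = None
        for m, weights in enumerate(ensemble.members):
            net.set_weights(weights)
            pm = predict_probability_map(net, ensemble.config, b.image, profile)
            member_maps[m][bid] = pm
            acc = pm.astype(np.float64) if acc is None else acc + pm
        mean_maps[bid] = (acc / len(ensemble.members)).astype(np.float32)
    return mean_maps, member_maps


# --------------------------------------------------------------------------
# evaluation helpers

def cribriform_reference(biopsies: list[SyntheticBiopsy], labelset: LabelSet,
                         ids: list[str]) -> dict[str, bool]:
    ci = labelset.cribriform_index
    return {bid: bool(b.masks[ci].any()) for bid, b in zip(ids, biopsies)}


def cribriform_annotation_masks(biopsies: list[SyntheticBiopsy],
                                labelset: LabelSet, profile: Profile,
                                ids: list[str]) -> dict[str, np.ndarray]:
    """Annotation masks pooled to the output grid (positive pooled fraction)."""
    ci = labelset.cribriform_index
    out = {}
    for bid, b in zip(ids, biopsies):
        h, w = b.masks.shape[1:]
        f = profile.pool_factor
        hc, wc = (h // f) * f, (w // f) * f
        pooled = pool_mask(b.masks[:, :hc, :wc], f)[ci]
        gh, gw = -(-h // f), -(-w // f)
        mask = np.zeros((gh, gw), dtype=bool)
        mask[:pooled.shape[0], :pooled.shape[1]] = pooled > 0
        out[bid] = mask
    return out


@dataclass
class StudyResult:
    """Everything the end-to-end study computes."""

    roc: EvaluationCurve
    froc: EvaluationCurve
    member_aucs: list[float]
    ensemble_auc: float
    reference: dict[str, bool]
    n_train_patches: int
    n_test: int
    member_info: list[dict] = field(default_factory=list)

    @property
    def mean_member_auc(self) -> float:
        return float(np.mean(self.member_aucs))


#: desk-scale minimum-region-area filter, mm^2 — chosen by the same rule as
#: the full-scale 0.0150 mm^2 filter: just below the smallest cribriform
#: archetype (radius >= 38 um -> area >= 0.0045 mm^2)
DESK_MIN_AREA_MM2 = 0.0040


def run_study(seed: int, n_train: int = 50, n_val: int = 8, n_test: int = 10,
              iterations: int = 2000, n_repeats: int = 1,
              alphas: tuple[float, ...] = (0.2, 0.3, 0.4, 1.0),
              profile: Profile | None = None,
              min_area_mm2: float = DESK_MIN_AREA_MM2) -> StudyResult:
    """Generate data, train an ensemble, predict held-out biopsies, evaluate.

    All randomness derives from ``seed``; train/validation/test sets are
    disjoint independently seeded subsets so the test prevalence matches the
    configured cribriform prevalence exactly.  The default area filter scales
    the full-resolution filter rule to desk-scale gland sizes.
    """
    labelset = LabelSet()
    profile = profile or desk_profile(seed)
    logger.info("rendering %d/%d/%d train/val/test biopsies",
                n_train, n_val, n_test)
    train_b = render_subset(n_train, profile.synthesis, seed * 3 + 1, labelset)
    val_b = render_subset(n_val, profile.synthesis, seed * 3 + 2, labelset)
    test_b = render_subset(n_test, profile.synthesis, seed * 3 + 3, labelset)
    train_s = tile_biopsies(train_b, profile)
    val_s = tile_biopsies(val_b, profile)
    del train_b, val_b      # patches reference the padded copies only
    logger.info("training on %d patches (%d validation)", len(train_s), len(val_s))

    tcfg = TrainConfig(iterations=iterations,
                       checkpoint_interval=profile.checkpoint_interval,
                       alphas=tuple(sorted(set(alphas))), seed=seed)
    ensemble, _runs = build_ensemble(train_s, val_s, profile.network, tcfg,
                                     labelset, n_repeats=n_repeats, alphas=alphas)

    ids = [f"test_{i:03d}" for i in range(n_test)]
    mean_maps, member_maps = ensemble_maps(ensemble, test_b, profile, ids)
    ci = labelset.cribriform_index
    crib_mean = {bid: m[ci] for bid, m in mean_maps.items()}
    reference = cribriform_reference(test_b, labelset, ids)
    roc = biopsy_roc(crib_mean, reference, min_area_mm2=min_area_mm2,
                     output_pixel_um=profile.output_pixel_um)
    member_aucs = []
    for mm in member_maps:
        crib_m = {bid: m[ci] for bid, m in mm.items()}
        member_aucs.append(biopsy_roc(crib_m, reference,
                                      min_area_mm2=min_area_mm2,
                                      output_pixel_um=profile.output_pixel_um).auc)
    ann_masks = cribriform_annotation_masks(test_b, labelset, profile, ids)
    froc = froc_sweep(crib_mean, ann_masks, min_area_mm2=min_area_mm2,
                      output_pixel_um=profile.output_pixel_um)
    return StudyResult(roc=roc, froc=froc, member_aucs=member_aucs,
                       ensemble_auc=roc.auc, reference=reference,
                       n_train_patches=len(train_s), n_test=n_test,
                       member_info=ensemble.member_info)
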
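"""Background masking, tiling and coarse-grid reassembly.

Tissue is separated from the white slide background through the optical
density of each RGB channel,

    OD_c = -log10(I_c / I_max),

which is near zero for unstained background.  A pixel is flagged background
when OD_c falls below a threshold (default 0.12) in *any* channel; a stricter
"all channels" reading is available behind a flag since the criterion is
ambiguous for strongly eosinophilic pixels.

Biopsies are padded with background white, subdivided into half-overlapping
square patches, and patches that are almost entirely background are discarded.
Reference masks travel with each patch both at full resolution (one-hot) and
average-pooled to the network's coarse output grid (soft, per-pixel class sums
equal to 1).  Predictions are reassembled by keeping only the central window
of each patch's output, which tiles the biopsy exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default OD threshold below which a channel reads as background
BACKGROUND_OD_THRESHOLD = 0.12
#: default background-fraction above which a patch is discarded
MAX_BACKGROUND_FRACTION = 0.995


@dataclass
class OpticalDensityMap:
    """Per-channel optical density values with the I_max used per channel."""

    od: np.ndarray          # (H, W, 3), unitless, >= 0
    i_max: np.ndarray       # (3,)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density must be finite everywhere")


def optical_density(image: np.ndarray, i_max: float | np.ndarray | None = None,
                    intensity_unit: float = 1.0 / 255.0) -> OpticalDensityMap:
    """Optical density OD_c = -log10(I_c / I_max) of an RGB image in [0, 1].

    ``i_max`` defaults to the per-channel maximum intensity of the image
    itself; pass 255/255.0 == 1.0 (or any scalar) to override.  Zero
    intensities are clamped to one 8-bit intensity unit before the log so the
    result stays finite.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if i_max is None:
        imax = img.reshape(-1, 3).max(axis=0)
    else:
        imax = np.broadcast_to(np.asarray(i_max, dtype=np.float64), (3,)).copy()
    if np.any(imax <= 0):
        raise ValueError("i_max must be positive in every channel")
    clamped = np.maximum(img, intensity_unit)
    od = -np.log10(np.minimum(clamped, imax) / imax)
    return OpticalDensityMap(od=od, i_max=imax)


def background_mask(od: OpticalDensityMap,
                    threshold: float = BACKGROUND_OD_THRESHOLD,
                    mode: str = "any") -> np.ndarray:
    """Boolean mask of background pixels: OD_c < threshold in any/all channels."""
    below = od.od < threshold
    if mode == "any":
        return below.any(axis=2)
    if mode == "all":
        return below.all(axis=2)
    raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")


def pool_mask(y_full: np.ndarray, factor: int = 32) -> np.ndarray:
    """Average-pool an (L, H, W) one-hot stack by ``factor`` in each axis.

    Each output cell is the mean of its factor x factor block, so per-cell
    class sums remain exactly 1.
    """
    y = np.asarray(y_full)
    n_l, h, w = y.shape
    if h % factor or w % factor:
        raise ValueError(f"mask size {h}x{w} not a multiple of pooling factor {factor}")
    pooled = y.reshape(n_l, h // factor, factor, w // factor, factor)
    return pooled.mean(axis=(2, 4), dtype=np.float64).astype(np.float32)


def downsample_by_factor(image: np.ndarray, factor: int = 4) -> np.ndarray:
    """Area-averaging downsample (e.g. scanner 0.23 um/px -> working 0.92 um/px)."""
    h, w = image.shape[:2]
    hc, wc = (h // factor) * factor, (w // factor) * factor
    img = image[:hc, :wc]
    if image.ndim == 3:
        blocks = img.reshape(hc // factor, factor, wc // factor, factor, -1)
        return blocks.mean(axis=(1, 3)).astype(image.dtype)
    blocks = img.reshape(hc // factor, factor, wc // factor, factor)
    return blocks.mean(axis=(1, 3)).astype(image.dtype)


@dataclass
class PatchSample:
    """One network input patch with aligned reference masks.

    ``origin`` is the (row, col) of the patch's top-left corner in the padded
    biopsy frame and always lies on the stride grid.
    """

    image: np.ndarray       # (P, P, 3) float32 in [0, 1]
    origin: tuple[int, int]
    y_full: np.ndarray      # (L, P, P) uint8 one-hot
    y_pooled: np.ndarray    # (L, P/f, P/f) float32, per-cell class sum 1
    labels_present: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        sums = self.y_pooled.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("pooled reference class sums deviate from 1")


@dataclass
class TilingReport:
    """Bookkeeping for one tiled biopsy (needed to reassemble predictions)."""

    image_shape: tuple[int, int]
    padded_shape: tuple[int, int]
    pad: int
    patch: int
    stride: int
    origins: list[tuple[int, int]] = field(default_factory=list)
    discarded: list[tuple[tuple[int, int], float]] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = [{"row": r, "col": c, "kept": True, "background_fraction": None}
                for r, c in self.origins]
        rows += [{"row": r, "col": c, "kept": False, "background_fraction": f}
                 for (r, c), f in self.discarded]
        return rows

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.to_rows()).to_csv(path, index=False)


def save_patches_npz(samples: list["PatchSample"], path) -> None:
    """Serialize patch tensors and pooled references as an NPZ archive."""
    arrays = {}
    for i, s in enumerate(samples):
        arrays[f"image_{i:04d}"] = np.ascontiguousarray(s.image)
        arrays[f"y_full_{i:04d}"] = np.ascontiguousarray(s.y_full)
        arrays[f"y_pooled_{i:04d}"] = s.y_pooled
        arrays[f"origin_{i:04d}"] = np.asarray(s.origin)
    np.savez_compressed(path, **arrays)


def load_patches_npz(path) -> list["PatchSample"]:
    with np.load(path) as data:
        n = sum(1 for k in data.files if k.startswith("image_"))
        out = []
        for i in range(n):
            y_full = data[f"y_full_{i:04d}"]
            present = tuple(int(l) for l in range(y_full.shape[0])
                            if y_full[l].any())
            out.append(PatchSample(
                image=data[f"image_{i:04d}"],
                origin=tuple(int(v) for v in data[f"origin_{i:04d}"]),
                y_full=y_full, y_pooled=data[f"y_pooled_{i:04d}"],
                labels_present=present))
    return out


def pad_to_grid(image: np.ndarray, masks: np.ndarray | None, patch: int, stride: int,
                non_labelled_index: int = 0,
                background_rgb: tuple[float, float, float] = (1.0, 1.0, 1.0),
                ) -> tuple[np.ndarray, np.ndarray | None, int, tuple[int, int]]:
    """Pad with background white by patch/4 on all sides, then to the stride grid.

    The patch/4 margin guarantees every tissue pixel lies inside the central
    window of some patch; the final right/bottom padding makes the patch grid
    cover the image exactly.
    """
    pad = patch // 4
    h, w = image.shape[:2]

    def grid_extra(size: int) -> int:
        padded = size + 2 * pad
        if padded < patch:
            return patch - padded
        rem = (padded - patch) % stride
        return (stride - rem) % stride

    eh, ew = grid_extra(h), grid_extra(w)
    img = np.pad(image, ((pad, pad + eh), (pad, pad + ew), (0, 0)), mode="constant")
    for c in range(3):
        img[..., c][np.pad(np.zeros((h, w), bool), ((pad, pad + eh), (pad, pad + ew)),
                           constant_values=True)] = background_rgb[c]
    padded_masks = None
    if masks is not None:
        padded_masks = np.pad(masks, ((0, 0), (pad, pad + eh), (pad, pad + ew)),
                              mode="constant")
        border = np.pad(np.zeros((h, w), bool), ((pad, pad + eh), (pad, pad + ew)),
                        constant_values=True)
        padded_masks[non_labelled_index][border] = 1
    return img, padded_masks, pad, img.shape[:2]


def tile(image: np.ndarray, masks: np.ndarray, patch: int = 1024,
         stride: int | None = None, pool_factor: int = 32,
         max_background: float = MAX_BACKGROUND_FRACTION,
         od_threshold: float = BACKGROUND_OD_THRESHOLD, od_mode: str = "any",
         i_max: float | np.ndarray | None = None,
         non_labelled_index: int = 0, pad: bool = True,
         min_label_fraction: float = 0.01,
         ) -> tuple[list[PatchSample], TilingReport]:
    """Subdivide a biopsy into half-overlapping patches with reference masks.

    Patches whose background fraction exceeds ``max_background`` (strictly)
    are discarded.  The background mask is computed once on the padded image
    so that I_max is a per-biopsy, per-channel quantity.  With ``pad=False``
    the image is tiled as-is (dimensions must be at least one patch).

    ``labels_present`` (which feeds the balanced-batch label pools) lists a
    gland class only when it covers at least ``min_label_fraction`` of the
    patch, so a patch grazing a gland corner does not stand in for that
    class during training; the non-labelled class is always listed.
    """
    stride = stride or patch // 2
    h, w = image.shape[:2]
    if pad:
        img, pmasks, padding, (ph, pw) = pad_to_grid(image, masks, patch, stride,
                                                     non_labelled_index)
    else:
        if h < patch or w < patch:
            raise ValueError("unpadded image smaller than one patch")
        img, pmasks, padding, (ph, pw) = image, masks, 0, (h, w)
    od = optical_density(img, i_max=i_max)
    bg = background_mask(od, threshold=od_threshold, mode=od_mode)
    report = TilingReport(image_shape=(h, w), padded_shape=(ph, pw), pad=padding,
                          patch=patch, stride=stride)
    samples: list[PatchSample] = []
    for r in range(0, ph - patch + 1, stride):
        for c in range(0, pw - patch + 1, stride):
            frac = float(bg[r:r + patch, c:c + patch].mean())
            if frac > max_background:
                report.discarded.append(((r, c), frac))
                continue
            y_full = pmasks[:, r:r + patch, c:c + patch]
            y_pooled = pool_mask(y_full, pool_factor)
            min_px = min_label_fraction * patch * patch
            counts = y_full.reshape(y_full.shape[0], -1).sum(axis=1)
            present = tuple(int(l) for l in range(y_full.shape[0])
                            if counts[l] >= min_px or l == non_labelled_index)
            # image and y_full are views into the padded arrays; consumers
            # (augmentation, network input) copy to contiguous buffers
            samples.append(PatchSample(
                image=img[r:r + patch, c:c + patch].astype(np.float32,
                                                           copy=False),
                origin=(r, c), y_full=y_full,
                y_pooled=y_pooled, labels_present=present))
            report.origins.append((r, c))
    return samples, report


def reassemble(patch_predictions: list[tuple[tuple[int, int], np.ndarray]],
               report: TilingReport, fill: np.ndarray | None = None) -> np.ndarray:
    """Stitch per-patch coarse outputs into one biopsy probability map.

    Each patch contributes only the central half-size window of its output,
    so every output pixel is sourced from exactly one patch.  ``fill`` (an
    (L,) probability vector) stands in for patches that were discarded as
    background; without it a missing patch raises an error naming its origin.
    Returns an (L, H/f, W/f) map cropped back to the unpadded extent.
    """
    if not patch_predictions:
        raise ValueError("no patch predictions given")
    out = np.asarray(patch_predictions[0][1])
    n_l, po, _ = out.shape
    factor = report.patch // po
    if report.stride % factor or report.pad % factor:
        raise ValueError("stride and pad must be multiples of the output factor")
    ph, pw = report.padded_shape
    gh, gw = ph // factor, pw // factor
    lo, hi = po // 4, po // 4 + po // 2      # central window rows/cols
    grid = np.empty((n_l, gh, gw), dtype=np.float32)
    covered = np.zeros((gh, gw), dtype=bool)
    if fill is not None:
        grid[:] = np.asarray(fill, dtype=np.float32)[:, None, None]
        covered[:] = True
    by_origin = {tuple(o): np.asarray(p) for o, p in patch_predictions}
    for r in range(0, ph - report.patch + 1, report.stride):
        for c in range(0, pw - report.patch + 1, report.stride):
            gr, gc = r // factor, c // factor
            pred = by_origin.get((r, c))
            if pred is None:
                if fill is None:
                    raise ValueError(f"missing prediction for patch at origin {(r, c)}")
                continue
            grid[:, gr + lo:gr + hi, gc + lo:gc + hi] = pred[:, lo:hi, lo:hi]
            covered[gr + lo:gr + hi, gc + lo:gc + hi] = True
    h, w = report.image_shape
    p = report.pad // factor
    ch, cw = -(-h // factor), -(-w // factor)
    if not covered[p:p + ch, p:p + cw].all():
        raise ValueError("patch grid does not cover the biopsy extent")
    return grid[:, p:p + ch, p:p + cw]
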
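"""Region-based evaluation of cribriform probability maps.

Predicted cribriform pixels (probability strictly greater than a cut-off)
are grouped into connected regions on the coarse output grid; regions can be
filtered by physical area (strictly larger than a minimum, in mm^2).  Two
complementary analyses sweep the cut-off:

* biopsy-wise ROC — a biopsy is reference-positive if it carries at least one
  cribriform annotation, prediction-positive if at least one (qualifying)
  predicted region exists; AUC by the trapezoid rule.
* annotation-wise FROC — an annotated cribriform region counts as detected
  when at least one pixel of a predicted region overlaps it; the x axis is
  the mean number of non-overlapping (false-positive) predicted regions per
  biopsy.

The default output grid inherits the working resolution times the network's
downsampling factor: 32 x 0.92 um = 29.44 um per output pixel, i.e.
8.6677e-4 mm^2 per output pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

#: output-grid pixel pitch of the full-scale network, micrometres
DEFAULT_OUTPUT_PIXEL_UM = 32 * 0.92


def _pixel_area_mm2(output_pixel_um: float) -> float:
    return (output_pixel_um * 1e-3) ** 2


@dataclass
class DetectionRegion:
    """A connected component of supra-threshold cribriform probability."""

    pixels: np.ndarray          # (n, 2) (row, col) on the output grid
    area_mm2: float
    max_prob: float
    mean_prob: float
    biopsy_id: str = ""

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def extract_regions(prob_map: np.ndarray, cutoff: float, connectivity: int = 8,
                    min_area_mm2: float = 0.0,
                    output_pixel_um: float = DEFAULT_OUTPUT_PIXEL_UM,
                    biopsy_id: str = "") -> list[DetectionRegion]:
    """Connected regions of pixels with probability > cutoff.

    ``connectivity`` is 4 or 8; regions whose area is not strictly larger
    than ``min_area_mm2`` are removed when the filter is positive.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    mask = np.asarray(prob_map) > cutoff
    labeled, n = ndimage.label(mask, structure=structure)
    px_area = _pixel_area_mm2(output_pixel_um)
    regions: list[DetectionRegion] = []
    for obj_i, sl in enumerate(ndimage.find_objects(labeled), start=1):
        comp = labeled[sl] == obj_i
        area = float(comp.sum()) * px_area
        if min_area_mm2 > 0.0 and area <= min_area_mm2:
            continue
        rr, cc = np.nonzero(comp)
        probs = np.asarray(prob_map)[sl][comp]
        regions.append(DetectionRegion(
            pixels=np.stack([rr + sl[0].start, cc + sl[1].start], axis=1),
            area_mm2=area, max_prob=float(probs.max()),
            mean_prob=float(probs.mean()), biopsy_id=biopsy_id))
    return regions


def qualifying_score(prob_map: np.ndarray, min_area_mm2: float = 0.0,
                     connectivity: int = 8,
                     output_pixel_um: float = DEFAULT_OUTPUT_PIXEL_UM) -> float:
    """Largest threshold t such that {p >= t} still contains a qualifying region.

    A biopsy is prediction-positive at cut-off c exactly when this score is
    strictly greater than c, so sweeping cut-offs reduces to ranking scores.
    Returns 0.0 when no threshold qualifies.
    """
    p = np.asarray(prob_map, dtype=np.float64)
    uniq = np.unique(p)
    uniq = uniq[uniq > 0.0]
    if uniq.size == 0:
        return 0.0
    px_area = _pixel_area_mm2(output_pixel_um)
    if min_area_mm2 <= 0.0:
        return float(uniq[-1])
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)

    def qualifies(t: float) -> bool:
        labeled, n = ndimage.label(p >= t, structure=structure)
        if n == 0:
            return False
        counts = np.bincount(labeled.ravel())[1:]
        return bool((counts * px_area > min_area_mm2).any())

    lo_i, hi_i = 0, uniq.size - 1
    if not qualifies(uniq[lo_i]):
        return 0.0
    # binary search for the largest qualifying threshold (monotone in t)
    while lo_i < hi_i:
        mid = (lo_i + hi_i + 1) // 2
        if qualifies(uniq[mid]):
            lo_i = mid
        else:
            hi_i = mid - 1
    return float(uniq[lo_i])


@dataclass
class EvaluationCurve:
    """Operating points of a ROC or FROC sweep (cutoffs strictly decreasing)."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    x: np.ndarray                  # FPR (ROC) or mean FP regions/biopsy (FROC)
    auc: float | None = None
    kind: str = "roc"

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=np.float64)
        self.sensitivity = np.asarray(self.sensitivity, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        if np.any(np.diff(self.cutoffs) >= 0):
            raise ValueError("cutoffs must be strictly decreasing")
        if np.any(np.diff(self.sensitivity) < -1e-12):
            raise ValueError("sensitivity must be non-decreasing along the sweep")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs,
                             "sensitivity": self.sensitivity,
                             "x": self.x})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sensitivity_at(self, max_x: float) -> float:
        """Highest sensitivity among operating points with x <= max_x."""
        ok = self.x <= max_x
        return float(self.sensitivity[ok].max()) if ok.any() else 0.0


def biopsy_roc(prob_maps: dict[str, np.ndarray], reference: dict[str, bool],
               min_area_mm2: float = 0.0, connectivity: int = 8,
               output_pixel_um: float = DEFAULT_OUTPUT_PIXEL_UM
               ) -> EvaluationCurve:
    """Biopsy-wise ROC over cribriform probability cut-offs.

    Reference-positive: the biopsy has >= 1 cribriform annotation.
    Prediction-positive at cut-off c: >= 1 predicted region passing the area
    filter.  AUC by trapezoid over (FPR, sensitivity).
    """
    ids = sorted(prob_maps)
    flags = np.array([bool(reference[i]) for i in ids])
    n_pos, n_neg = int(flags.sum()), int((~flags).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative biopsy")
    scores = np.array([qualifying_score(prob_maps[i], min_area_mm2, connectivity,
                                        output_pixel_um) for i in ids])
    cutoffs = np.concatenate([[1.0], np.unique(scores)[::-1], [0.0]])
    cutoffs = np.unique(cutoffs)[::-1]
    sens, fpr = [], []
    for c in cutoffs:
        pred = scores > c
        sens.append((pred & flags).sum() / n_pos)
        fpr.append((pred & ~flags).sum() / n_neg)
    sens_arr, fpr_arr = np.array(sens), np.array(fpr)
    order = np.argsort(fpr_arr, kind="stable")
    auc = float(np.trapezoid(sens_arr[order], fpr_arr[order]))
    return EvaluationCurve(cutoffs=cutoffs, sensitivity=sens_arr, x=fpr_arr,
                           auc=auc, kind="roc")


def annotation_froc(detections_per_cutoff: dict[float, list[DetectionRegion]],
                    annotations: list[tuple[str, np.ndarray]],
                    n_biopsies: int) -> EvaluationCurve:
    """FROC from per-cutoff detections against annotated cribriform regions.

    ``annotations`` holds (biopsy_id, boolean mask on the output grid) pairs.
    A detection overlapping no annotation of its biopsy is a false positive;
    sensitivity is the fraction of annotations hit by >= 1 detection pixel.
    """
    if not annotations:
        raise ValueError("FROC needs at least one cribriform annotation")
    if n_biopsies < 1:
        raise ValueError("n_biopsies must be >= 1")
    cutoffs = sorted(detections_per_cutoff, reverse=True)
    sens, fp_rate = [], []
    for c in cutoffs:
        dets = detections_per_cutoff[c]
        hit = 0
        for bid, mask in annotations:
            ann_hit = any(
                d.biopsy_id == bid and mask[d.pixels[:, 0], d.pixels[:, 1]].any()
                for d in dets)
            hit += bool(ann_hit)
        fp = 0
        for d in dets:
            overlaps = any(bid == d.biopsy_id
                           and mask[d.pixels[:, 0], d.pixels[:, 1]].any()
                           for bid, mask in annotations)
            fp += not overlaps
        sens.append(hit / len(annotations))
        fp_rate.append(fp / n_biopsies)
    return EvaluationCurve(cutoffs=np.asarray(cutoffs, dtype=np.float64),
                           sensitivity=np.array(sens), x=np.array(fp_rate),
                           auc=None, kind="froc")


def froc_sweep(prob_maps: dict[str, np.ndarray],
               annotation_masks: dict[str, np.ndarray],
               cutoffs: np.ndarray | None = None,
               min_area_mm2: float = 0.0, connectivity: int = 8,
               output_pixel_um: float = DEFAULT_OUTPUT_PIXEL_UM
               ) -> EvaluationCurve:
    """Convenience FROC: label annotation masks, extract detections, sweep.

    ``annotation_masks`` maps biopsy id to a boolean cribriform-annotation
    mask on the output grid (a cell is annotated when its pooled cribriform
    fraction is positive).  Each connected annotation component counts as one
    annotation.
    """
    annotations: list[tuple[str, np.ndarray]] = []
    structure = ndimage.generate_binary_structure(2, 2)
    for bid in sorted(annotation_masks):
        labeled, n = ndimage.label(annotation_masks[bid], structure=structure)
        for i in range(1, n + 1):
            annotations.append((bid, labeled == i))
    if cutoffs is None:
        vals = np.unique(np.concatenate(
            [np.unique(m) for m in prob_maps.values()]))
        vals = vals[(vals >= 0) & (vals < 1)]
        if vals.size > 64:          # thin dense sweeps deterministically
            vals = vals[np.linspace(0, vals.size - 1, 64).astype(int)]
        cutoffs = np.unique(np.concatenate([vals, [0.0125, 0.1, 0.5]]))
    dets: dict[float, list[DetectionRegion]] = {}
    for c in np.asarray(cutoffs, dtype=np.float64):
        dets[float(c)] = [
            r for bid in sorted(prob_maps)
            for r in extract_regions(prob_maps[bid], float(c), connectivity,
                                     min_area_mm2, output_pixel_um, biopsy_id=bid)]
    return annotation_froc(dets, annotations, n_biopsies=len(prob_maps))


def contour_decision(prob_map: np.ndarray, contour_mask: np.ndarray,
                     cutoff: float) -> bool:
    """Cribriform call restricted to a delineated contour.

    True iff any output pixel inside the contour has probability strictly
    greater than the cut-off; predictions outside the contour are discarded.
    """
    contour = np.asarray(contour_mask, dtype=bool)
    if not contour.any():
        raise ValueError("contour mask is empty")
    return bool((np.asarray(prob_map)[contour] > cutoff).any())


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa with marginal-product chance agreement.

    Defined as 1.0 in the degenerate case p_e = 1 (both raters constant and
    in full agreement).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two rated items")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float((a == b).mean())
    p_e = float(sum((a == c).mean() * (b == c).mean() for c in cats))
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def overlay_rgba(annotation_mask: np.ndarray, detection_mask: np.ndarray
                 ) -> np.ndarray:
    """RGBA overlay: light blue TP, green FN, dark blue FP (transparent elsewhere)."""
    ann = np.asarray(annotation_mask, dtype=bool)
    det = np.asarray(detection_mask, dtype=bool)
    out = np.zeros(ann.shape + (4,), dtype=np.uint8)
    out[ann & det] = (90, 200, 250, 160)     # true positive
    out[ann & ~det] = (60, 180, 75, 160)     # false negative
    out[~ann & det] = (0, 60, 160, 160)      # false positive
    return out
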
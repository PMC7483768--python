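"""Procedural generation of H&E-like needle-biopsy images with exact masks.

The generator emits an elongated tissue strip on a white background and
populates it with geometric caricatures of the six annotated growth patterns
plus non-labelled stroma.  Realism is explicitly not the goal: archetypes are
distinguishable by *morphology only* (sieve vs. ring vs. chain vs. tuft), the
epithelial palette being shared across all gland classes so that mean color
carries no class information and a classifier must attend to structure.

Archetype geometry:

* ``G3``             - small gland, one central round lumen, thin epithelial ring
* ``G4 fused``       - elongated mass, a chain of 2-4 medium lumina (merged rings)
* ``G4 ill-defined`` - diffuse epithelial blotches with nuclear clusters, no lumina
* ``G4 complex fused`` - large branched mass with irregular elongated slit lumina
* ``G4 glomeruloid`` - one large lumen containing an attached internal tuft
* ``G4 cribriform``  - one epithelial blob perforated by >= 3 small round lumina

Every placed archetype contributes one polygonal
:class:`~cribnet.annotations.AnnotationRegion`; the returned class masks are
produced by rasterizing exactly those polygons, so mask/annotation agreement
is exact by construction.  All randomness flows from the config seed and the
output is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import (AnnotationRegion, BiopsyRecord, save_image,
                          save_manifest, save_mask_png, rasterize_annotations,
                          write_annotations)
from .labels import CRIBRIFORM, LabelSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Geometry and abundance of one growth-pattern archetype."""

    label: str
    count_range: tuple[int, int]          # glands per biopsy, when present
    radius_um_range: tuple[float, float]  # characteristic gland radius
    lumina_range: tuple[int, int]         # lumina per gland
    fusion_degree: float = 0.0            # 0..1, elongation of the mass
    nuclear_density: float = 9.0          # nuclei per 1000 um^2 of epithelium
    presence_prob: float = 1.0            # fraction of biopsies containing it

    def __post_init__(self) -> None:
        if self.label == CRIBRIFORM and self.lumina_range[0] < 3:
            raise ValueError("cribriform glands must have at least 3 lumina")
        if self.label == "G3" and self.fusion_degree != 0.0:
            raise ValueError("G3 glands are not fused")
        for rng_ in (self.count_range, self.radius_um_range, self.lumina_range):
            if rng_[1] < rng_[0]:
                raise ValueError(f"empty range {rng_} in archetype {self.label}")


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """The study-condition archetype mix.

    Biopsies emulate tumor-dense needle cores (the clinical selection is the
    biopsy with the most tumor volume, containing mainly G3/G4 carcinoma),
    so glands pack much of the strip; cribriform archetypes appear in ~35%
    of biopsies.
    """
    return (
        ArchetypeSpec("G3", (4, 7), (18.0, 28.0), (1, 1), 0.0, 9.0, 0.9),
        ArchetypeSpec("G4 fused", (2, 4), (26.0, 38.0), (2, 4), 0.7, 9.0, 0.8),
        ArchetypeSpec("G4 ill-defined", (2, 4), (20.0, 32.0), (0, 0), 0.3, 6.0, 0.8),
        ArchetypeSpec("G4 complex fused", (1, 3), (36.0, 52.0), (4, 7), 0.8, 9.0, 0.7),
        ArchetypeSpec("G4 glomeruloid", (1, 3), (24.0, 34.0), (1, 1), 0.0, 9.0, 0.7),
        ArchetypeSpec("G4 cribriform", (1, 3), (38.0, 55.0), (6, 10), 0.2, 9.0, 0.35),
    )


@dataclass(frozen=True)
class HEColorModel:
    """Shared H&E palette; all values in [0, 1] RGB."""

    hematoxylin_rgb: tuple[float, float, float] = (0.32, 0.22, 0.52)
    eosin_rgb: tuple[float, float, float] = (0.64, 0.48, 0.62)
    epithelium_rgb: tuple[float, float, float] = (0.58, 0.45, 0.63)
    lumen_rgb: tuple[float, float, float] = (0.95, 0.94, 0.96)
    background_rgb: tuple[float, float, float] = (0.97, 0.96, 0.97)
    noise_amplitude: float = 0.02

    def __post_init__(self) -> None:
        for name in ("hematoxylin_rgb", "eosin_rgb", "epithelium_rgb",
                     "lumen_rgb", "background_rgb"):
            if not all(0.0 <= v <= 1.0 for v in getattr(self, name)):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SynthesisConfig:
    """Everything :func:`generate_biopsy` needs; deterministic given ``seed``."""

    seed: int = 0
    canvas: tuple[int, int] = (2048, 6144)      # (H, W) px
    pixel_size_um: float = 0.92
    strip_width_um: float = 800.0
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    colors: HEColorModel = field(default_factory=HEColorModel)
    max_place_tries: int = 600

    def __post_init__(self) -> None:
        strip_px = self.strip_width_um / self.pixel_size_um
        if strip_px > self.canvas[0] * 0.9:
            raise ValueError("canvas too small for the requested tissue strip")


def desk_config(seed: int = 0, **overrides) -> SynthesisConfig:
    """Scaled-down biopsy used for single-CPU training and the test suite."""
    kwargs = dict(seed=seed, canvas=(512, 1536), strip_width_um=330.0)
    kwargs.update(overrides)
    return SynthesisConfig(**kwargs)


@dataclass
class SyntheticBiopsy:
    """Output of :func:`generate_biopsy`."""

    image: np.ndarray                  # (H, W, 3) float32 in [0, 1]
    masks: np.ndarray                  # (L, H, W) uint8 one-hot
    regions: list[AnnotationRegion]
    strip_mask: np.ndarray             # tissue strip footprint (bool)
    tissue_mask: np.ndarray            # stained pixels (strip minus lumina)
    bright_mask: np.ndarray            # unstained pixels inside the strip
    config: SynthesisConfig


# --------------------------------------------------------------------------
# geometry helpers

def _blob_polygon(rng: np.random.Generator, center: np.ndarray, radius_px: float,
                  elongation: float, angle: float, n_vertices: int = 48,
                  jitter: float = 0.07) -> np.ndarray:
    """Smooth star-convex outline: low-frequency radial perturbation of a disk,
    anisotropically scaled for fused morphologies."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, radius_px)
    for k in range(2, 6):
        amp = rng.uniform(0.0, jitter) * radius_px
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rows = r * np.sin(theta)
    cols = r * np.cos(theta) * (1.0 + elongation)
    ca, sa = np.cos(angle), np.sin(angle)
    rot_rows = rows * ca + cols * sa
    rot_cols = -rows * sa + cols * ca
    return np.stack([center[0] + rot_rows, center[1] + rot_cols], axis=1)


def _disk_mask(shape: tuple[int, int], center: np.ndarray, radius: float,
               aspect: float = 1.0, angle: float = 0.0) -> np.ndarray:
    h, w = shape
    r0 = max(0, int(center[0] - radius * (1 + aspect)) - 2)
    r1 = min(h, int(center[0] + radius * (1 + aspect)) + 3)
    c0 = max(0, int(center[1] - radius * (1 + aspect)) - 2)
    c1 = min(w, int(center[1] + radius * (1 + aspect)) + 3)
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    out[r0:r1, c0:c1] = (u / radius) ** 2 + (v / (radius * aspect)) ** 2 <= 1.0
    return out


def _paint(image: np.ndarray, mask: np.ndarray, color, alpha: float = 1.0) -> None:
    col = np.asarray(color, dtype=np.float32)
    image[mask] = (1.0 - alpha) * image[mask] + alpha * col


def _stamp_nuclei(image: np.ndarray, candidate_idx: np.ndarray, n_nuclei: int,
                  rng: np.random.Generator, color, pixel_size_um: float,
                  elongated: bool = False) -> None:
    """Render anti-aliased elliptical nuclei at random candidate pixels."""
    if n_nuclei <= 0 or len(candidate_idx) == 0:
        return
    h, w = image.shape[:2]
    picks = rng.integers(0, len(candidate_idx), n_nuclei)
    base = np.asarray(color, dtype=np.float32)
    for p in picks:
        cr, cc = candidate_idx[p]
        a = rng.uniform(1.8, 2.6) / pixel_size_um       # semi-major, px
        b = rng.uniform(1.1, 1.6) / pixel_size_um
        if elongated:
            a *= rng.uniform(1.8, 2.6)
            b *= 0.8
        ang = rng.uniform(0, np.pi)
        jit = rng.uniform(-0.04, 0.04, 3).astype(np.float32)
        ext = int(np.ceil(a)) + 1
        r0, r1 = max(0, cr - ext), min(h, cr + ext + 1)
        c0, c1 = max(0, cc - ext), min(w, cc + ext + 1)
        rr, cc2 = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        dr, dc = rr - cr, cc2 - cc
        ca, sa = np.cos(ang), np.sin(ang)
        u = (dr * ca + dc * sa) / a
        v = (-dr * sa + dc * ca) / b
        d = np.sqrt(u * u + v * v)
        alpha = np.clip(2.5 * (1.0 - d), 0.0, 1.0)[..., None].astype(np.float32)
        patch = image[r0:r1, c0:c1]
        image[r0:r1, c0:c1] = patch * (1 - alpha) + (base + jit) * alpha


# --------------------------------------------------------------------------
# main generator

def _strip_geometry(cfg: SynthesisConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wavy horizontal band: per-column centerline and half-width (px)."""
    h, w = cfg.canvas
    half = 0.5 * cfg.strip_width_um / cfg.pixel_size_um
    x = np.arange(w)
    center = h / 2.0 + 0.08 * h * np.sin(2 * np.pi * x / rng.uniform(0.8, 1.4) / w
                                         + rng.uniform(0, 2 * np.pi))
    center += 0.03 * h * np.sin(2 * np.pi * x / rng.uniform(0.2, 0.35) / w
                                + rng.uniform(0, 2 * np.pi))
    width = half * (1.0 + 0.12 * np.sin(2 * np.pi * x / rng.uniform(0.3, 0.6) / w
                                        + rng.uniform(0, 2 * np.pi)))
    lo = np.clip(center - width, 2, h - 3)
    hi = np.clip(center + width, 2, h - 3)
    rows = np.arange(h)[:, None]
    strip = (rows >= lo[None, :]) & (rows <= hi[None, :])
    return strip, lo, hi


def _place_glands(cfg: SynthesisConfig, rng: np.random.Generator,
                  lo: np.ndarray, hi: np.ndarray,
                  counts: dict[str, int]) -> list[dict]:
    """Rejection-sample non-overlapping gland sites inside the strip."""
    placed: list[dict] = []
    order = sorted(cfg.archetypes, key=lambda s: -s.radius_um_range[1])
    h, w = cfg.canvas
    for spec in order:
        for _ in range(counts.get(spec.label, 0)):
            radius_um = rng.uniform(*spec.radius_um_range)
            radius = radius_um / cfg.pixel_size_um
            eff = radius * (1.0 + spec.fusion_degree) * 1.12
            ok = False
            for _try in range(cfg.max_place_tries):
                cc = rng.uniform(eff + 2, w - eff - 2)
                col = int(cc)
                gap = hi[col] - lo[col]
                if gap < 2 * eff * 0.85:
                    continue
                span_lo = lo[col] + eff * 0.8
                span_hi = hi[col] - eff * 0.8
                if span_hi <= span_lo:
                    continue
                cr = rng.uniform(span_lo, span_hi)
                if any(np.hypot(cr - g["center"][0], cc - g["center"][1])
                       < 1.01 * (eff + g["eff"]) for g in placed):
                    continue
                placed.append({"spec": spec, "center": np.array([cr, cc]),
                               "radius": radius, "eff": eff,
                               "angle": rng.uniform(0, np.pi)})
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place archetype {spec.label!r} on the canvas; "
                    "reduce counts or enlarge the canvas/strip")
    return placed


def _render_gland(image: np.ndarray, gland: dict, epi_mask: np.ndarray,
                  cfg: SynthesisConfig, rng: np.random.Generator,
                  bright: np.ndarray) -> None:
    """Draw one gland: shared epithelial palette, archetype-specific lumina."""
    colors = cfg.colors
    spec: ArchetypeSpec = gland["spec"]
    center = gland["center"]
    radius = gland["radius"]
    angle = gland["angle"]
    px = cfg.pixel_size_um

    diffuse = spec.lumina_range == (0, 0) and spec.label == "G4 ill-defined"
    if diffuse:
        # blotchy, partially transparent epithelium without lumina
        blotch = gaussian_filter(rng.standard_normal(image.shape[:2]), 6.0)
        soft = epi_mask & (blotch > np.quantile(blotch[epi_mask], 0.25)
                           if epi_mask.any() else epi_mask)
        _paint(image, epi_mask, colors.epithelium_rgb, alpha=0.45)
        _paint(image, soft, colors.epithelium_rgb, alpha=0.55)
    else:
        _paint(image, epi_mask, colors.epithelium_rgb, alpha=1.0)

    # ---- lumina ----------------------------------------------------------
    n_lum = int(rng.integers(spec.lumina_range[0], spec.lumina_range[1] + 1))
    lumina = np.zeros(image.shape[:2], dtype=bool)
    tuft = np.zeros_like(lumina)
    if spec.label == "G3" and n_lum:
        lum_r = radius * rng.uniform(0.40, 0.52)
        lumina |= _disk_mask(lumina.shape, center, lum_r)
    elif spec.label == "G4 glomeruloid" and n_lum:
        lum_r = radius * rng.uniform(0.55, 0.68)
        lumen = _disk_mask(lumina.shape, center, lum_r)
        lumina |= lumen
        # internal tuft attached to the lumen wall
        off = lum_r * 0.45
        tdir = rng.uniform(0, 2 * np.pi)
        tcenter = center + off * np.array([np.sin(tdir), np.cos(tdir)])
        tuft = _disk_mask(lumina.shape, tcenter, lum_r * 0.5) & lumen
    elif spec.label == "G4 cribriform":
        # sieve: many small round perforations scattered through the mass
        lum_r0 = max(3.2 / px, radius * 0.085)
        placed_l: list[np.ndarray] = []
        tries = 0
        while len(placed_l) < n_lum and tries < 500:
            tries += 1
            rad = lum_r0 * rng.uniform(0.85, 1.2)
            rho = rng.uniform(0, radius * 0.75)
            th = rng.uniform(0, 2 * np.pi)
            cand = center + rho * np.array([np.sin(th),
                                            np.cos(th) * (1 + spec.fusion_degree)])
            if any(np.hypot(*(cand - q)) < 2.3 * lum_r0 for q in placed_l):
                continue
            placed_l.append(cand)
            lumina |= _disk_mask(lumina.shape, cand, rad)
        if len(placed_l) < 3:  # sieve guarantee
            for k in range(3 - len(placed_l)):
                cand = center + radius * 0.35 * np.array(
                    [np.sin(2.1 * k), np.cos(2.1 * k)])
                lumina |= _disk_mask(lumina.shape, cand, lum_r0)
    elif spec.label in ("G4 fused", "G4 complex fused") and n_lum:
        # chain of merged rings along the elongation axis; lumina markedly
        # larger than the cribriform perforations
        axis = np.array([np.sin(angle), np.cos(angle)])
        perp = np.array([np.cos(angle), -np.sin(angle)])
        span = radius * (1 + spec.fusion_degree) * 0.70
        offsets = np.linspace(-span, span, n_lum)
        for k, off in enumerate(offsets):
            wobble = perp * rng.uniform(-0.18, 0.18) * radius
            cl = center + axis * off * rng.uniform(0.85, 1.1) + wobble
            if spec.label == "G4 fused":
                lum_r = radius * rng.uniform(0.28, 0.38)
                lumina |= _disk_mask(lumina.shape, cl, lum_r)
            else:
                # complex fused: irregular elongated slits, varied orientation
                lum_r = radius * rng.uniform(0.10, 0.15)
                lumina |= _disk_mask(lumina.shape, cl, lum_r,
                                     aspect=rng.uniform(2.6, 4.0),
                                     angle=rng.uniform(0, np.pi))
    lumina &= epi_mask
    tuft &= epi_mask
    shown_lumina = lumina & ~tuft
    _paint(image, shown_lumina, colors.lumen_rgb, alpha=1.0)
    bright |= shown_lumina

    # ---- nuclei ----------------------------------------------------------
    epi_visible = epi_mask & ~shown_lumina
    idx = np.argwhere(epi_visible)
    area_um2 = len(idx) * px * px
    n_nuc = int(round(spec.nuclear_density * area_um2 / 1000.0))
    _stamp_nuclei(image, idx, n_nuc, rng, colors.hematoxylin_rgb, px)


def generate_biopsy(config: SynthesisConfig,
                    labelset: LabelSet | None = None) -> SyntheticBiopsy:
    """Render one synthetic biopsy with pixel-exact reference masks."""
    labelset = labelset or LabelSet()
    rng = np.random.default_rng(config.seed)
    h, w = config.canvas
    colors = config.colors

    strip, lo, hi = _strip_geometry(config, rng)

    # archetype counts for this biopsy (presence handled by the caller or here)
    counts: dict[str, int] = {}
    for spec in config.archetypes:
        if spec.count_range[1] == 0:
            counts[spec.label] = 0
        else:
            counts[spec.label] = int(rng.integers(spec.count_range[0],
                                                  spec.count_range[1] + 1))
    glands = _place_glands(config, rng, lo, hi, counts)

    # regions + exact masks ------------------------------------------------
    regions: list[AnnotationRegion] = []
    for g in glands:
        poly = _blob_polygon(rng, g["center"], g["radius"],
                             g["spec"].fusion_degree, g["angle"])
        poly[:, 0] = np.clip(poly[:, 0], 0, h - 1)
        poly[:, 1] = np.clip(poly[:, 1], 0, w - 1)
        regions.append(AnnotationRegion(poly, g["spec"].label,
                                        config.pixel_size_um,
                                        name=f"{g['spec'].label} #{len(regions)}"))
    masks = rasterize_annotations(regions, h, w, labelset)

    # render ---------------------------------------------------------------
    image = np.empty((h, w, 3), dtype=np.float32)
    image[:] = np.asarray(colors.background_rgb, dtype=np.float32)
    # stroma with fibrous texture
    texture = np.stack([gaussian_filter(rng.standard_normal((h, w)), 4.0)
                        for _ in range(3)], axis=-1).astype(np.float32)
    texture /= max(1e-6, texture.std())
    stroma = np.asarray(colors.eosin_rgb, np.float32) + 0.035 * texture
    image[strip] = np.clip(stroma[strip], 0.30, 0.705)
    idx_stroma = np.argwhere(strip)
    area_um2 = len(idx_stroma) * config.pixel_size_um ** 2
    _stamp_nuclei(image, idx_stroma, int(round(1.2 * area_um2 / 1000.0)), rng,
                  colors.hematoxylin_rgb, config.pixel_size_um, elongated=True)

    bright = np.zeros((h, w), dtype=bool)
    for g, region in zip(glands, regions):
        epi = masks[labelset.index(region.label)].astype(bool) \
            & _region_footprint(region, h, w)
        _render_gland(image, g, epi, config, rng, bright)

    # smooth additive noise; amplitude is the ~3-sigma excursion
    noise = np.stack([gaussian_filter(rng.standard_normal((h, w)), 1.2)
                      for _ in range(3)], axis=-1).astype(np.float32)
    noise /= max(1e-6, noise.std())
    image = np.clip(image + (colors.noise_amplitude / 3.0) * noise,
                    0.0, 1.0).astype(np.float32)

    tissue = strip & ~bright
    return SyntheticBiopsy(image=image, masks=masks, regions=regions,
                           strip_mask=strip, tissue_mask=tissue,
                           bright_mask=bright, config=config)


def _region_footprint(region: AnnotationRegion, h: int, w: int) -> np.ndarray:
    from .annotations import polygon_mask
    return polygon_mask(region.polygon, h, w)


# --------------------------------------------------------------------------
# dataset generation

def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, 7919 + index]).generate_state(1)[0]
               % (2 ** 31))


def plan_presence(n_biopsies: int, archetypes: tuple[ArchetypeSpec, ...],
                  seed: int) -> list[dict[str, bool]]:
    """Deterministic per-biopsy presence plan.

    The cribriform prevalence is allocated exactly (round(n * presence_prob)
    positive biopsies); other archetypes are Bernoulli draws with a coverage
    fix-up so every label occurs at least once in the dataset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    plan = [dict() for _ in range(n_biopsies)]
    for a_i, spec in enumerate(archetypes):
        if spec.label == CRIBRIFORM:
            k = int(round(n_biopsies * spec.presence_prob))
            k = max(1, k) if spec.presence_prob > 0 else 0
            order = rng.permutation(n_biopsies)
            chosen = set(order[:k].tolist())
            for i in range(n_biopsies):
                plan[i][spec.label] = i in chosen
        else:
            draws = rng.random(n_biopsies) < spec.presence_prob
            if spec.presence_prob > 0 and not draws.any():
                draws[a_i % n_biopsies] = True
            for i in range(n_biopsies):
                plan[i][spec.label] = bool(draws[i])
    return plan


def generate_dataset(n_biopsies: int, base_config: SynthesisConfig, seed: int,
                     out_dir: str | Path,
                     labelset: LabelSet | None = None) -> list[BiopsyRecord]:
    """Write ``n_biopsies`` synthetic biopsies (PNG + XML + mask) and a manifest."""
    if n_biopsies < 1:
        raise ValueError("n_biopsies must be >= 1")
    labelset = labelset or LabelSet()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    presence = plan_presence(n_biopsies, base_config.archetypes, seed)
    records: list[BiopsyRecord] = []
    for i in range(n_biopsies):
        specs = tuple(
            replace(spec, count_range=spec.count_range if presence[i][spec.label]
                    else (0, 0))
            for spec in base_config.archetypes)
        cfg = replace(base_config, seed=_child_seed(seed, i), archetypes=specs)
        sample = generate_biopsy(cfg, labelset)
        stem = f"biopsy_{i:03d}"
        img_path = out_dir / f"{stem}.png"
        xml_path = out_dir / f"{stem}.xml"
        save_image(sample.image, img_path)
        write_annotations(sample.regions, xml_path, labelset)
        save_mask_png(sample.masks, out_dir / f"{stem}_mask.png")
        records.append(BiopsyRecord(
            image_path=str(img_path), regions=sample.regions,
            annotation_path=str(xml_path),
            pixel_size_um=base_config.pixel_size_um, biopsy_id=stem))
    save_manifest(records, out_dir / "manifest.json")
    return records
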
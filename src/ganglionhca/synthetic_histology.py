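"""Seeded generator of synthetic H&E colon-wall slides with ground truth.

Every downstream stage — layer segmentation, candidate detection,
contextual re-scoring, triage, decision rules — is exercised on slides from
this generator, so it renders exactly the anatomy the method reasons about:

* a laminar colon wall as horizontal bands (surface epithelium at the top,
  then mucosa/lamina propria, submucosa, muscularis propria, serosa, with
  unstained background below), which makes the layer ground truth exact;
* mature ganglion cells as ~100 px somata (large pale nucleus, one
  prominent dark nucleolus, abundant pink-purple cytoplasm) grouped in
  clusters in the submucosa/muscularis, with Schwann-like spindles and
  blood-vessel lumens nearby;
* immature ganglion cells: smaller, with small dark nuclei, inconspicuous
  nucleoli and scant but intensely stained cytoplasm — the neonatal variant
  that mimics plasma cells;
* mimics (plasma-cell/lymphocyte-like dark blobs) placed only in layers
  where ganglion cells never occur (epithelium, mucosa, serosa).

The image is composed in stain-concentration space through the fixed
two-stain Beer–Lambert model of :mod:`ganglionhca.stains`, plus Gaussian
texture noise, so stain unmixing downstream can be validated against known
mixing.  A single seeded generator is threaded through all stochastic
choices: the same spec and seed reproduce the bundle bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

from .annotations import Annotation, AnnotationSet, read_annotations, write_annotations
from .config import LAYER_BY_NAME, LAYER_PALETTE
from .stains import STAIN_OD_MATRIX, STAIN_RESIDUAL_VECTOR, od_to_rgb
from .tissue_hierarchy import LayerMap

__all__ = [
    "SlideSpec",
    "SlideImage",
    "GroundTruthBundle",
    "LabeledCase",
    "generate_slide",
    "generate_cohort",
    "write_annotations",
    "read_annotations",
    "write_bundle",
    "read_bundle",
]

_BAND_ORDER = ("epithelium", "mucosa", "submucosa", "muscularis", "serosa")

#: Soma radii in px at the reference magnification: a mature ganglion cell
#: spans roughly 100 px; immature cells are roughly half that.
_MATURE_RADIUS = (44.0, 52.0)
_IMMATURE_RADIUS = (17.0, 23.0)
_MIMIC_RADIUS = (7.0, 11.0)
_PLACEMENT_MARGIN = 4.0  # px between a soma edge and its band boundary


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide."""

    width_px: int = 1664
    height_px: int = 1280
    #: Physical pixel size; 0.25 um/px puts a ~25 um mature soma at ~100 px.
    pixel_size_um: float = 0.25
    #: Band thickness fractions for epithelium, mucosa, submucosa,
    #: muscularis, serosa (top to bottom); the remainder is background.
    layer_band_fractions: tuple[float, ...] = (0.06, 0.22, 0.28, 0.30, 0.08)
    n_mature_ganglia: int = 8
    n_immature_ganglia: int = 3
    n_mimics: int = 12
    cluster_size_mean: float = 3.0
    #: Expected extra vessels per megapixel of tissue (clusters always get
    #: one companion vessel of their own).
    vessel_density: float = 1.0
    #: Std-dev of Gaussian stain-concentration noise (OD units).
    noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        fr = tuple(float(f) for f in self.layer_band_fractions)
        if len(fr) != 5:
            raise ValueError("layer_band_fractions needs 5 entries")
        if any(f < 0 for f in fr):
            raise ValueError("band fractions must be nonnegative")
        if sum(fr) > 1.0 + 1e-9:
            raise ValueError("band fractions must sum to <= 1")
        self.layer_band_fractions = fr
        for name in ("n_mature_ganglia", "n_immature_ganglia", "n_mimics"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cluster_size_mean <= 0:
            raise ValueError("cluster_size_mean must be positive")
        if self.vessel_density < 0 or self.noise_level < 0:
            raise ValueError("vessel_density and noise_level must be >= 0")

    def band_rows(self) -> dict[str, tuple[int, int]]:
        """Row ranges [y0, y1) of each anatomical band."""
        rows: dict[str, tuple[int, int]] = {}
        y = 0
        for name, frac in zip(_BAND_ORDER, self.layer_band_fractions):
            h = int(round(frac * self.height_px))
            rows[name] = (y, min(y + h, self.height_px))
            y = min(y + h, self.height_px)
        return rows


@dataclass
class SlideImage:
    """An RGB tissue image with physical pixel-size metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_size_um: float = 0.25

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class GroundTruthBundle:
    """A synthetic slide with its exact layer map and annotations."""

    image: SlideImage
    layers: LayerMap
    annotations: AnnotationSet
    spec: SlideSpec

    def __post_init__(self) -> None:
        if self.image.pixels.shape[:2] != self.layers.shape:
            raise ValueError("image and layer map dimensions differ")


@dataclass
class LabeledCase:
    """One cohort case: its diagnostic label and ground-truth slide."""

    case_id: str
    label: Literal["HSCR", "non-HSCR", "inadequate"]
    bundle: GroundTruthBundle


# --------------------------------------------------------------------------
# rendering primitives (concentration space)
# --------------------------------------------------------------------------

def _ellipse_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    rx: float,
    ry: float,
    angle: float = 0.0,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Boolean mask of a rotated ellipse, restricted to its bounding box."""
    h, w = shape
    r = max(rx, ry)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), mask


def _paint(
    ch: np.ndarray,
    ce: np.ndarray,
    cx: float,
    cy: float,
    rx: float,
    ry: float,
    hval: float,
    eval_: float,
    angle: float = 0.0,
) -> None:
    sl, mask = _ellipse_mask(ch.shape, cx, cy, rx, ry, angle)
    ch[sl][mask] = hval
    ce[sl][mask] = eval_


def _circle_polygon(cx: float, cy: float, r: float, n: int = 24) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)


def _ellipse_polygon(
    cx: float, cy: float, rx: float, ry: float, angle: float, n: int = 24
) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    u, v = rx * np.cos(theta), ry * np.sin(theta)
    ca, sa = math.cos(angle), math.sin(angle)
    return np.stack([cx + u * ca - v * sa, cy + u * sa + v * ca], axis=1)


# --------------------------------------------------------------------------
# object placement
# --------------------------------------------------------------------------

def _permissible_bands_for(
    bands: dict[str, tuple[int, int]], radius: float
) -> list[tuple[str, int, int]]:
    """Permissible bands tall enough to hold a soma of the given radius."""
    need = 2.0 * (radius + _PLACEMENT_MARGIN)
    out = []
    for name in ("submucosa", "muscularis"):
        y0, y1 = bands[name]
        if y1 - y0 >= need:
            out.append((name, y0, y1))
    return out


def _sample_in_band(
    rng: np.random.Generator,
    width: int,
    y0: int,
    y1: int,
    radius: float,
) -> tuple[float, float]:
    m = radius + _PLACEMENT_MARGIN
    x = rng.uniform(m, width - m)
    y = rng.uniform(y0 + m, y1 - m)
    return x, y


def _place_soma(
    rng: np.random.Generator,
    width: int,
    y0: int,
    y1: int,
    radius: float,
    center: tuple[float, float] | None,
    placed: list[tuple[float, float, float]],
    spread: float = 170.0,
    min_gap: float = 8.0,
) -> tuple[float, float]:
    """Rejection-sample a soma centre, near ``center`` if given, keeping a
    clear gap to previously placed somata (one candidate per soma)."""
    m = radius + _PLACEMENT_MARGIN
    for attempt in range(400):
        if center is not None and attempt < 300:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = rng.uniform(0.0, spread * (1.0 + attempt / 150.0))
            x = float(np.clip(center[0] + rad * math.cos(ang), m, width - m))
            y = float(np.clip(center[1] + rad * math.sin(ang), y0 + m, y1 - m))
        else:
            x, y = _sample_in_band(rng, width, y0, y1, radius)
        ok = all(
            math.hypot(x - px, y - py) >= radius + pr + min_gap
            for px, py, pr in placed
        )
        if ok:
            placed.append((x, y, radius))
            return x, y
    raise RuntimeError(
        "could not place a ganglion soma without overlap; the slide is too "
        "small for the requested cell counts"
    )


def _cluster_sizes(
    rng: np.random.Generator, n: int, mean: float
) -> list[int]:
    sizes: list[int] = []
    remaining = n
    while remaining > 0:
        s = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return sizes


# --------------------------------------------------------------------------
# slide generation
# --------------------------------------------------------------------------

def generate_slide(spec: SlideSpec) -> GroundTruthBundle:
    """Render one synthetic colon-wall slide with exact ground truth.

    Raises
    ------
    ValueError
        If ganglia are requested but neither permissible band is thick
        enough to contain a soma (no silent truncation).
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width_px, spec.height_px
    bands = spec.band_rows()

    # --- ground-truth layer map (bands only; objects inherit band labels)
    layer_labels = np.zeros((h, w), dtype=np.uint8)
    for name, (y0, y1) in bands.items():
        layer_labels[y0:y1, :] = LAYER_BY_NAME[name]
    layers = LayerMap(layer_labels)

    # --- base tissue in concentration space
    ch = np.zeros((h, w), dtype=np.float64)
    ce = np.zeros((h, w), dtype=np.float64)
    for name, (y0, y1) in bands.items():
        hv, ev = LAYER_PALETTE[name]
        ch[y0:y1, :] = hv
        ce[y0:y1, :] = ev

    # muscularis fibre striping (subtle, horizontal)
    my0, my1 = bands["muscularis"]
    if my1 > my0:
        yy = np.arange(my0, my1)
        ce[my0:my1, :] *= (1.0 + 0.06 * np.sin(2.0 * math.pi * yy / 9.0))[
            :, None
        ]

    # crypt nuclei speckle in the mucosa — vetoed territory, but it gives
    # the hierarchical filter real false alarms to eliminate
    cy0, cy1 = bands["mucosa"]
    if cy1 - cy0 > 8:
        n_crypt = int((cy1 - cy0) * w / 2500)
        for _ in range(n_crypt):
            x = rng.uniform(4, w - 4)
            y = rng.uniform(cy0 + 4, cy1 - 4)
            r = rng.uniform(2.0, 4.0)
            _paint(ch, ce, x, y, r, r, 1.1, 0.2)

    annotations: list[Annotation] = []
    placed: list[tuple[float, float, float]] = []

    # --- ganglion clusters with vessel/Schwann context
    n_ganglia = spec.n_mature_ganglia + spec.n_immature_ganglia
    if n_ganglia > 0:
        min_radius_needed = (
            _MATURE_RADIUS[1] if spec.n_mature_ganglia > 0
            else _IMMATURE_RADIUS[1]
        )
        host_bands = _permissible_bands_for(bands, min_radius_needed)
        if not host_bands:
            raise ValueError(
                "submucosa/muscularis bands are too thin to contain a "
                "ganglion cell; enlarge the slide or the band fractions"
            )

    def _draw_vessel(cx: float, cy: float) -> None:
        rx = rng.uniform(20.0, 28.0)
        ry = rng.uniform(0.55, 0.75) * rx
        ang = rng.uniform(0.0, math.pi)
        _paint(ch, ce, cx, cy, rx, ry, 0.35, 0.60, ang)           # wall
        _paint(ch, ce, cx, cy, rx - 6.0, ry - 4.0, 0.02, 0.05, ang)  # lumen
        annotations.append(
            Annotation("vessel", _ellipse_polygon(cx, cy, rx, ry, ang))
        )

    def _draw_spindles(cx: float, cy: float, y0: int, y1: int) -> None:
        for _ in range(int(rng.integers(2, 5))):
            ang_pos = rng.uniform(0.0, 2.0 * math.pi)
            rad = rng.uniform(70.0, 150.0)
            sx = float(np.clip(cx + rad * math.cos(ang_pos), 20, w - 20))
            sy = float(np.clip(cy + rad * math.sin(ang_pos), y0 + 6, y1 - 6))
            srx = rng.uniform(13.0, 18.0)
            sry = rng.uniform(2.0, 3.0)
            sang = rng.uniform(0.0, math.pi)
            _paint(ch, ce, sx, sy, srx, sry, 0.9, 0.4, sang)
            annotations.append(
                Annotation(
                    "schwann_cluster",
                    _ellipse_polygon(sx, sy, srx + 1.5, sry + 1.5, sang),
                )
            )

    def _draw_cluster(
        kind: str, count: int, cluster_centers: list[tuple[float, float]]
    ) -> None:
        lo, hi = _MATURE_RADIUS if kind == "mature" else _IMMATURE_RADIUS
        usable = _permissible_bands_for(bands, hi)
        if not usable:
            usable = _permissible_bands_for(bands, lo + 1.0)
        if not usable:
            raise ValueError(
                "submucosa/muscularis bands are too thin to contain a "
                f"{kind} ganglion cell"
            )
        weights = np.array([y1 - y0 for _, y0, y1 in usable], dtype=float)
        name, y0, y1 = usable[int(rng.choice(len(usable),
                                             p=weights / weights.sum()))]
        # keep cluster centres apart so clusters are distinct structures
        for _ in range(60):
            ccx, ccy = _sample_in_band(rng, w, y0, y1, hi + 10.0)
            if all(math.hypot(ccx - ox, ccy - oy) >= 420.0
                   for ox, oy in cluster_centers):
                break
        cluster_centers.append((ccx, ccy))
        for _ in range(count):
            r = rng.uniform(lo, hi)
            x, y = _place_soma(rng, w, y0, y1, r, (ccx, ccy), placed)
            if kind == "mature":
                # abundant pink-purple cytoplasm, large pale nucleus,
                # one prominent dark nucleolus
                _paint(ch, ce, x, y, r, r, 0.50, 0.90)
                nr = 0.42 * r
                _paint(ch, ce, x, y, nr, nr, 0.30, 0.15)
                _paint(ch, ce, x, y, 5.0, 5.0, 1.50, 0.20)
                annotations.append(
                    Annotation("mature_ganglion",
                               _circle_polygon(x, y, r + 2.0))
                )
            else:
                # scant, intensely stained cytoplasm; small dark nucleus
                _paint(ch, ce, x, y, r, r, 0.80, 0.50)
                nr = 0.75 * r
                _paint(ch, ce, x, y, nr, nr, 1.00, 0.10)
                annotations.append(
                    Annotation("immature_ganglion",
                               _circle_polygon(x, y, r + 2.0))
                )
        _draw_spindles(ccx, ccy, y0, y1)
        vx = float(np.clip(ccx + rng.uniform(-200.0, 200.0), 40, w - 40))
        vy = float(np.clip(ccy + rng.uniform(-120.0, 120.0),
                           y0 + 26, y1 - 26))
        _draw_vessel(vx, vy)

    cluster_centers: list[tuple[float, float]] = []
    if spec.n_mature_ganglia > 0:
        for size in _cluster_sizes(rng, spec.n_mature_ganglia,
                                   spec.cluster_size_mean):
            _draw_cluster("mature", size, cluster_centers)
    if spec.n_immature_ganglia > 0:
        for size in _cluster_sizes(rng, spec.n_immature_ganglia,
                                   spec.cluster_size_mean):
            _draw_cluster("immature", size, cluster_centers)

    # --- free vessels anywhere in the submucosa
    sy0, sy1 = bands["submucosa"]
    if sy1 - sy0 > 70:
        tissue_mpx = sum(y1 - y0 for y0, y1 in bands.values()) * w / 1e6
        for _ in range(int(round(spec.vessel_density * tissue_mpx))):
            vx, vy = _sample_in_band(rng, w, sy0, sy1, 34.0)
            _draw_vessel(vx, vy)

    # --- mimics, only in layers devoid of ganglion cells
    mimic_bands = []
    for name in ("mucosa", "serosa", "epithelium"):
        y0, y1 = bands[name]
        if y1 - y0 >= 2 * (_MIMIC_RADIUS[1] + 2):
            mimic_bands.append((y0, y1))
    if spec.n_mimics > 0 and mimic_bands:
        for _ in range(spec.n_mimics):
            y0, y1 = mimic_bands[int(rng.integers(len(mimic_bands)))]
            r = rng.uniform(*_MIMIC_RADIUS)
            x, y = _sample_in_band(rng, w, y0, y1, r)
            _paint(ch, ce, x, y, r, r, 1.2, 0.2)
            annotations.append(
                Annotation("mimic", _circle_polygon(x, y, r + 1.5, n=16))
            )

    # --- noise and Beer–Lambert composition (float32 keeps the render
    # fast on whole-slide-scale images; quantisation to uint8 dominates)
    ch32 = ch.astype(np.float32)
    ce32 = ce.astype(np.float32)
    if spec.noise_level > 0:
        ch32 += spec.noise_level * rng.standard_normal(ch.shape,
                                                       dtype=np.float32)
        ce32 += spec.noise_level * rng.standard_normal(ce.shape,
                                                       dtype=np.float32)
        res = (0.3 * spec.noise_level) * rng.standard_normal(
            ch.shape, dtype=np.float32)
    else:
        res = None
    np.clip(ch32, 0.0, None, out=ch32)
    np.clip(ce32, 0.0, None, out=ce32)
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    for band in range(3):
        od_band = ch32 * np.float32(STAIN_OD_MATRIX[0, band])
        od_band += ce32 * np.float32(STAIN_OD_MATRIX[1, band])
        if res is not None:
            od_band += res * np.float32(STAIN_RESIDUAL_VECTOR[band])
        np.negative(od_band, out=od_band)
        np.exp(od_band, out=od_band)
        od_band *= np.float32(255.0)
        np.rint(od_band, out=od_band)
        np.clip(od_band, 0.0, 255.0, out=od_band)
        rgb[..., band] = od_band.astype(np.uint8)
    image = SlideImage(rgb, pixel_size_um=spec.pixel_size_um)

    return GroundTruthBundle(
        image=image,
        layers=layers,
        annotations=AnnotationSet(annotations),
        spec=spec,
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

_INADEQUATE_FRACTIONS = (0.10, 0.82, 0.0, 0.0, 0.0)


def generate_cohort(
    n_cases: int,
    hscr_fraction: float,
    inadequate_fraction: float = 0.0,
    seed: int = 0,
    base_spec: SlideSpec | None = None,
) -> list[LabeledCase]:
    """Generate a labelled cohort of synthetic cases (one slide each).

    HSCR cases contain no ganglion cells; non-HSCR cases contain at least
    one; inadequate cases emulate rectal biopsies that are too superficial
    — their slides have no submucosa or muscularis at all, and therefore no
    ganglion cells either.
    """
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    if hscr_fraction < 0 or inadequate_fraction < 0:
        raise ValueError("fractions must be nonnegative")
    if hscr_fraction + inadequate_fraction > 1.0 + 1e-9:
        raise ValueError("hscr_fraction + inadequate_fraction must be <= 1")
    if n_cases == 0:
        return []
    base = base_spec if base_spec is not None else SlideSpec()

    n_hscr = int(round(n_cases * hscr_fraction))
    n_inad = int(round(n_cases * inadequate_fraction))
    n_inad = min(n_inad, n_cases - n_hscr)
    labels = (["HSCR"] * n_hscr + ["inadequate"] * n_inad
              + ["non-HSCR"] * (n_cases - n_hscr - n_inad))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    cases: list[LabeledCase] = []
    for i, label in enumerate(labels):
        case_seed = int(rng.integers(0, 2**31 - 1))
        if label == "HSCR":
            spec = replace(base, n_mature_ganglia=0, n_immature_ganglia=0,
                           seed=case_seed)
        elif label == "inadequate":
            spec = replace(
                base,
                layer_band_fractions=_INADEQUATE_FRACTIONS,
                n_mature_ganglia=0,
                n_immature_ganglia=0,
                vessel_density=0.0,
                seed=case_seed,
            )
        else:
            n_mat = max(1, int(rng.poisson(base.n_mature_ganglia)))
            n_imm = int(rng.poisson(base.n_immature_ganglia))
            spec = replace(base, n_mature_ganglia=n_mat,
                           n_immature_ganglia=n_imm, seed=case_seed)
        cases.append(
            LabeledCase(
                case_id=f"case_{i:03d}",
                label=label,  # type: ignore[arg-type]
                bundle=generate_slide(spec),
            )
        )
    return cases


# --------------------------------------------------------------------------
# bundle persistence
# --------------------------------------------------------------------------

def write_bundle(bundle: GroundTruthBundle, directory: str | Path) -> None:
    """Write slide (RGB TIFF), layer map (TIFF + legend) and annotations."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "slide.tif", bundle.image.pixels,
                     photometric="rgb")
    bundle.layers.write(directory / "layers.tif")
    write_annotations(bundle.annotations, directory / "annotations.xml")


def read_bundle(directory: str | Path,
                pixel_size_um: float = 0.25) -> GroundTruthBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    directory = Path(directory)
    slide_path = directory / "slide.tif"
    if not slide_path.exists():
        raise FileNotFoundError(f"missing slide file: {slide_path}")
    pixels = tifffile.imread(slide_path)
    layers = LayerMap.read(directory / "layers.tif")
    anns = read_annotations(directory / "annotations.xml")
    return GroundTruthBundle(
        image=SlideImage(pixels, pixel_size_um=pixel_size_um),
        layers=layers,
        annotations=anns,
        spec=SlideSpec(width_px=pixels.shape[1], height_px=pixels.shape[0]),
    )
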
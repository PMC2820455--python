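"""Synthetic high-content screening plates with known ground truth.

Emulates a two-channel perinuclear tau assay: each well holds cells whose
nuclei fluoresce in a nuclear channel and whose cytoplasm carries "total
tau" (green) and "phospho-tau" (red) signal in a halo around the nucleus.
An siRNA knockdown is modeled as multiplicative factors on the per-cell red
and green intensities (1.0 = no effect); cytotoxicity enters only through
the expected cell count.

Two generation paths share one generative model:

* :func:`render_well_image` draws actual 3-channel 16-bit images plus a
  ground-truth cell table, for exercising the image-quantitation stage;
* :func:`simulate_well_table` draws the per-well aggregate readouts
  directly, for fast screen-scale simulation.

Noise model (per well): one multiplicative well factor with CV ``well_cv``
shared by both tau channels (staining / confluence variation — it cancels
in the per-well phospho/total ratio); independent per-cell lognormal
variation with CV ``cell_cv`` per channel; additive background and Gaussian
read noise on rendered pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_cdt
from skimage.draw import ellipse as _draw_ellipse

from ._seeds import substream
from .platemap import ROLE_CONTROL, ROLE_EMPTY

__all__ = [
    "EffectSpec",
    "NoiseModel",
    "Baselines",
    "RenderedWell",
    "SyntheticPlateSet",
    "render_well_image",
    "simulate_well_table",
    "simulate_screen_tables",
    "render_screen_images",
    "effects_from_factors",
]

#: plateau width of the cytoplasmic halo, matched to the measurement ring
RING_PLATEAU = 4


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect of one siRNA on the two tau readouts."""

    gene: str
    phospho_factor: float = 1.0
    total_factor: float = 1.0
    cell_count_mean: float = 300.0

    def __post_init__(self) -> None:
        if self.phospho_factor <= 0 or self.total_factor <= 0:
            raise ValueError("intensity factors must be > 0")
        if self.cell_count_mean < 0:
            raise ValueError("cell_count_mean must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters of the synthetic assay.

    Defaults put the SD of control-normalized null wells at ~0.05-0.06,
    the dispersion of a well-behaved triplicate screen.
    """

    cell_cv: float = 0.25
    well_cv: float = 0.04
    background_level: float = 100.0
    read_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if min(self.cell_cv, self.well_cv, self.background_level, self.read_noise_sd) < 0:
            raise ValueError("noise parameters must be >= 0")


#: noiseless variant used by exactness tests and the noiseless pipeline mode
QUIET = NoiseModel(cell_cv=0.0, well_cv=0.0, background_level=0.0, read_noise_sd=0.0)


@dataclass(frozen=True)
class Baselines:
    """Unperturbed per-cell mean intensities (image units / counts)."""

    phospho: float = 6000.0
    total: float = 6000.0
    nuclear: float = 15000.0


@dataclass
class RenderedWell:
    """One rendered well: image stack plus the generator's ground truth."""

    image: np.ndarray  # (3, H, W) uint16, channel order nuclear/green/red
    truth: pd.DataFrame  # per cell: row, col, area, ring_mean_red, ring_mean_green
    placement_shortfall: bool  # True if fewer cells were placed than drawn


@dataclass
class SyntheticPlateSet:
    """A simulated screen: plate map, well table and the planted truth."""

    platemap: pd.DataFrame
    wells: pd.DataFrame
    truth: dict[str, EffectSpec]
    seed: int


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def _place_nuclei(
    rng: np.random.Generator, n: int, shape: tuple[int, int], halo: int
) -> tuple[list[tuple[float, float, float, float, float]], bool]:
    """Rejection-sample non-overlapping ellipse nuclei fully inside the frame.

    Returns (cells, shortfall); each cell is (cy, cx, a, b, theta) with
    semi-axes a, b. Centers keep the nucleus plus its measurement ring off
    the border so rendered cells are measurable without clipping.
    """
    h, w = shape
    ys = np.empty(n)
    xs = np.empty(n)
    rs = np.empty(n)
    placed: list[tuple[float, float, float, float, float]] = []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        a, b = rng.uniform(4.0, 8.0, size=2)  # semi-axes: full axes 8-16 px
        r = max(a, b)
        margin = r + halo + 1
        if 2 * margin >= min(h, w):
            break
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        k = len(placed)
        if k and np.any((cy - ys[:k]) ** 2 + (cx - xs[:k]) ** 2 < (r + rs[:k] + 2.0) ** 2):
            continue
        ys[k], xs[k], rs[k] = cy, cx, r
        placed.append((cy, cx, a, b, rng.uniform(0, math.pi)))
    return placed, len(placed) < n


def render_well_image(
    effect: EffectSpec,
    noise: NoiseModel = NoiseModel(),
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    baselines: Baselines = Baselines(),
    halo_range: tuple[int, int] = (6, 10),
    rng: np.random.Generator | None = None,
) -> RenderedWell:
    """Render one well as a nuclear/green/red 16-bit stack with ground truth.

    Nuclei are non-overlapping ellipses; each cell's cytoplasmic halo holds
    a constant plateau over the first ``RING_PLATEAU`` pixels around the
    nucleus (so a 4-px measurement ring reads the per-cell mean exactly in
    the noiseless case) and decays linearly to zero over the remainder of
    the halo width (drawn per cell from ``halo_range``).

    The ground-truth table records, per cell, the centroid, nucleus area and
    the noiseless ring means (per-cell plateau amplitudes, i.e. before
    background and read noise).
    """
    if len(image_shape) != 2 or min(image_shape) < 32:
        raise ValueError("image_shape must be 2-D and at least 32 px per side")
    rng = substream(seed, "render", effect.gene) if rng is None else rng
    h, w = image_shape
    halo_hi = int(halo_range[1])

    n = int(rng.poisson(effect.cell_count_mean))
    cells, shortfall = _place_nuclei(rng, n, (h, w), halo_hi)
    if shortfall:
        warnings.warn(
            f"placed only {len(cells)} of {n} requested cells in {h}x{w} well",
            stacklevel=2,
        )

    well_factor = _lognormal(rng, noise.well_cv)
    chan = {k: np.zeros((h, w), dtype=np.float64) for k in ("nuclear", "green", "red")}
    records = []
    for label, (cy, cx, a, b, theta) in enumerate(cells, start=1):
        rr, cc = _draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        amp_red = baselines.phospho * effect.phospho_factor * well_factor * _lognormal(rng, noise.cell_cv)
        amp_green = baselines.total * effect.total_factor * well_factor * _lognormal(rng, noise.cell_cv)
        amp_nuc = baselines.nuclear * _lognormal(rng, noise.cell_cv)
        halo = int(rng.integers(halo_range[0], halo_range[1] + 1))

        np.maximum.at(chan["nuclear"], (rr, cc), amp_nuc)

        # halo profile over Chebyshev distance d from the nucleus:
        # 1.0 for d <= plateau, then linear decay reaching 0 beyond `halo`
        r_ext = int(math.ceil(max(a, b))) + halo + 1
        y0, y1 = max(0, int(cy) - r_ext), min(h, int(cy) + r_ext + 1)
        x0, x1 = max(0, int(cx) - r_ext), min(w, int(cx) + r_ext + 1)
        local = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        local[rr - y0, cc - x0] = True
        d = distance_transform_cdt(~local, metric="chessboard")
        profile = np.zeros_like(d, dtype=np.float64)
        profile[local] = 1.0
        inner = (d >= 1) & (d <= RING_PLATEAU)
        outer = (d > RING_PLATEAU) & (d <= halo)
        profile[inner] = 1.0
        profile[outer] = 1.0 - (d[outer] - RING_PLATEAU) / (halo - RING_PLATEAU + 1.0)
        chan["red"][y0:y1, x0:x1] = np.maximum(chan["red"][y0:y1, x0:x1], amp_red * profile)
        chan["green"][y0:y1, x0:x1] = np.maximum(chan["green"][y0:y1, x0:x1], amp_green * profile)

        records.append(
            {
                "label": label,
                "row": cy,
                "col": cx,
                "area": rr.size,
                "ring_mean_red": amp_red,
                "ring_mean_green": amp_green,
            }
        )

    stack = np.empty((3, h, w), dtype=np.uint16)
    for i, key in enumerate(("nuclear", "green", "red")):
        img = chan[key] + noise.background_level
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
        stack[i] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        records,
        columns=["label", "row", "col", "area", "ring_mean_red", "ring_mean_green"],
    )
    return RenderedWell(image=stack, truth=truth, placement_shortfall=shortfall)


def simulate_well_table(
    effect: EffectSpec,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    baselines: Baselines = Baselines(),
    rng: np.random.Generator | None = None,
) -> dict:
    """Draw one well's aggregate readouts without rendering pixels.

    Matches the rendered path's generative moments: the reported channel
    means are ``background + baseline x factor x well_factor x mean of N
    per-cell lognormal draws`` with ``N ~ Poisson(cell_count_mean)``.
    Returns a dict with ``cell_count``, ``phospho_mean``, ``total_mean``.
    """
    rng = substream(seed, "table", effect.gene) if rng is None else rng
    n = int(rng.poisson(effect.cell_count_mean))
    well_factor = _lognormal(rng, noise.well_cv)
    if n == 0:
        return {"cell_count": 0, "phospho_mean": np.nan, "total_mean": np.nan}
    red = baselines.phospho * effect.phospho_factor * well_factor * _lognormal(rng, noise.cell_cv, n).mean()
    green = baselines.total * effect.total_factor * well_factor * _lognormal(rng, noise.cell_cv, n).mean()
    return {
        "cell_count": n,
        "phospho_mean": red + noise.background_level,
        "total_mean": green + noise.background_level,
    }


def effects_from_factors(
    factors: dict[str, tuple[float, float]], cell_count_mean: float = 300.0
) -> dict[str, EffectSpec]:
    """Build an effect table from ``{gene: (phospho_factor, total_factor)}``."""
    return {
        g: EffectSpec(g, phospho_factor=p, total_factor=t, cell_count_mean=cell_count_mean)
        for g, (p, t) in factors.items()
    }


def _effect_for(gene: str, role: str, effects: dict[str, EffectSpec], cell_count_mean: float) -> EffectSpec | None:
    if role == ROLE_EMPTY:
        return None
    if role == ROLE_CONTROL:
        return EffectSpec("NS", 1.0, 1.0, cell_count_mean)
    eff = effects.get(gene)
    if eff is None:
        eff = EffectSpec(gene, 1.0, 1.0, cell_count_mean)
    return eff


def simulate_screen_tables(
    platemap: pd.DataFrame,
    effects: dict[str, EffectSpec] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    baselines: Baselines = Baselines(),
    cell_count_mean: float = 300.0,
) -> SyntheticPlateSet:
    """Simulate every occupied well of a plate map through the table path.

    Genes absent from ``effects`` (and NS controls) get null effects with
    ``cell_count_mean`` cells; per-well substreams are keyed by
    (plate_id, well) so results are independent of well order.
    """
    effects = effects or {}
    rows = []
    for rec in platemap.itertuples(index=False):
        eff = _effect_for(rec.gene, rec.role, effects, cell_count_mean)
        if eff is None:
            continue
        rng = substream(seed, "well", rec.plate_id, rec.well)
        m = simulate_well_table(eff, noise, baselines=baselines, rng=rng)
        rows.append(
            {
                "plate_id": rec.plate_id,
                "well": rec.well,
                "replicate": rec.replicate,
                "role": rec.role,
                "gene": rec.gene,
                "sirna_id": rec.sirna_id,
                **m,
            }
        )
    wells = pd.DataFrame(rows)
    return SyntheticPlateSet(platemap=platemap, wells=wells, truth=dict(effects), seed=seed)


def render_screen_images(
    platemap: pd.DataFrame,
    out_dir,
    effects: dict[str, EffectSpec] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    baselines: Baselines = Baselines(),
    cell_count_mean: float = 300.0,
) -> pd.DataFrame:
    """Render every occupied well to ``{plate_id}_{well}.tif`` (3-page TIFF).

    Returns the combined ground-truth table (one row per rendered cell)
    with plate/well identifiers. Channel page order is nuclear/green/red.
    """
    import tifffile
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    effects = effects or {}
    truths = []
    for rec in platemap.itertuples(index=False):
        eff = _effect_for(rec.gene, rec.role, effects, cell_count_mean)
        if eff is None:
            continue
        rng = substream(seed, "well", rec.plate_id, rec.well)
        rw = render_well_image(eff, noise, image_shape=image_shape, baselines=baselines, rng=rng)
        tifffile.imwrite(out_dir / f"{rec.plate_id}_{rec.well}.tif", rw.image)
        t = rw.truth.assign(plate_id=rec.plate_id, well=rec.well, gene=rec.gene)
        truths.append(t)
    return pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
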
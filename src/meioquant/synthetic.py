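"""Synthetic inputs for every pipeline stage.

The generators here produce data with the statistical structure the
downstream analyses assume — SMLM localization clouds drawn from hollow-ring
or filled-ellipse densities with per-localization precision, diffraction-
limited spot images with Gaussian PSFs, progeny SNP genotypes with
independent per-interval crossover probabilities, and per-zone focus counts —
so the whole pipeline is exercisable and testable without microscopy or
progeny data. Every generator is deterministic given its seed, and the seed
is recorded in the output's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .smlm import EllipseParams, LocalizationCloud, _rotation

__all__ = [
    "SimConfig",
    "Image2D",
    "DEFAULT_PRECISION_XY",
    "DEFAULT_PRECISION_Z",
    "gen_focus_localizations",
    "gen_spot_field",
    "gen_genotype_cohort",
    "gen_zone_counts",
]

# Lateral/axial localization-precision defaults: lognormal with a realistic
# SMLM spread, truncated at the filter bounds so most localizations are usable.
DEFAULT_PRECISION_XY: Mapping[str, float] = {"median": 8.0, "sigma": 0.35, "max": 15.0}
DEFAULT_PRECISION_Z: Mapping[str, float] = {"median": 15.0, "sigma": 0.35, "max": 25.0}

_Z_SLAB_SD = 30.0  # nm; in-focus foci viewed frontally carry no shape info in z


@dataclass
class SimConfig:
    """Bundle of generator settings for scripted runs; the seed stamps
    every output's metadata."""

    seed: int = 0
    blocks: dict = field(default_factory=dict)


@dataclass
class Image2D:
    """Single-plane fluorescence image with its pixel pitch in nm."""

    data: np.ndarray
    pixel_size: float  # nm per pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D")


def _sample_precision(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Precision spec: a positive scalar (constant) or a mapping with keys
    median, sigma (log-SD) and max (truncation bound, resampled)."""
    if np.isscalar(spec):
        val = float(spec)
        if val <= 0:
            raise ValueError("precision must be positive")
        return np.full(n, val)
    median = float(spec["median"])
    sigma = float(spec.get("sigma", 0.35))
    upper = float(spec.get("max", np.inf))
    out = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    bad = out > upper
    while np.any(bad):
        out[bad] = rng.lognormal(mean=np.log(median), sigma=sigma, size=int(bad.sum()))
        bad = out > upper
    return out


def _sample_perimeter(ellipse: EllipseParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Points uniform in arc length along the ellipse perimeter (inverse-CDF
    sampling on a dense parameter grid)."""
    t = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    local = np.column_stack([ellipse.a * np.cos(t), ellipse.b * np.sin(t)])
    seg = np.linalg.norm(np.roll(local, -1, axis=0) - local, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    u = rng.uniform(0.0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    frac = (u - cum[idx]) / seg[idx]
    pts = local[idx] + frac[:, None] * (np.roll(local, -1, axis=0)[idx] - local[idx])
    return pts @ _rotation(ellipse.theta).T + np.array([ellipse.cx, ellipse.cy])


def _sample_interior(ellipse: EllipseParams, n: int, rng: np.random.Generator) -> np.ndarray:
    r = np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    local = np.column_stack([ellipse.a * r * np.cos(phi), ellipse.b * r * np.sin(phi)])
    return local @ _rotation(ellipse.theta).T + np.array([ellipse.cx, ellipse.cy])


def gen_focus_localizations(
    shape_kind: str,
    ellipse: EllipseParams,
    n_loc: int,
    precision_xy=None,
    precision_z=None,
    background_frac: float = 0.0,
    roi_halfwidth: float = 200.0,
    seed: int = 0,
    focus_id: str = "focus",
    channel: str = "msh5",
) -> LocalizationCloud:
    """Simulate one focus's SMLM localization cloud.

    Each localization is drawn, with probability 1 - ``background_frac``,
    from the model density (uniform along the perimeter for "hollow",
    uniform over the interior for "filled") and displaced by an isotropic
    Gaussian with that localization's drawn lateral precision; otherwise it
    is uniform over the square ROI of half-width ``roi_halfwidth`` centered
    on the ellipse. z is a Gaussian slab (SD 30 nm) blurred by the axial
    precision; background z is uniform across the slab's +/-300 nm range.
    """
    if shape_kind not in ("hollow", "filled"):
        raise ValueError(f"shape_kind must be 'hollow' or 'filled', got {shape_kind!r}")
    if n_loc < 1:
        raise ValueError("n_loc must be >= 1")
    if not 0.0 <= background_frac <= 1.0:
        raise ValueError("background_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prec_xy = _sample_precision(
        DEFAULT_PRECISION_XY if precision_xy is None else precision_xy, n_loc, rng
    )
    prec_z = _sample_precision(
        DEFAULT_PRECISION_Z if precision_z is None else precision_z, n_loc, rng
    )

    is_bg = rng.random(n_loc) < background_frac
    n_model = int((~is_bg).sum())
    xy = np.empty((n_loc, 2))
    if n_model:
        sampler = _sample_perimeter if shape_kind == "hollow" else _sample_interior
        xy[~is_bg] = sampler(ellipse, n_model, rng)
    n_bg = n_loc - n_model
    center = np.array([ellipse.cx, ellipse.cy])
    if n_bg:
        xy[is_bg] = center + rng.uniform(-roi_halfwidth, roi_halfwidth, size=(n_bg, 2))
    z = np.empty(n_loc)
    z[~is_bg] = rng.normal(0.0, _Z_SLAB_SD, size=n_model)
    if n_bg:
        z[is_bg] = rng.uniform(-300.0, 300.0, size=n_bg)

    xy_obs = xy + rng.normal(size=(n_loc, 2)) * prec_xy[:, None]
    z_obs = z + rng.normal(size=n_loc) * prec_z

    data = pd.DataFrame(
        {
            "x_nm": xy_obs[:, 0],
            "y_nm": xy_obs[:, 1],
            "z_nm": z_obs,
            "locprec_nm": prec_xy,
            "locprec_z_nm": prec_z,
            "channel": channel,
        }
    )
    meta = {
        "seed": seed,
        "shape_kind": shape_kind,
        "background_frac": background_frac,
        "ellipse": {
            "cx": ellipse.cx,
            "cy": ellipse.cy,
            "full_major_axis": ellipse.full_major_axis,
            "full_minor_axis": ellipse.full_minor_axis,
            "theta": ellipse.theta,
        },
    }
    return LocalizationCloud(focus_id, data, roi_halfwidth=roi_halfwidth, meta=meta)


def gen_spot_field(
    emitters: Sequence[tuple],
    anchors: Sequence[tuple] = (),
    pixel_size: float = 65.0,
    image_shape: tuple = (64, 64),
    noise_sd: float = 5.0,
    offset: float = 100.0,
    seed: int = 0,
):
    """Render point emitters as anisotropic Gaussians on a pixel grid.

    ``emitters`` are (x_nm, y_nm, sigma_x_nm, sigma_y_nm, amplitude) tuples;
    ``anchors`` are (x_nm, y_nm) reference foci (the COSA-1 channel). Pixel
    (row, col) is centered at ((col + 0.5), (row + 0.5)) * pixel_size. The
    image is the emitter sum plus a constant offset and Gaussian read noise.
    Returns (Image2D, emitter ground-truth table, anchor table).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    h, w = image_shape
    rng = np.random.default_rng(seed)
    img = np.full((h, w), float(offset))
    xc = (np.arange(w) + 0.5) * pixel_size
    yc = (np.arange(h) + 0.5) * pixel_size
    X, Y = np.meshgrid(xc, yc)
    rows = []
    for i, (x, y, sx, sy, amp) in enumerate(emitters):
        if not (0 <= x < w * pixel_size and 0 <= y < h * pixel_size):
            raise ValueError(f"emitter {i} at ({x}, {y}) nm lies outside the image")
        img += amp * np.exp(-((X - x) ** 2) / (2 * sx**2) - ((Y - y) ** 2) / (2 * sy**2))
        rows.append(
            {"emitter_id": i, "x_nm": x, "y_nm": y, "sigma_x_nm": sx, "sigma_y_nm": sy,
             "amplitude": amp}
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    truth = pd.DataFrame(rows, columns=["emitter_id", "x_nm", "y_nm", "sigma_x_nm",
                                        "sigma_y_nm", "amplitude"])
    anchor_df = pd.DataFrame(
        [{"anchor_id": i, "x_nm": x, "y_nm": y} for i, (x, y) in enumerate(anchors)],
        columns=["anchor_id", "x_nm", "y_nm"],
    )
    image = Image2D(img, pixel_size, meta={"seed": seed, "noise_sd": noise_sd, "offset": offset})
    return image, truth, anchor_df


def gen_genotype_cohort(
    n_progeny: int,
    interval_probs: Sequence[float],
    missing_rate: float = 0.0,
    seed: int = 0,
    markers: Sequence[str] = ("A", "B", "C", "D", "E"),
) -> pd.DataFrame:
    """Simulate progeny chromatids over ordered SNP markers.

    Each progeny contributes one chromatid: the first marker's parental
    origin is uniform over {Bristol, Hawaiian}; each marker interval then
    flips the phase independently with its probability (no crossover
    interference — the double-crossover rate is a diagnostic output, not an
    input). Calls are masked to "NA" at ``missing_rate``. Columns: progeny_id
    plus one column per marker with values in {B, H, NA}.
    """
    probs = np.asarray(interval_probs, dtype=float)
    if len(probs) != len(markers) - 1:
        raise ValueError("need one interval probability per adjacent marker pair")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("interval probabilities must lie in [0, 1]")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    start = rng.integers(0, 2, size=n_progeny)
    flips = rng.random((n_progeny, len(probs))) < probs
    phase = np.empty((n_progeny, len(markers)), dtype=int)
    phase[:, 0] = start
    for j in range(len(probs)):
        phase[:, j + 1] = phase[:, j] ^ flips[:, j]
    calls = np.where(phase == 0, "B", "H").astype(object)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = "NA"
    df = pd.DataFrame(calls, columns=list(markers))
    df.insert(0, "progeny_id", [f"p{i:05d}" for i in range(n_progeny)])
    df.attrs["seed"] = seed
    df.attrs["interval_probs"] = probs.tolist()
    return df


def gen_zone_counts(
    zone_means: Sequence[float],
    n_nuclei_per_zone,
    dispersion: float | None = None,
    seed: int = 0,
    group: str = "sim",
) -> pd.DataFrame:
    """Per-nucleus integer focus counts by gonad zone.

    Counts are Poisson with the given per-zone rate, or negative-binomial
    with shape ``dispersion`` (variance m + m^2/dispersion) when over-
    dispersion is wanted. Returns a long CountTable: unit_id, group, zone,
    value.
    """
    means = np.asarray(zone_means, dtype=float)
    if np.any(means < 0):
        raise ValueError("zone rates must be >= 0")
    if np.isscalar(n_nuclei_per_zone):
        ns = [int(n_nuclei_per_zone)] * len(means)
    else:
        ns = [int(v) for v in n_nuclei_per_zone]
    if len(ns) != len(means):
        raise ValueError("n_nuclei_per_zone must match zone_means in length")
    rng = np.random.default_rng(seed)
    rows = []
    unit = 0
    for zone_idx, (m, n) in enumerate(zip(means, ns), start=1):
        if m == 0:
            vals = np.zeros(n, dtype=int)
        elif dispersion is None:
            vals = rng.poisson(m, size=n)
        else:
            k = float(dispersion)
            vals = rng.negative_binomial(k, k / (k + m), size=n)
        for v in vals:
            rows.append({"unit_id": f"nuc{unit:05d}", "group": group, "zone": zone_idx,
                         "value": int(v)})
            unit += 1
    df = pd.DataFrame(rows, columns=["unit_id", "group", "zone", "value"])
    df.attrs["seed"] = seed
    return df
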
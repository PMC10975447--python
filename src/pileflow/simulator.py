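"""Synthetic ground-truth generators for every stage of the pipeline.

Four generators with known truth:

* flow curves following the cone-growth power law, with optional stick–slip
  avalanche oscillations and Gaussian pixel noise;
* pile-growth image stacks (triangular silhouette, bright on black, with an
  optional central feed jet) rendered at the rig's native 128 x 160 / 25 fps
  geometry;
* particle silhouettes of controlled sphericity (disk, ellipse, rough blob);
* central-composite-design response columns from prescribed coefficients.

All stochastic paths are driven by an explicit seed and are bit-for-bit
reproducible.  The avalanche model is deliberately minimal: the flank
steepens until it exceeds the repose angle by a critical amount, then sheds
a wedge, giving a rising-ramp/sudden-drop sawtooth whose period is drawn
from a shifted Poisson distribution — the simplest caricature of
self-organized critical slipping, not a particle-level model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .flowfit import FlowCurve
from .geometry import cone_height
from .imaging import ImageStack

__all__ = [
    "SimConfig",
    "AvalancheConfig",
    "simulate_flow_curve",
    "simulate_pile_stack",
    "generate_particle_mask",
    "simulate_design_responses",
]


@dataclass(frozen=True)
class AvalancheConfig:
    """Stick–slip avalanche oscillation parameters."""

    enabled: bool = False
    critical_excess: float = 2.0  # degrees of flank steepening before a slip
    amplitude_px: float = 6.0  # peak-to-trough drop on the flow curve
    mean_period_frames: float = 20.0
    min_period_frames: int = 5


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic pile-growth run.

    Either give the physical knobs (``alpha_true`` in degrees and
    ``feed_rate`` in px^3/s of fed cone volume) or prescribe the power-law
    triple ``abc`` directly.  ``area_scale`` converts pile height (px) to
    slice bright-area (px); it is the slice band width for an ideal render.
    """

    alpha_true: float = 35.0
    feed_rate: float = 50000.0
    duration: float = 20.0
    fps: float = 25.0
    frame_shape: tuple[int, int] = (128, 160)
    area_scale: float = 5.0
    baseline: float = 0.0
    abc: tuple[float, float, float] | None = None
    avalanche: AvalancheConfig = field(default_factory=AvalancheConfig)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration * self.fps < 10:
            raise ValueError("duration * fps must give at least 10 frames")
        if self.fps <= 0 or self.feed_rate <= 0:
            raise ValueError("fps and feed_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _power_law_params(cfg: SimConfig) -> tuple[float, float, float]:
    """The exact (a, b, c) triple implied by the configuration."""
    if cfg.abc is not None:
        return tuple(float(v) for v in cfg.abc)
    tan_a = math.tan(math.radians(cfg.alpha_true))
    b = cfg.area_scale * (3.0 * cfg.feed_rate * tan_a**2 / math.pi) ** (1.0 / 3.0)
    return float(cfg.baseline), float(b), 1.0 / 3.0


def _avalanche_signal(
    n_frames: int, av: AvalancheConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Sawtooth residual: linear build-up, instantaneous drop at slip times."""
    if not av.enabled:
        return np.zeros(n_frames), []
    mean_extra = max(av.mean_period_frames - av.min_period_frames, 0.1)
    drops: list[int] = []
    pos = 0
    while True:
        period = av.min_period_frames + rng.poisson(mean_extra)
        pos += int(period)
        if pos >= n_frames:
            break
        drops.append(pos)
    signal = np.zeros(n_frames)
    start = 0
    bounds = drops + [n_frames]
    for stop in bounds:
        length = stop - start
        if length > 0:
            signal[start:stop] = np.linspace(
                -av.amplitude_px / 2.0, av.amplitude_px / 2.0, length
            )
        start = stop
    return signal, drops


def simulate_flow_curve(cfg: SimConfig) -> tuple[FlowCurve, dict[str, Any]]:
    """Synthetic flow curve with exact ground truth.

    The trend is ``a + b * t**c`` with the triple from the cone geometry
    (or ``cfg.abc`` verbatim); avalanche sawtooth and Gaussian noise are
    superimposed when enabled.  Returns the curve and a ground-truth record
    with the exact parameters and slip positions.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times()
    a, b, c = _power_law_params(cfg)
    trend = np.full_like(t, a)
    trend[t > 0] += b * t[t > 0] ** c
    saw, drops = _avalanche_signal(len(t), cfg.avalanche, rng)
    noise = rng.normal(0.0, cfg.noise_sigma, len(t)) if cfg.noise_sigma > 0 else 0.0
    curve = FlowCurve(times=t, areas=trend + saw + noise, fps=cfg.fps)
    truth = {
        "a": a,
        "b": b,
        "c": c,
        "n_avalanches": len(drops),
        "avalanche_drops": drops,
        "avalanche_amplitude_px": cfg.avalanche.amplitude_px
        if cfg.avalanche.enabled
        else 0.0,
        "noise_sigma": cfg.noise_sigma,
        "seed": cfg.seed,
    }
    return curve, truth


def _pile_heights(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Apex height (px, float) per frame from the fed cone volume."""
    t = cfg.times()
    h = np.zeros_like(t)
    pos = t > 0
    h[pos] = [cone_height(cfg.feed_rate * ti, cfg.alpha_true) for ti in t[pos]]
    return h


def simulate_pile_stack(
    cfg: SimConfig,
    jet: bool = True,
    jet_width: int = 8,
) -> tuple[ImageStack, dict[str, Any]]:
    """Render a growing triangular pile silhouette, bright on black.

    Each frame shows the pile (flank slope ``alpha_true`` from the
    horizontal, apex under the nozzle at the center column) at the height
    implied by the fed volume; ``jet`` adds a bright central column band
    imitating the falling particle stream, which the off-center slice
    choice must avoid.  Intensities are binary {0, 255}, no anti-aliasing,
    so slice areas are exactly countable.

    The ground-truth record carries the apex heights, the implied power-law
    triple for a fully covered off-center band, and the per-frame analytic
    silhouette area.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.frame_shape
    heights = _pile_heights(cfg, rng)
    if heights.max() > rows - 2:
        raise ValueError(
            f"pile height {heights.max():.1f} px exceeds the {rows}-px frame; "
            "shorten the duration or reduce the feed rate"
        )
    tan_a = math.tan(math.radians(cfg.alpha_true))
    apex = cols // 2
    dist = np.abs(np.arange(cols) - apex)

    frames = np.zeros((len(heights), rows, cols), dtype=np.uint8)
    for k, h in enumerate(heights):
        surf = np.rint(np.maximum(0.0, h - dist * tan_a)).astype(int)
        for col in np.nonzero(surf)[0]:
            frames[k, rows - surf[col] :, col] = 255
        if jet and k < len(heights) - 1:  # jet stops in the final (static) frame
            half = jet_width // 2
            lo, hi = apex - half, apex + half
            for col in range(max(lo, 0), min(hi, cols)):
                frames[k, : rows - surf[col], col] = 255
    stack = ImageStack(frames=frames, fps=cfg.fps)

    a, b, c = _power_law_params(cfg)
    # analytic silhouette area, minus the tails clipped by the frame edges
    # (the triangle footprint may exceed the field of view, as on the rig)
    e_left = np.maximum(0.0, heights - apex * tan_a)
    e_right = np.maximum(0.0, heights - (cols - 1 - apex) * tan_a)
    silhouette = heights**2 / tan_a - (e_left**2 + e_right**2) / (2.0 * tan_a)
    truth = {
        "alpha_true": cfg.alpha_true,
        "heights_px": heights,
        "abc_height": (0.0, b / cfg.area_scale, c),
        "silhouette_area_px": silhouette,
        "apex_col": apex,
        "seed": cfg.seed,
    }
    return stack, truth


def band_ground_truth(
    cfg: SimConfig, band: tuple[int, int]
) -> dict[str, Any]:
    """Analytic bright-area series of a column band of the rendered pile.

    Exact (to rasterization rounding) expected output of
    :func:`pileflow.imaging.slice_area_series` for a stack from
    :func:`simulate_pile_stack` without avalanches, plus the asymptotic
    power-law triple valid once the band lies inside the pile footprint.
    """
    rows, cols = cfg.frame_shape
    tan_a = math.tan(math.radians(cfg.alpha_true))
    apex = cols // 2
    dist = np.abs(np.arange(cols)[band[0] : band[1]] - apex)
    heights = _pile_heights(cfg, np.random.default_rng(cfg.seed))
    areas = np.array(
        [np.rint(np.maximum(0.0, h - dist * tan_a)).sum() for h in heights]
    )
    _, b_h, c = _power_law_params(cfg)
    width = band[1] - band[0]
    return {
        "areas": areas,
        "a_band": -float(tan_a * dist.sum()),
        "b_band": width * b_h / cfg.area_scale,
        "c": c,
    }


def generate_particle_mask(
    kind: str,
    size_px: int,
    aspect: float = 1.0,
    roughness: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Particle silhouette of controlled shape, with its continuous sphericity.

    ``kind`` is ``"disk"`` (pellet-like, sphericity -> 1), ``"ellipse"``
    (axis ratio ``aspect``), or ``"rough"`` (radially perturbed blob,
    granule-like; ``roughness`` is the relative amplitude of the random
    harmonic perturbation).  ``size_px`` is the major diameter.  Returns
    the boolean mask and the sphericity of the underlying continuous
    outline (shoelace area and polyline perimeter, independent of the
    pixel grid).
    """
    if size_px < 8:
        raise ValueError("size_px must be at least 8")
    rng = np.random.default_rng(seed)
    r0 = size_px / 2.0
    theta = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)

    if kind == "disk":
        radial = np.full_like(theta, r0)
    elif kind == "ellipse":
        if aspect < 1.0:
            raise ValueError("aspect must be >= 1 (major/minor)")
        a_ax, b_ax = r0, r0 / aspect
        radial = a_ax * b_ax / np.sqrt(
            (b_ax * np.cos(theta)) ** 2 + (a_ax * np.sin(theta)) ** 2
        )
    elif kind == "rough":
        radial = np.full_like(theta, r0)
        for k in range(2, 8):
            amp = rng.normal(0.0, 1.0)
            phase = rng.uniform(0.0, 2.0 * math.pi)
            radial = radial + r0 * roughness * amp * np.cos(k * theta + phase) / 3.0
        radial = np.clip(radial, 0.2 * r0, None)
    else:
        raise ValueError(f"unknown particle kind {kind!r}")

    x = radial * np.cos(theta)
    y = radial * np.sin(theta)
    # continuous ground truth: shoelace area, polyline perimeter
    area_true = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    perim_true = float(
        np.sum(np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))))
    )
    psi_true = 4.0 * math.pi * area_true / perim_true**2

    pad = int(math.ceil(radial.max())) + 2
    canvas = np.zeros((2 * pad, 2 * pad), dtype=bool)
    rr, cc = _draw_polygon(y + pad, x + pad, canvas.shape)
    canvas[rr, cc] = True
    return canvas, float(psi_true)


def simulate_design_responses(
    design,
    true_coefficients: dict[str, float],
    sigma: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Response column for a coded design from prescribed term coefficients.

    ``design`` is a DataFrame with coded factor columns (x1..x4);
    ``true_coefficients`` maps term names (``"Intercept"``, ``"x1"``,
    ``"x1:x2"``, ``"x1^2"``) to values.  Gaussian noise with standard
    deviation ``sigma`` is added when positive.
    """
    from .doe import term_column

    rng = np.random.default_rng(seed)
    n = len(design)
    y = np.zeros(n)
    for term, coef in true_coefficients.items():
        y = y + coef * term_column(design, term)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, n)
    return y
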
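"""Synthetic shrinking-spheroid image series for the morphometry pipeline.

Each frame is a phase-contrast-like picture of a compacting spheroid: a
dark interior surrounded by a bright halo ring on a mid-grey background.
The smooth-core boundary is a circle whose perimeter interpolates
linearly from the initial value down to ``final_fraction`` of it; a
band-limited radial roughness of known amplitude perturbs the boundary,
emulating the berry-like rough surface of poorly compacting aggregates.
The truth lists the smooth-core perimeters per frame.
"""

from __future__ import annotations

import numpy as np

from segdyn.morphometry import FrameImage
from segdyn.synthetic.truth import SyntheticTruth


def generate_spheroid_series(
    initial_perimeter: float,
    final_fraction: float,
    roughness_amp: float,
    n_frames: int,
    pixel_size: float,
    seed: int,
    noise_sd: float = 3.0,
    halo_width_px: float = 3.0,
    frame_interval_h: float = 1.0,
) -> tuple[list[FrameImage], SyntheticTruth]:
    """Phase-contrast-like frames of a spheroid compacting over time.

    ``initial_perimeter`` is the smooth-core perimeter (µm) of frame 0;
    by the last frame it has shrunk to ``final_fraction`` of that.  The
    boundary radius is ρ(φ) = r_t + roughness(φ) with a fixed random
    harmonic roughness profile of amplitude ``roughness_amp`` (µm),
    rescaled with the core so its relative shape persists across frames.
    """
    if not (0.0 < final_fraction <= 1.0):
        raise ValueError("final_fraction must lie in (0, 1]")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    r0 = initial_perimeter / (2.0 * np.pi)
    r_final = final_fraction * r0
    if roughness_amp >= min(r0, r_final):
        raise ValueError("roughness_amp must be smaller than the disk radius")
    rng = np.random.default_rng(seed)

    # Fixed band-limited roughness profile (harmonics 4..12, random phase).
    harmonics = np.arange(4, 13)
    amps = rng.uniform(0.5, 1.0, size=harmonics.size)
    phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)

    def rough(phi: np.ndarray) -> np.ndarray:
        s = sum(
            a * np.cos(k * phi + p) for a, k, p in zip(amps, harmonics, phases)
        )
        peak = np.abs(
            sum(a for a in amps)
        )  # conservative normalisation to the requested amplitude
        return roughness_amp * s / peak

    margin = 4 * halo_width_px * pixel_size + roughness_amp
    half = r0 + margin
    n_px = int(np.ceil(2 * half / pixel_size))
    coords = (np.arange(n_px) + 0.5) * pixel_size - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    r_px = np.sqrt(xx**2 + yy**2)
    phi = np.arctan2(yy, xx)
    dr = rough(phi)

    perims = np.linspace(r0, r_final, max(n_frames, 1)) * 2.0 * np.pi
    frames: list[FrameImage] = []
    bg, interior, halo = 128.0, 60.0, 235.0
    for i, P in enumerate(perims):
        r_core = P / (2.0 * np.pi)
        boundary = r_core + dr
        signed = r_px - boundary  # <0 inside
        img = np.full((n_px, n_px), bg)
        img[signed < 0] = interior
        band = np.exp(-0.5 * (signed / (halo_width_px * pixel_size)) ** 2)
        img = img + (halo - bg) * band
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames.append(
            FrameImage(
                np.clip(img, 0, 255),
                pixel_size=pixel_size,
                timestamp=i * frame_interval_h,
            )
        )
    truth = SyntheticTruth(
        kind="spheroid",
        true_perimeters=perims.copy(),
        extras={"roughness_amp": roughness_amp, "final_fraction": final_fraction},
    )
    return frames, truth
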
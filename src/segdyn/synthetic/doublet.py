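"""Synthetic cell-doublet images with analytically known contact angle."""

from __future__ import annotations

import numpy as np

from segdyn.doublet_mechanics import contact_angle_from_circles
from segdyn.synthetic.truth import SyntheticTruth


def generate_doublet_image(
    radius1: float,
    radius2: float,
    center_distance: float,
    pixel_size: float,
    seed: int,
    noise_sd: float = 5.0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Binary-plus-noise image of two intersecting disks.

    The circles must genuinely intersect, |ρ₁ − ρ₂| < d < ρ₁ + ρ₂; the
    true contact angle follows from the chord geometry and is returned in
    the truth (``true_theta`` is the mean of the two per-cell angles).
    """
    if not (abs(radius1 - radius2) < center_distance < radius1 + radius2):
        raise ValueError(
            "circles must intersect: require |r1 - r2| < d < r1 + r2"
        )
    rng = np.random.default_rng(seed)
    margin = 2.0 * pixel_size
    x1, x2 = 0.0, center_distance
    xmin = min(x1 - radius1, x2 - radius2) - margin
    xmax = max(x1 + radius1, x2 + radius2) + margin
    ymax = max(radius1, radius2) + margin
    nx = int(np.ceil((xmax - xmin) / pixel_size))
    ny = int(np.ceil(2 * ymax / pixel_size))
    xs = xmin + (np.arange(nx) + 0.5) * pixel_size
    ys = -ymax + (np.arange(ny) + 0.5) * pixel_size
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    inside = ((xx - x1) ** 2 + yy**2 <= radius1**2) | (
        (xx - x2) ** 2 + yy**2 <= radius2**2
    )
    img = inside.astype(np.float64) * 255.0
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255)

    geom = contact_angle_from_circles(((x1, 0.0), radius1), ((x2, 0.0), radius2))
    truth = SyntheticTruth(
        kind="doublet",
        true_theta=geom.theta_mean,
        extras={
            "theta1": geom.theta1,
            "theta2": geom.theta2,
            "mask": inside,
            "origin_um": (float(ys[0]), float(xs[0])),
        },
    )
    return img, truth
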
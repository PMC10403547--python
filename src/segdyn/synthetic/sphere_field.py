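"""Random sphere fields: ground truth for the cluster-diameter estimator.

Channel A is the union of non-overlapping random spheres of one known
diameter — an idealised population of homotypic cell clusters whose mean
diameter is exactly the generation parameter.  Channel B is the
complement within a spherical aggregate mask, mimicking the second cell
type filling the rest of the aggregate.
"""

from __future__ import annotations

import numpy as np

from segdyn.stack import VoxelStack
from segdyn.synthetic.truth import SyntheticTruth


def generate_sphere_field(
    true_diameter: float,
    fill_fraction: float,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    seed: int,
    noise_sd: float = 5.0,
    max_attempts_per_sphere: int = 2000,
) -> tuple[VoxelStack, SyntheticTruth]:
    """Two-channel stack of random same-size spheres plus complement.

    Sphere centres are drawn uniformly over the grid and accepted when at
    least one diameter away from every accepted centre (physical µm
    distances), until the A-channel voxel fraction reaches
    ``fill_fraction``.  Spheres may be clipped by the field boundary.
    Intensities are 255 inside / 0 outside plus Gaussian noise of
    ``noise_sd``, clipped to [0, 255].

    The returned truth carries ``true_R0 = true_diameter`` and the clean
    boolean label masks under ``extras['labels_a'|'labels_b']``.
    """
    spacing = tuple(float(s) for s in spacing)
    if true_diameter < 3.0 * max(spacing):
        raise ValueError(
            f"diameter {true_diameter} µm is too small for spacing {spacing}: "
            "the estimator cannot resolve clusters under 3 voxels across"
        )
    if not (0.0 < fill_fraction <= 0.5):
        raise ValueError("fill_fraction must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in grid_shape)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    radius = true_diameter / 2.0

    zz, yy, xx = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    mask_a = np.zeros(shape, dtype=bool)
    centers: list[np.ndarray] = []
    target_voxels = fill_fraction * mask_a.size
    attempts = 0
    while mask_a.sum() < target_voxels:
        c = rng.uniform(0.0, extent)
        if centers and np.min(np.linalg.norm(np.array(centers) - c, axis=1)) < true_diameter:
            attempts += 1
            if attempts > max_attempts_per_sphere * max(1, len(centers)):
                break  # field saturated below the requested fraction
            continue
        centers.append(c)
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        mask_a |= d2 <= radius**2

    # Aggregate mask: the inscribed ball of the field.
    center = extent / 2.0
    agg_r = extent.min() / 2.0
    agg = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= agg_r**2
    mask_b = agg & ~mask_a

    def to_channel(m: np.ndarray) -> np.ndarray:
        img = m.astype(np.float64) * 255.0
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=m.shape)
        return np.clip(img, 0, 255).astype(np.uint8)

    stack = VoxelStack(
        channels={"A": to_channel(mask_a), "B": to_channel(mask_b)},
        spacing=spacing,
    )
    truth = SyntheticTruth(
        kind="sphere_field",
        true_R0=float(true_diameter),
        extras={"labels_a": mask_a, "labels_b": mask_b, "n_spheres": len(centers)},
    )
    return stack, truth
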
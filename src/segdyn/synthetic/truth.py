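"""Ground-truth record returned by every synthetic generator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SyntheticTruth:
    """What the generator actually built, for parameter-recovery tests.

    Only the fields relevant to ``kind`` are set; ``extras`` carries
    generator-specific arrays (e.g. the label field behind a rendered
    stack).
    """

    kind: str  # sphere_field | coarsening | spheroid | doublet | dpa
    true_R0: float | None = None  # µm
    true_exponent: float | None = None
    true_perimeters: np.ndarray | None = None  # µm
    true_theta: float | None = None  # degrees
    true_separation_pressure: float | None = None  # Pa
    extras: dict = field(default_factory=dict)
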
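"""Synthetic dual-pipette aspiration pressure-step records.

The probe pipette applies stepwise increasing pressures (typical range
2–10 Pa, step sizes 0.5–3 Pa); the record marks the first step whose
pressure reaches the doublet's true separation threshold.
"""

from __future__ import annotations

import numpy as np

from segdyn.doublet_mechanics import DPARecord
from segdyn.synthetic.truth import SyntheticTruth


def generate_dpa_record(
    pipette_radius: float,
    true_threshold: float,
    start_pressure: float = 2.0,
    step: float = 1.0,
    seed: int = 0,
    max_steps: int = 20,
    step_bounds: tuple[float, float] = (0.5, 3.0),
) -> tuple[DPARecord, SyntheticTruth]:
    """Pressure-step record separating at the first step ≥ threshold.

    A threshold below the start pressure separates at step 0 (flagged
    downstream as a lower-bound force); a threshold beyond the last step
    yields a no-separation record (F_s undefined).  The generator is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if not (step_bounds[0] <= step <= step_bounds[1]):
        raise ValueError(f"step must lie in {step_bounds} Pa")
    if start_pressure < 0:
        raise ValueError("start_pressure must be >= 0")
    if max_steps < 1:
        raise ValueError("need at least one step")
    pressures = start_pressure + step * np.arange(max_steps)
    reached = np.flatnonzero(pressures >= true_threshold)
    separated_at = int(reached[0]) if reached.size else None
    record = DPARecord(
        pipette_radius_um=pipette_radius,
        pressures_pa=pressures,
        separated_at=separated_at,
    )
    truth = SyntheticTruth(
        kind="dpa",
        true_separation_pressure=float(true_threshold),
        extras={"separated_at": separated_at},
    )
    return record, truth
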
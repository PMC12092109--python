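#!/usr/bin/env python
"""Generate the synthetic study tail.

Builds a 43-vertebra synthetic series shaped like the Vienna
*Plateosaurus* tail — Ca1 about 25 cm tall, geometric taper, the
length/height crossing planted at Ca25, and the same four interior
vertebrae (Ca4, Ca9, Ca27, Ca37) deleted — and writes the measurement
table, its closed-form ground truth, and a noiseless twin used by the
later stages.
"""

import dataclasses
import json
from pathlib import Path

from caudawhip.series import write_measurements
from caudawhip.synthetic import SyntheticSeriesSpec, generate_series, ground_truth

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SPEC = SyntheticSeriesSpec(
    n_vertebrae=43,
    ca1_height_cm=25.0,
    ca1_length_cm=6.0,
    height_taper=0.93,
    tp_true=25,
    noise_sd_cm=0.1,
    missing_positions=(4, 9, 27, 37),
    seed=42,
)


def main() -> None:
    for label, spec in (
        ("synthetic_tail", SPEC),
        ("synthetic_tail_noiseless", dataclasses.replace(SPEC, noise_sd_cm=0.0)),
    ):
        series = generate_series(spec)
        path = write_measurements(series, OUT / f"{label}.csv")
        truth = ground_truth(spec)
        sidecar = dataclasses.asdict(truth)
        sidecar["spec"] = dataclasses.asdict(spec)
        with open(OUT / f"{label}_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        print(
            f"{label}: {len(series)} preserved vertebrae, "
            f"missing {list(series.missing_positions)}, "
            f"true TP Ca{truth.tp_position}, "
            f"true total length {truth.total_length_cm:.1f} cm -> {path.name}"
        )


if __name__ == "__main__":
    main()
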
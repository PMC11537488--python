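#!/usr/bin/env python
"""Simulate per-condition behavioral datasets and engram trajectories.

For every condition preset this draws a between-subjects forgetting-curve
dataset (12 mice per test day at days 1, 7, 14, 21) from the generative
model and writes it, plus the underlying daily relevancy / prediction-error
traces, under results/.
"""

from pathlib import Path

from engram_forgetting import ModelParams, condition_presets
from engram_forgetting.engram_model import trajectories_frame
from engram_forgetting.synthetic_data import (
    attach_raw_times,
    generate_forgetting_curve_dataset,
    write_csv,
)
from engram_forgetting.task_model import STANDARD_TEST_DAYS

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name, preset in sorted(condition_presets().items()):
        params = ModelParams(alpha_neg=preset.alpha_neg)
        schedules = [preset.schedule_for(d) for d in STANDARD_TEST_DAYS]
        obs = attach_raw_times(
            generate_forgetting_curve_dataset(
                params, schedules=schedules, n_mice_per_day=12, seed=SEED
            )
        )
        write_csv(obs, OUT / f"simulated_{name}.csv",
                  header_comment=f"condition={name} alpha_neg={preset.alpha_neg} seed={SEED}")
        trajectories_frame(schedules, params).to_csv(
            OUT / f"trajectories_{name}.csv", index=False
        )
        mean_mu = sum(o.mu_hat for o in obs) / len(obs)
        print(f"{name:16s} alpha_neg={preset.alpha_neg:<5} "
              f"{len(obs)} mice, mean familiar-object exploration {mean_mu:.3f}")
    print(f"\nwrote datasets and trajectories to {OUT}")


if __name__ == "__main__":
    main()
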
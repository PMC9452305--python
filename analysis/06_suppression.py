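"""Cross-inhibition by paired stomach-duodenum stimulation.

Runs the six-stimulus paired series (stomach, duodenum, mix, repeated),
classifies each selectively responsive neuron by the three strict
mix-vs-single criteria, and compares the recovered suppressed fractions to
the configured ground truth (29.0% of duodenum responders, 17.4% of stomach
responders).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from viscmap import SimConfig, paired_pulse_protocol
from viscmap.config import SuppressionSpec
from viscmap.pipeline import process_experiment
from viscmap.suppression import (
    DUODENUM_TARGET,
    STOMACH_TARGET,
    suppression_summary,
    suppression_table,
)
from viscmap.synth import generate_experiment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument(
        "--noiseless",
        action="store_true",
        help="noise- and drift-free traces (classifier is exact there)",
    )
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    kwargs = dict(noise_sd=0.0, drift_rate=0.0) if args.noiseless else {}
    config = SimConfig(
        n_neurons=2000,
        seed=args.seed,
        suppression=[
            SuppressionSpec("duodenum", "stomach", 0.29, 0.8),
            SuppressionSpec("stomach", "duodenum", 0.174, 0.8),
        ],
        **kwargs,
    )
    protocol, sidx = paired_pulse_protocol()
    _, truth, fluor = generate_experiment(config, protocol)
    dff, table = process_experiment(
        fluor, protocol, seed=args.seed, detrend=not args.noiseless
    )

    calls = pd.concat(
        [
            suppression_table(dff, protocol, sidx, table, DUODENUM_TARGET),
            suppression_table(dff, protocol, sidx, table, STOMACH_TARGET),
        ],
        ignore_index=True,
    )
    calls.to_csv(args.out / "suppression_calls.csv", index=False)
    summary = suppression_summary(calls)
    (args.out / "suppression_summary.json").write_text(json.dumps(summary, indent=2))

    for target, spec in ((DUODENUM_TARGET, 0.29), (STOMACH_TARGET, 0.174)):
        s = summary.get(target)
        if s:
            print(f"{target}: {100 * s['fraction_suppressed']:.1f}% suppressed "
                  f"({s['n_suppressed']}/{s['n_eligible']}; configured {100 * spec:.1f}%)")
    if not args.noiseless:
        print("note: under measurement noise the strict mix<single criteria "
              "over-call; rerun with --noiseless for the exact classifier")
    print(f"wrote suppression_calls.csv and suppression_summary.json to {args.out}/")


if __name__ == "__main__":
    main()
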
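"""Parameter-recovery study: how well does the fit recover a known truth?

Simulates many noisy five-isoform datasets from the frustrated reference
ground truth and refits each on the default reduced grid, reporting per
parameter the coupling-sign recovery rate and the rate of landing within
two grid steps of the truth.

With observables normalized to the reference construct the dataset carries
8 informative observations against 9 parameters, so one direction of
parameter space is exactly unconstrained; the printout flags the parameters
whose recovery is limited by this, rather than by noise.
"""

import argparse
from pathlib import Path

from gr_eam.synthetic_data import parameter_recovery_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-datasets", type=int, default=200)
    parser.add_argument("--noise-sd", type=float, default=0.05)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    report = parameter_recovery_study(
        n_datasets=args.n_datasets, noise_sd=args.noise_sd, seed=args.seed
    )
    out = args.out_dir / "parameter_recovery.csv"
    report.to_csv(out, float_format="%.17g", lineterminator="\n")
    print(
        f"{args.n_datasets} datasets at {args.noise_sd:.0%} noise "
        f"(seed {args.seed}):"
    )
    print(report.to_string(float_format=lambda v: f"{v:.3f}"))
    weak = report[report["within_2_steps_rate"] < 0.90].index.tolist()
    if weak:
        print(
            f"\nweakly recovered: {', '.join(weak)} - these lie along the "
            "unconstrained direction of the ratio-normalized data (see "
            "docs/methods.md, identifiability)"
        )
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
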
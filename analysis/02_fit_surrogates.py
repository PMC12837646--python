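"""Refit the three MLP surrogates on the measured campaign.

Trains the 3-9-2, 3-10-6 and 3-10-5 architectures (200 random restarts of
BFGS sum-of-squares training each, 9/3/3 split) and writes the model
bundles, the per-partition performance summary and the per-response
validation battery under results/surrogates/.
"""

from pathlib import Path

from uaeopt.pipeline import PipelineConfig, run

OUT = Path("results/surrogates")


def main() -> None:
    artifacts = run(PipelineConfig(stages=["fit"], seed=1, restarts=200,
                                   output_dir=str(OUT)))
    summary = artifacts["fit"]["summary"]
    print("per-partition coefficient of determination:")
    print(summary[["architecture", "train_r2", "test_r2",
                   "valid_r2"]].to_string())
    report = artifacts["fit"]["report"]
    worst = report.sort_values("aard", ascending=False).head(3)
    print("\nresponses with the largest relative deviation (AARD, %):")
    print(worst[["model", "aard", "rmse", "r2"]].to_string())
    print(f"\nmodel bundles and tables written to {OUT}/")


if __name__ == "__main__":
    main()
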
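"""Simulate two-reader ordinal scoring at the published marginal score
distributions, then test reconstruction effects (Wilcoxon signed-rank vs
baseline) and inter-reader agreement (Cohen's kappa with band labels).

Expected pattern: overall-quality and noise scores improve sharply on the
DLR reconstructions (p << 0.001), while the artifact scores do not move at
all (identical margins; agreement near-excellent).
"""

from pathlib import Path

from ctiq.pipeline import RunConfig, simulate_scores_and_agreement

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    df = simulate_scores_and_agreement(RunConfig(seed=1))
    df.to_csv(RESULTS / "score_agreement.csv", index=False)
    print(df.to_string(index=False))
    artifacts = df[df.parameter == "artifact"]
    print("\nartifact scores unchanged across reconstructions:",
          bool((artifacts.wilcoxon_vs_baseline_p.dropna() > 0.05).all()))
    quality = df[(df.parameter != "artifact") & (df.reconstruction_id.str.startswith("DLR"))]
    print("DLR quality/noise shifts significant:",
          bool((quality.wilcoxon_vs_baseline_p < 0.001).all()))


if __name__ == "__main__":
    main()
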
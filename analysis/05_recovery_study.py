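"""Monte-Carlo recovery study: bias, coverage and power across scenarios.

Scenario grid over the strong-instrument base (tau = 0.1, n_x = 200,000):
a null effect, a moderate causal effect, balanced pleiotropy, and directional
pleiotropy (InSIDE held).  200 replicates per scenario keeps the script quick;
the acceptance suite runs the 500-replicate versions of the key rows.
"""

import pathlib
import sys

from gutmr import EstimatorConfig, SyntheticConfig, recovery_report

SEED = 20240410
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"

SCENARIOS = {
    "null_effect": SyntheticConfig(J=50, beta0=0.0, tau=0.1, n_x=2e5),
    "causal_clean": SyntheticConfig(J=50, beta0=0.3, tau=0.1, n_x=2e5),
    "balanced_pleiotropy": SyntheticConfig(J=50, beta0=0.3, tau=0.1, n_x=2e5,
                                           rho_invalid=0.3, mu_alpha=0.0, sd_alpha=0.05),
    "directional_pleiotropy": SyntheticConfig(J=50, beta0=0.3, tau=0.1, n_x=2e5,
                                              rho_invalid=0.3, mu_alpha=0.05),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = recovery_report(
        SCENARIOS, n_reps=200, seed=SEED,
        estimator_config=EstimatorConfig(n_boot=200, presso_k=200),
    )
    report.to_csv(OUT / "recovery_report.tsv", sep="\t", index=False, float_format="%.4g")
    cols = ["scenario", "estimator", "mean_bias", "empirical_se", "rmse",
            "coverage", "rejection_rate"]
    print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("\nreading guide: under directional pleiotropy the IVW mean bias grows "
          "while the weighted median stays closer to the truth; coverage of the "
          "median/mode bootstrap CIs runs conservative (above 0.95).")
    return 0


if __name__ == "__main__":
    sys.exit(main())
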
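"""Study 3: empirical-style analysis on an emulated sample.

Generates an empirical-like sample of 1,010 responders from the per-pair
response-pattern proportions of the nine classic dilemma pairs, plus a
linked high-conflict moral dilemma (HCMD) Likert battery, then runs the
full psychometric battery: pattern classification with the difference
statistic, acceptance rates, inter-dilemma Spearman correlations,
alpha/omega for the sum-score formulation of U, split-half permutation
reliability for U and D, and the cross-battery correlation table.  Writes
results under results/empirical_mimic/.
"""

from pathlib import Path

from pdproc import (
    default_pattern_spec,
    generate_empirical_mimic,
    generate_hcmd,
    run_empirical_analysis,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "empirical_mimic"


def main(seed: int = 1, hcmd_link: float = -0.5) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_pattern_spec(seed=seed, hcmd_link=hcmd_link)
    responses = generate_empirical_mimic(spec)
    hcmd = generate_hcmd(spec, responses)
    report = run_empirical_analysis(responses, hcmd=hcmd, seed=seed)
    report.to_json(OUT / "report.json")
    (OUT / "report.txt").write_text(report.render() + "\n")
    report.scatter.to_csv(OUT / "scatter.csv")
    print(report.render())
    rates = report.tables["acceptance_rates"]
    rel = report.tables["reliability"]
    print(
        f"\nFinding: mean acceptance {rates['pct_acc_ic']:.1f}% (IC) / "
        f"{rates['pct_acc_c']:.1f}% (C); split-half corrected reliability "
        f"U {rel['splithalf_u']['mean']:.2f}, D {rel['splithalf_d']['mean']:.2f}. "
        "Note the mimic sample draws dilemma pairs independently, so its "
        "cross-pair reliability is a floor, not an estimate of the real data's."
    )


if __name__ == "__main__":
    main()
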
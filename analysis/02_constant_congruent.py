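"""Study 1 variant: hold every responder's congruent mean constant.

When responses to congruent dilemmas do not vary between responders (here
every responder judges exactly half of the C dilemmas unacceptable, with
incongruent responses still random), U and D both become monotone
functions of the same IC mean in opposite directions, and their correlation
turns strongly negative — showing that the near-zero U-D correlation in the
random study hinges entirely on between-responder variance in the congruent
set.  Writes results under results/sim1_constant_c/.
"""

from pathlib import Path

from pdproc import SimulationConfig, run_simulation1

OUT = Path(__file__).resolve().parent.parent / "results" / "sim1_constant_c"


def main(seed: int = 1, c_constant: float = 0.5) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = run_simulation1(SimulationConfig(seed=seed), c_constant=c_constant)
    report.to_json(OUT / "report.json")
    (OUT / "report.txt").write_text(report.render() + "\n")
    report.scatter.to_csv(OUT / "scatter.csv")
    print(report.render())
    r = report.tables["correlations_full_r"]
    print(
        f"\nFinding: with the congruent mean fixed at {c_constant}, "
        f"r(U,D) = {r.loc['U', 'D']:.2f} — the sign reversal shows the null "
        "U-D correlation depends on congruent-set variance."
    )


if __name__ == "__main__":
    main()
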
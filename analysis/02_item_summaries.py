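"""Item-level dysfunction and improvement between admission and endpoint.

Reads the simulated assessments and writes the 20-row item summary table
(counts and percentages of dysfunction and improvement, admission/discharge
means, improvement and improvement rate) to results/table1_items.csv.
"""

from pathlib import Path

from icftraj import items

IN = Path("results/cohort/assessments.csv")
OUT = Path("results/table1_items.csv")


def main() -> None:
    records = items.read_assessments(IN)
    adm, end = items.split_admission_endpoint(records)
    df = items.summary_frame(items.item_cohort_summary(adm, end))
    df.to_csv(OUT, index=False)
    worst = df.sort_values("pct_dysfunction", ascending=False).head(3)
    print(f"cohort of {len(adm)} patients; most affected items at admission:")
    for _, r in worst.iterrows():
        print(f"  {r['code']} {r['name']}: {r['pct_dysfunction']:.1f}% dysfunctional, "
              f"improvement rate {r['improvement_rate']:.1f}%")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
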
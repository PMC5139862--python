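"""Compare survival between MVD groups: 2x2 summary, KM curves, log-rank.

Reads results/cohort.csv and results/mvd_scores.csv, writes
results/km_curves.csv, results/survival_summary.json and results/report.txt.
Run after 02_score_images.py.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from gist_mvd.io import read_cohort_csv, write_json
from gist_mvd.survival import (
    cohort_descriptives,
    km_curve,
    logrank_test,
    summarize_groups,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()

    cohort = read_cohort_csv(ROOT / "results" / "cohort.csv")
    scores = pd.read_csv(ROOT / "results" / "mvd_scores.csv",
                         dtype={"patient_id": str})
    df = cohort.merge(scores[["patient_id", "mvd_mean", "mvd_group"]], on="patient_id")

    summary = summarize_groups(df)
    km_rows = []
    for g in ("low", "high"):
        sub = df[df["mvd_group"] == g]
        if len(sub) == 0:
            continue
        curve = km_curve(sub["followup_years"].to_numpy(),
                         sub["death_event"].to_numpy())
        for t, s, n, d in zip(curve.event_times, curve.survival,
                              curve.at_risk, curve.deaths):
            km_rows.append({"group": g, "time": t, "survival": s,
                            "at_risk": n, "deaths": d})
    pd.DataFrame(km_rows).to_csv(ROOT / "results" / "km_curves.csv", index=False)

    lo = df[df["mvd_group"] == "low"]
    hi = df[df["mvd_group"] == "high"]
    res = logrank_test(lo["followup_years"].to_numpy(), lo["death_event"].to_numpy(),
                       hi["followup_years"].to_numpy(), hi["death_event"].to_numpy(),
                       permutations=2000, seed=0)

    payload = {
        "contingency": {g: dataclasses.asdict(s) for g, s in summary.groups.items()},
        "logrank": {"statistic": res.statistic, "p_value": res.p_value,
                    "permutation_p": res.permutation_p},
        "descriptives": cohort_descriptives(df),
    }
    write_json(payload, ROOT / "results" / "survival_summary.json")

    c = summary.groups
    report = (
        f"MVD groups: {c['low'].n} low ({c['low'].group_pct}%), "
        f"{c['high'].n} high ({c['high'].group_pct}%).\n"
        f"Deaths: {c['high'].deaths}/{c['high'].n} ({c['high'].death_pct}%) high "
        f"vs {c['low'].deaths}/{c['low'].n} ({c['low'].death_pct}%) low.\n"
        f"Log-rank: chi-square = {res.statistic:.3f} (1 df), P = {res.p_value:.4g} "
        f"(permutation P = {res.permutation_p:.4g}).\n"
    )
    (ROOT / "results" / "report.txt").write_text(report)
    print(report, end="")
    print(f"tables -> {ROOT / 'results'}")


if __name__ == "__main__":
    main()
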
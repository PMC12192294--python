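"""Exploratory survival analysis of the synthetic cohort.

Produces the prevalence table of early sexual debut by covariate level
(unweighted counts, survey-weighted percentages, Pearson chi-square),
Kaplan-Meier curves overall and by sex, and log-rank comparisons.
Outputs: results/table1.csv, results/km_curves.csv, results/logrank.csv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from geodebut.descriptives import km_estimate, logrank_test, prevalence_table, survival_median
from geodebut.records import read_records

COVARIATES = ["sex", "residence", "alcohol"]


def main(cohort: Path = ROOT / "results" / "cohort.csv", outdir: Path = ROOT / "results") -> None:
    records = read_records(cohort, covariates=COVARIATES)

    tables = pd.concat([prevalence_table(records, c) for c in COVARIATES], ignore_index=True)
    tables.to_csv(outdir / "table1.csv", index=False, float_format="%.12g")
    print(tables.to_string(index=False))

    km_frames = [km_estimate(records, "overall").to_frame()]
    for lev, sub in records.groupby("sex"):
        km_frames.append(km_estimate(sub, f"sex={lev}").to_frame())
    pd.concat(km_frames, ignore_index=True).to_csv(
        outdir / "km_curves.csv", index=False, float_format="%.12g"
    )
    print(f"\nKM median debut age: {survival_median(km_estimate(records))} years")

    rows = []
    for c in COVARIATES:
        lr = logrank_test(records, c)
        rows.append({"covariate": c, "statistic": lr.statistic, "df": lr.df, "p": lr.p_value})
        print(f"log-rank {c}: chi2={lr.statistic:.3f} (df={lr.df}), p={lr.p_value:.4g}")
    pd.DataFrame(rows).to_csv(outdir / "logrank.csv", index=False, float_format="%.12g")


if __name__ == "__main__":
    main()
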
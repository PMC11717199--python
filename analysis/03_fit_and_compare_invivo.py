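#!/usr/bin/env python
"""Classify and fit the cohort with all three models; compare accuracy.

Keeps patients with >= 6 measurements, assigns each a trend category,
fits the two-population Gompertz model (grid search over the initial
sensitive fraction), the General Gompertz law and the General von
Bertalanffy law to every series, and compares the models' normalized
MSE within each trend category (pairwise two-sided t-tests, mirroring
a category x model-pair p-value table).
"""

import json
from pathlib import Path

import pandas as pd

from polygompertz import (
    COMPARATORS,
    FitConfig,
    classify_trend,
    filter_min_measurements,
    fit_comparator,
    fit_invivo_series,
    nmse,
    nmse_ttest_matrix,
)
from polygompertz.cli_io import read_cohort

SEED = 0
OUT = Path("results/invivo")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort_all = read_cohort("scratch/data/cohort.csv")
    cohort = filter_min_measurements(cohort_all, 6)
    print(f"{len(cohort)}/{len(cohort_all)} series pass the >= 6 measurement filter")

    categories = {s.patient_id: classify_trend(s) for s in cohort}
    pd.DataFrame(sorted((k, str(v)) for k, v in categories.items()),
                 columns=["patient_id", "category"]).to_csv(OUT / "categories.csv", index=False)

    config = FitConfig(seed=SEED)
    series_by_id = {s.patient_id: s for s in cohort}
    fits_by_model = {"polymorphic_gompertz": {}}
    for spec in COMPARATORS.values():
        fits_by_model[spec.model_id] = {}
    rows = []
    for s in cohort:
        poly = fit_invivo_series(s, config)
        fits_by_model["polymorphic_gompertz"][s.patient_id] = poly
        rows.append({"patient_id": s.patient_id, "model_id": "polymorphic_gompertz",
                     "category": str(categories[s.patient_id]), "p0": poly.p0,
                     "nmse": nmse(poly, s), "params": json.dumps(
                         {"rho": poly.params.rho, "K": poly.params.K, "lam": poly.params.lam})})
        for spec in COMPARATORS.values():
            f = fit_comparator(s, spec, config)
            fits_by_model[spec.model_id][s.patient_id] = f
            rows.append({"patient_id": s.patient_id, "model_id": spec.model_id,
                         "category": str(categories[s.patient_id]), "p0": None,
                         "nmse": nmse(f, s), "params": json.dumps(f.params)})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "fits.csv", index=False)

    summary = (df.groupby(["category", "model_id"])["nmse"]
               .agg(["mean", "median", "count"]).round(4))
    summary.to_csv(OUT / "error_by_category.csv")
    print("\nnMSE by trend category and model:")
    print(summary.to_string())

    mats = nmse_ttest_matrix(fits_by_model, series_by_id, categories)
    long_rows = [(cat, a, b, mat.loc[a, b])
                 for cat, mat in mats.items()
                 for a in mat.index for b in mat.columns if a < b]
    tmat = pd.DataFrame(long_rows, columns=["category", "model_a", "model_b", "p_value"])
    tmat.to_csv(OUT / "nmse_ttest_matrix.csv", index=False)
    print("\npairwise nMSE t-tests (p-values):")
    print(tmat.to_string(index=False))


if __name__ == "__main__":
    main()
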
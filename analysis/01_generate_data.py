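#!/usr/bin/env python
"""Generate the synthetic study data: one 192-well plate and one cohort.

The plate emulates a factorial co-culture experiment (8 seeding
proportions x drug +/- x CAF +/- x 6 replicates, drug at 20 h, 5%
multiplicative count noise).  The cohort emulates sparse clinical
volume series (baseline + ~6-week visits, 4-12 points, diameter-level
noise) covering all five trend categories.

Raw series go to scratch/data/ (regenerable from seed); the ground-truth
parameter tables go to results/data/.
"""

from pathlib import Path

import numpy as np

from polygompertz import CohortDesign, PlateDesign, gen_invitro_plate, gen_invivo_cohort
from polygompertz.cli_io import write_cohort, write_wells

SEED = 0
SCRATCH = Path("scratch/data")
RESULTS = Path("results/data")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    wells, plate_truth = gen_invitro_plate(PlateDesign(seed=SEED))
    write_wells(wells, SCRATCH / "wells.csv")
    plate_truth.to_csv(RESULTS / "wells_truth.csv")
    n_drug = sum(w.drug for w in wells)
    print(f"plate: {len(wells)} wells ({n_drug} with drug), "
          f"{wells[0].measured.n} time points each -> {SCRATCH/'wells.csv'}")

    cohort, cohort_truth = gen_invivo_cohort(CohortDesign(seed=SEED + 1))
    write_cohort(cohort, SCRATCH / "cohort.csv")
    cohort_truth.to_csv(RESULTS / "cohort_truth.csv")
    lengths = np.array([s.n for s in cohort])
    print(f"cohort: {len(cohort)} patients, {lengths.min()}-{lengths.max()} visits, "
          f"{(lengths >= 6).sum()} with >= 6 measurements -> {SCRATCH/'cohort.csv'}")
    print("intended categories:",
          cohort_truth.category.value_counts().sort_index().to_dict())


if __name__ == "__main__":
    main()
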
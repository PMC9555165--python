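"""Relative precision: does weighted scoring separate severity groups better?

Simulates a study-sized cohort, splits it 1000/355 into developmental and
validation halves, fits the GRM on the developmental half, scores the
validation half with the unweighted, frequency and GRM-weighted methods, and
compares their severity-group F statistics via the relative-precision index.
"""

import numpy as np

from irtscore import (
    SimulationConfig,
    build_evaluation_table,
    fit_mmle_em,
    normal_grid,
    score_cohort,
    simulate_grm_cohort,
    split_cohort,
)

records = simulate_grm_cohort(SimulationConfig(n=1355, seed=12))
dev, val = split_cohort(records, 1000 / 1355, seed=12)
fit = fit_mmle_em(dev, "grm", grid=normal_grid(41, 5.5))

labels = np.array([r.severity_group for r in val], dtype=object)
sets = {
    method: score_cohort(val, fit.params if method == "grm" else None,
                         method)["rescaled"].to_numpy()
    for method in ("unweighted", "frequency", "grm")
}
table = build_evaluation_table(sets, labels, reference_method="unweighted")
print(table.to_text())
# RP (bottom rows) is each method's F statistic divided by the unweighted
# reference's: above 1.000 means sharper severity-group separation. The
# frequency-only score typically loses precision (it discards intensity);
# the GRM-weighted score typically gains it.
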
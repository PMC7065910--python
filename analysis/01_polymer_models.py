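#!/usr/bin/env python
"""Elasticity groundwork: tabulate the ssDNA/dsDNA force–extension models,
locate the conversion-factor crossover, and demonstrate parameter recovery
from noisy force–extension points.

Writes results/force_extension.csv and results/elasticity_summary.json.

Found: at 30 pN one unwound bp adds x_ss − x_ds ≈ 0.188 nm of tether; the
conversion changes sign at ≈6.04 pN, below which the ΔL estimator is
ill-conditioned and the dark-region (fluorescence) estimator must be used.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from forktrack.elasticity import (
    DEFAULT_DSDNA,
    DEFAULT_SSDNA,
    conversion_factor,
    crossover_force,
    extension_per_bp_ds,
    extension_per_nt_ss,
    fit_force_extension,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

forces = np.linspace(1.0, 60.0, 60)
table = pd.DataFrame(
    {
        "force_pN": forces,
        "x_ss_nm_per_nt": [extension_per_nt_ss(DEFAULT_SSDNA, f) for f in forces],
        "x_ds_nm_per_bp": [extension_per_bp_ds(DEFAULT_DSDNA, f) for f in forces],
        "conversion_nm_per_bp": [conversion_factor(force=f) for f in forces],
    }
)
table.to_csv(OUT / "force_extension.csv", index=False)

# recovery demo: refit the eFJC from 2%-noise synthetic measurements
rng = np.random.default_rng(0)
pts = [
    (f, extension_per_nt_ss(DEFAULT_SSDNA, f) * (1 + 0.02 * rng.normal()))
    for f in np.linspace(5, 45, 50)
]
fit = fit_force_extension(pts, "ssDNA")

summary = {
    "x_ss_30pN_nm": extension_per_nt_ss(DEFAULT_SSDNA, 30.0),
    "x_ds_30pN_nm": extension_per_bp_ds(DEFAULT_DSDNA, 30.0),
    "conversion_30pN_nm_per_bp": conversion_factor(force=30.0),
    "crossover_force_pN": crossover_force(),
    "fit_recovered_Lc_nm": fit.params.contour_per_monomer,
    "fit_recovered_kuhn_nm": fit.params.persistence_or_kuhn,
    "fit_rmse_nm": fit.rmse_nm,
}
(OUT / "elasticity_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
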
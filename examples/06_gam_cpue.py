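"""Standardize CPUE with a GAM of space, time, and environment.

Cells are built per year-month, environmental covariates attached by
nearest-cell lookup, collinearity screened with VIF (< 5), and smooth terms
added forward in a fixed order, each kept only if it lowers the AIC.
"""

from fishspat import (
    GamSpec,
    SyntheticConfig,
    generate_env_fields,
    generate_hauls,
    grid_hauls,
    sample_env_at,
    stepwise_select,
    vif_screen,
)
from fishspat.gam import sst_optimum_window

config = SyntheticConfig(seed=7, n_hauls_per_year=2000)
fields = generate_env_fields(config)
hauls = generate_hauls(config, fields)

grids = grid_hauls(hauls, cell_size=0.1, period="year-month")
frames = []
for label, g in grids.items():
    year, month = label.split("-")
    df = g.cells.rename(columns={"lon_c": "lon", "lat_c": "lat"}).copy()
    df["year"], df["month"] = int(year), int(month)
    frames.append(df)
import pandas as pd

records = sample_env_at(pd.concat(frames, ignore_index=True), fields)

spec = GamSpec()
vif = vif_screen(records, columns=list(spec.terms))
print("VIF screen (threshold 5):")
print(vif.round(3).to_string(index=False))

spec.terms = tuple(vif.loc[vif["passed"], "covariate"])
path, final = stepwise_select(records, spec)
print("\nstepwise path (accepted steps lower the AIC):")
print(path[["formula", "aic", "deviance_explained_pct", "accepted"]]
      .round(2).to_string(index=False))

print(f"\nfinal model: {final.formula}")
print(f"AIC {final.aic:.1f}, deviance explained {final.deviance_explained_pct:.1f}%")
lo, hi = sst_optimum_window(final)
print(f"fitted SST optimum window: {lo:.1f}-{hi:.1f} C")
print(
    "\nThe SST partial effect plateaus inside the thermal window the catch "
    "model was built with (10-20 C) and falls off outside it."
)
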
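"""Density-dependence regressions on the natural-log scale.

Fits ln(total fg/cell) and ln(total ng/L) against ln(total diatom
density) after a 95%-interval outlier screen, then checks whether any
environmental covariate displaces density in a VIF-screened backward
multiple regression.
"""

import argparse
from pathlib import Path

import pandas as pd

from oxynet import io as oio, quant, regress

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--profile", type=Path, default=Path("results/profile"))
parser.add_argument("--out", type=Path, default=Path("results/regressions.csv"))
args = parser.parse_args()

abundance = oio.read_table(args.data / "abundance.csv", oio.ABUNDANCE_SCHEMA)
env = oio.read_table(args.data / "environment.csv", oio.ENV_SCHEMA)
classes = pd.read_csv(args.profile / "class_fg_per_cell.csv", index_col="sample")
ng_l = pd.read_csv(args.profile / "ng_per_litre.csv", index_col="sample")

density = abundance.sum(axis=0)
x = regress.ln_series(density).rename("ln_density")
y_cell = regress.ln_series(classes["total"], "fg/cell")
retained, dropped = regress.exclude_outliers(x, y_cell)
fit_cell = regress.fit_simple(x.loc[retained], y_cell.loc[retained],
                              excluded=list(dropped.index))
fit_litre = regress.fit_simple(x, regress.ln_series(ng_l.sum(axis=1), "ng/L"))

env_ln = env.copy()
env_ln["chl_a"] = regress.ln_series(env["chl_a"], "chl-a")
env_fit, trace, removed = regress.fit_environment(y_cell, env_ln, x)

rows = []
for name, fit in [("fg_per_cell~density", fit_cell), ("ng_per_litre~density", fit_litre)]:
    rows.append({
        "model": name, "slope": fit.slope, "intercept": fit.intercept,
        "adj_r2": fit.adj_r2, "F": fit.f_stat, "df": fit.df_resid,
        "p": fit.p_value, "N": fit.n, "excluded": ";".join(map(str, fit.excluded)),
    })
rows.append({
    "model": "fg_per_cell~environment+density",
    "slope": env_fit.slopes.get("ln_density"), "intercept": env_fit.intercept,
    "adj_r2": env_fit.adj_r2, "F": env_fit.f_stat, "df": env_fit.df_resid,
    "p": env_fit.p_value, "N": env_fit.n,
    "excluded": ";".join(sorted(env_fit.slopes)),
})
args.out.parent.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(args.out, index=False)

print(f"per-cell: y = {fit_cell.slope:.3f}x + {fit_cell.intercept:.2f}; "
      f"adj-R2 = {fit_cell.adj_r2:.3f}; F = {fit_cell.f_stat:.1f}; "
      f"df = {fit_cell.df_resid}; N = {fit_cell.n} "
      f"(excluded: {fit_cell.excluded or 'none'})")
print(f"per-litre: y = {fit_litre.slope:.3f}x + {fit_litre.intercept:.2f}; "
      f"adj-R2 = {fit_litre.adj_r2:.3f}")
print(f"environment model retains: {sorted(env_fit.slopes) or ['(none)']}; "
      f"VIF removed: {removed or 'none'}")
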
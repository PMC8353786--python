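"""Whole-season correlations and the fitted H x ln(VI+1) equations.

Shows the central phenomenon: pooled over both phenology stages, LAI
correlates weakly with any single vegetation index (hysteresis), while the
height product recovers a usable whole-season linear model. Writes the
R² table and fitted equations under results/.
"""

from pathlib import Path

import pandas as pd

from ricelai.models import ModelForm
from ricelai.validation import prepare_xy, add_vi_columns
from ricelai.indices import INDEX_NAMES
from ricelai.models import fit_linear, r_squared

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    obs_csv = ROOT / "results" / "observations.csv"
    if not obs_csv.exists():
        raise SystemExit("run analysis/02_extract_observations.py first")
    table = add_vi_columns(pd.read_csv(obs_csv))

    r2_rows, eq_rows = [], []
    for index in INDEX_NAMES:
        row = {"index": index}
        for form in ModelForm:
            x, y, _ = prepare_xy(table, index, form)
            row[form.value] = r_squared(x, y)
            if form is ModelForm.H_TIMES_LNVI:
                fit = fit_linear(x, y)
                eq_rows.append(dict(
                    index=index, slope=fit.slope, intercept=fit.intercept,
                    r2=fit.r2, rmse=fit.rmse, n=fit.n_samples,
                ))
        r2_rows.append(row)

    r2 = pd.DataFrame(r2_rows).set_index("index")
    eqs = pd.DataFrame(eq_rows)
    r2.to_csv(ROOT / "results" / "r2_whole_season.csv")
    eqs.to_csv(ROOT / "results" / "final_equations.csv", index=False)

    print("whole-season R² by predictor:")
    print(r2.round(3).to_string())
    print("\nfitted whole-season equations:")
    for r in eqs.itertuples():
        print(f"  LAI = {r.slope:5.2f} x H x ln({r.index}+1) "
              f"+ {r.intercept:5.2f}   (R² {r.r2:.2f}, RMSE {r.rmse:.2f})")


if __name__ == "__main__":
    main()
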
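"""Compare short- vs long-term model coefficients per sample matrix.

For each matrix, takes the best model at 3 h and at 24 h from the full
analysis and reports the fraction of shared selected wavelengths whose
regression coefficients have opposite signs — the signature that the
treatment moves the same bands in opposite directions when a treated fish
is compared against a fresh control (3 h) versus an ice-stored one (24 h).
"""

from pathlib import Path

import pandas as pd

from nirfish.pipeline import RunConfig, compare_terms, run_analysis

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

if __name__ == "__main__":
    spectra_csv = RESULTS / "synthetic_study.csv"
    if not spectra_csv.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    result = run_analysis(RunConfig(input_path=str(spectra_csv)))
    rows, tables = [], []
    for matrix in "EGMS":
        cmp = compare_terms(
            result.be_results[(matrix, 3, result.best[(matrix, 3)])],
            result.be_results[(matrix, 24, result.best[(matrix, 24)])],
        )
        rows.append({
            "matrix": matrix,
            "shared_wavelengths": cmp.shared_wavelengths.size,
            "opposite_sign_fraction": cmp.opposite_sign_fraction,
        })
        tables.append(cmp.table.assign(matrix=matrix))
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "term_comparison_summary.csv", index=False)
    pd.concat(tables).to_csv(RESULTS / "term_comparison_wavelengths.csv", index=False)
    print(summary.to_string(index=False))
    print("\nhigh opposite-sign fractions reproduce the short- vs long-term "
          "coefficient reversal on the wavelengths the treatment truly affects")
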
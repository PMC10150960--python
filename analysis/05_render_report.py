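"""Render the association and classification results as readable tables:
coefficients with Wald z in parentheses and significance stars, and CV
metrics as mean ± SD. Writes results/summary.txt and prints it."""

from pathlib import Path

import pandas as pd

from hypocause.report import render_text

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    multi = RESULTS / "assoc" / "multiple_regression.csv"
    summary = RESULTS / "report" / "cv_summary.csv"
    assoc = pd.read_csv(multi) if multi.exists() else None
    cv = pd.read_csv(summary) if summary.exists() else None
    text = render_text(assoc, cv)
    (RESULTS / "summary.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
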
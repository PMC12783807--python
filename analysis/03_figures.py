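"""Render the assessment figures from the tables written by 02_assess.py.

Produces the four diagnostic views: the Redfield ternary scatter coloured
by TSI class, the DIN-vs-TotP plane with TSI boundaries and the Redfield
N:P line, the overall-vs-minimum-monthly Si plot coded by season, and the
exceedance-ratio panels with monthly ranges.
"""

from pathlib import Path

import pandas as pd

from npsi.plots import render_figures

RESULTS = Path("results")


def main() -> None:
    summary = pd.read_csv(RESULTS / "site_summary.csv")
    monthly = pd.read_csv(RESULTS / "monthly_metrics.csv")
    written = render_figures(summary, monthly, RESULTS / "figures")
    for path in written:
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
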
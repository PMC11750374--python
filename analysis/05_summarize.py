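#!/usr/bin/env python
"""Reduce the posterior to the effect tables and print the global table.

One row per (target, term): posterior mean, s.d., probability of direction;
effects with pd >= 90% are bolded. The global block summarizes the
hyper-means mu (effects shared across species); species blocks summarize
the species-specific effect rows I.
"""

from pathlib import Path

from wingallometry.model import PosteriorDraws
from wingallometry.summary import render_table, summarize, write_summary

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "demo"


def main():
    draws = PosteriorDraws.load(ROOT / "scratch" / "draws_HY.npz")
    rows = summarize(draws)
    write_summary(rows, OUT / "summary_HY.csv")
    print(render_table(rows, level="global"))
    iy = draws.columns.index("year")
    year_row = [r for r in rows if r.level == "global" and r.term == "year"
                and r.target == "allometric_intercept"][0]
    print(f"\nyear effect on the allometric intercept: "
          f"{year_row.mean:+.3f} +/- {year_row.sd:.3f} "
          f"(pd {year_row.pd:.1f}%)")
    print(f"summary table: {OUT / 'summary_HY.csv'}")


if __name__ == "__main__":
    main()
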
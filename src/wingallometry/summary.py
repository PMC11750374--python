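"""Reduce posterior draws to effect tables: mean, s.d., probability of direction.

The reporting surface mirrors the convention of the allometry analysis:
global effects (the hyper-means mu) and species-specific effects (rows of I)
on the allometric intercept and slope, each summarized by the posterior mean,
posterior s.d., and the probability of direction (pd) - the share of draws
agreeing in sign with the majority, a one-sided evidence measure in
[50%, 100%]. Effects with pd >= 90% are emphasized (rendered bold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PosteriorDraws

EMPHASIS_PD = 90.0

TARGETS = ("allometric_intercept", "allometric_slope")
_TARGET_PARAMS = {
    "allometric_intercept": ("mu0", "I0"),
    "allometric_slope": ("mu1", "I1"),
}


@dataclass(frozen=True)
class SummaryRow:
    target: str        # allometric_intercept | allometric_slope
    term: str          # covariate column name
    level: str         # "global" or "species:<id>"
    mean: float
    sd: float
    pd: float          # percentage
    direction: str     # "+", "-" or "tie"
    emphasized: bool


def probability_of_direction(samples) -> tuple[float, str]:
    """pd = 100 * max(#positive, #negative) / N, with the majority sign.

    Exact zeros count toward neither sign but remain in the denominator.
    An even positive/negative split is a tie at 50%.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample vector")
    n_pos = int(np.sum(x > 0))
    n_neg = int(np.sum(x < 0))
    pd_pct = 100.0 * max(n_pos, n_neg) / x.size
    if n_pos > n_neg:
        direction = "+"
    elif n_neg > n_pos:
        direction = "-"
    else:
        direction = "tie"
    return pd_pct, direction


def _row(target, term, level, samples) -> SummaryRow:
    pd_pct, direction = probability_of_direction(samples)
    sd = float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0
    return SummaryRow(
        target=target, term=term, level=level,
        mean=float(np.mean(samples)), sd=sd,
        pd=pd_pct, direction=direction,
        emphasized=bool(pd_pct >= EMPHASIS_PD),
    )


def summarize(draws: PosteriorDraws) -> list[SummaryRow]:
    """One row per (target, term) globally, then per species.

    Draw vectors are pooled across chains post-warmup. Row order follows the
    model's covariate column order: the intercept block, then the slope block,
    global rows first, then each species in index order.
    """
    rows: list[SummaryRow] = []
    for target in TARGETS:
        mu_name, _ = _TARGET_PARAMS[target]
        mu = draws.pooled(mu_name)                      # (N, C)
        for c, term in enumerate(draws.columns):
            rows.append(_row(target, term, "global", mu[:, c]))
    for sp_i, sp in enumerate(draws.species):
        for target in TARGETS:
            _, i_name = _TARGET_PARAMS[target]
            eff = draws.pooled(i_name)                  # (N, S, C)
            for c, term in enumerate(draws.columns):
                rows.append(_row(target, term, f"species:{sp}", eff[:, sp_i, c]))
    return rows


def summary_frame(rows: list[SummaryRow], *, round_decimals: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows])
    if round_decimals is not None:
        for col in ("mean", "sd"):
            df[col] = df[col].round(round_decimals)
        df["pd"] = df["pd"].round(1)
    return df


def write_summary(rows: list[SummaryRow], path: str | Path,
                  *, round_decimals: int | None = 2) -> pd.DataFrame:
    df = summary_frame(rows, round_decimals=round_decimals)
    df.to_csv(path, index=False)
    return df


def render_table(rows: list[SummaryRow], level: str = "global") -> str:
    """Plain-text effect table with ** bold markers ** on emphasized rows."""
    lines = [f"{'target':<22} {'term':<28} {'mean':>7} {'sd':>6}  pd"]
    for r in rows:
        if r.level != level:
            continue
        term = f"**{r.term}**" if r.emphasized else r.term
        lines.append(
            f"{r.target:<22} {term:<28} {r.mean:>7.2f} {r.sd:>6.2f}  "
            f"{r.pd:.1f}% ({r.direction})"
        )
    return "\n".join(lines)
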
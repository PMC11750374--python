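#!/usr/bin/env python
"""Derive annual-cycle windows and assemble the species-year design matrix.

Computes each species' peak migration window (mean collection date +/- 1
s.d.) and pre-breeding window from the demonstration phenology, then builds
the standardized covariate matrix G (constant, climate terms, year) that the
hierarchical model consumes. Writes windows.json and covariates_HY.csv.
"""

import json
from pathlib import Path

import pandas as pd

from wingallometry.climate import build_covariate_table, season_windows
from wingallometry.morpho import read_specimens

from importlib.util import spec_from_file_location, module_from_spec

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def _demo_config():
    spec = spec_from_file_location(
        "step01", Path(__file__).with_name("01_simulate.py"))
    mod = module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod.CONFIG


def main():
    cfg = _demo_config()
    specimens = read_specimens(OUT / "specimens.csv")
    windows = season_windows(specimens)
    (OUT / "windows.json").write_text(json.dumps(
        {sp: w.to_dict() for sp, w in windows.items()}, indent=2))
    for sp, w in windows.items():
        print(f"{sp}: autumn window {w.autumn_window}")

    seasonal = pd.read_csv(OUT / "climate_seasonal.csv")
    G = build_covariate_table(seasonal, cfg.model_spec(), cfg.years)
    G.write(OUT / "covariates_HY.csv")
    print(f"G: {len(G.table)} species-year rows, "
          f"columns {G.column_spec}")


if __name__ == "__main__":
    main()
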
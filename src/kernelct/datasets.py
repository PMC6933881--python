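"""Packaged reference dataset: the six-variety maize cohort.

Ships the published per-variety means of the 28 structural parameters,
breakage rates, and moisture contents for six dent maize varieties
(XY335, M751, DH618, KX3564, KX9384, LC808), plus the published
four-predictor path-coefficient decomposition and the full
parameter-breakage correlation screen. These let the statistics stage be
exercised and cross-checked without any image processing.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_variety_means",
    "load_path_coefficients",
    "load_breakage_correlations",
]

_DATA = resources.files(__package__) / "data"


def load_variety_means() -> pd.DataFrame:
    """Per-variety means: 28 structural parameters + BR_pct + moisture_pct.

    ``BR_pct`` is the breakage rate in percent; divide by 100 before
    regressing against structural parameters (the published breakage model
    is on the fraction scale). Weight is per-kernel mass in mg.
    """
    with (_DATA / "variety_means.csv").open() as fh:
        return pd.read_csv(fh, index_col="variety")


def load_path_coefficients() -> dict:
    """Published path decomposition: direct + indirect coefficient matrix.

    Keys: ``predictors`` (X1..X4), ``labels``, ``direct`` (standardized
    direct path coefficients) and ``indirect`` (nested mapping, Xi -> Xj ->
    indirect effect of Xi through Xj).
    """
    with (_DATA / "path_coefficients.json").open() as fh:
        return json.load(fh)


def load_breakage_correlations() -> pd.DataFrame:
    """Published parameter-breakage correlation screen, one row per parameter.

    Indexed by the source's letter codes; two distinct entries carry the
    label "Endosperm volume ratio" in the original and are preserved as-is.
    """
    with (_DATA / "breakage_correlations.json").open() as fh:
        payload = json.load(fh)
    return pd.DataFrame(payload["entries"]).set_index("key")
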
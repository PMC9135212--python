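"""Indirect standardization: expected counts and standardized incidence ratios.

Expected counts follow E_i = r * n_i where r is the reference rate, total
observed events divided by total population within the standardization
stratum (by default each period, so every period's expected counts sum to
its observed counts); the standardized incidence ratio is SIR = y / E,
equal to 1 wherever an area experiences exactly the stratum-wide rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import PanelCounts


def expected_counts(
    panel: PanelCounts, stratify_by_period: bool = True
) -> PanelCounts:
    """Fill the panel's expected counts by indirect standardization.

    With ``stratify_by_period`` (default) the reference rate is computed
    within each period, matching per-year SIR mapping; otherwise a single
    pooled rate over the whole panel is used.  Returns a new panel; the
    identity sum(E) == sum(y) holds exactly within every stratum.
    """
    y, n = panel.y, panel.population
    if np.any(n <= 0):
        raise ValueError("populations must be strictly positive")
    if stratify_by_period:
        tot_n = n.sum(axis=0)
        if np.any(tot_n <= 0):
            raise ValueError("zero total population in a period stratum")
        rate = y.sum(axis=0) / tot_n
        E = rate[None, :] * n
    else:
        tot_n = n.sum()
        if tot_n <= 0:
            raise ValueError("zero total population")
        E = (y.sum() / tot_n) * n
    return PanelCounts(
        area_ids=list(panel.area_ids),
        periods=list(panel.periods),
        y=y.copy(),
        population=n.copy(),
        expected=E,
    )


def sir(panel: PanelCounts) -> pd.DataFrame:
    """Per-(area, period) standardized incidence ratio y / E.

    Zero observed counts give SIR 0 (valid); expected counts must have
    been filled first.
    """
    if panel.expected is None:
        raise ValueError(
            "panel has no expected counts; run expected_counts first"
        )
    if np.any(panel.expected <= 0):
        raise ValueError("expected counts must be strictly positive")
    frame = panel.to_frame()
    frame["sir"] = (panel.y / panel.expected).ravel()
    return frame


def rate_per_100k(panel: PanelCounts) -> pd.DataFrame:
    """Crude per-(area, period) rate: 1e5 * y / population."""
    frame = panel.to_frame()
    frame["rate_per_100k"] = (1e5 * panel.y / panel.population).ravel()
    return frame


def drop_unpopulated(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pre-filter for real-data dialects: split off rows with population <= 0.

    Returns (kept, dropped).  Building a panel from rows with
    non-positive population is refused elsewhere, so dirty administrative
    extracts are cleaned explicitly and auditable here rather than
    silently."""
    bad = frame["population"] <= 0
    return frame.loc[~bad].copy(), frame.loc[bad].copy()
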
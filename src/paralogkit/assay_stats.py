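"""Printed assay formulas: electrolyte leakage, cotyledon greening,
comparative-Ct relative expression.

Electrolyte leakage is a membrane-damage proxy from three conductivity
readings of the same tissue sample: S0 before shaking, S1 after gentle
shaking, S2 after autoclaving (total lysis). The comparative-Ct (ddCt)
method assumes perfect doubling per PCR cycle, so a one-cycle shift in
ddCt is a two-fold change in relative abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class ELMeasurement:
    """Conductivity triple, same (arbitrary) units for all three readings."""

    S0: float
    S1: float
    S2: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.S2 <= self.S0:
            raise ValueError("total-lysis conductivity S2 must exceed baseline S0")
        # S0 <= S1 <= S2 expected; deviations flagged, not rejected
        if not (self.S0 <= self.S1 <= self.S2):
            self.flagged = True


@dataclass
class QPCRMeasurement:
    Ct_target_sample: float
    Ct_ref_sample: float
    Ct_target_calibrator: float
    Ct_ref_calibrator: float

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name}={v}: Ct values must be finite and positive")


@dataclass
class GreeningCount:
    n_green: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_green <= self.n_total:
            raise ValueError("n_green must lie in [0, n_total]")


def electrolyte_leakage(m: ELMeasurement) -> float:
    """EL(%) = (S1 - S0) / (S2 - S0) x 100.

    Unit-free (any common conductivity unit cancels). Values outside
    [0, 100] are returned as-is; the measurement carries a ``flagged``
    attribute when the readings are not monotone.
    """
    return (m.S1 - m.S0) / (m.S2 - m.S0) * 100.0


def greening_rate(c: GreeningCount) -> float:
    """Percent of seedlings with green cotyledons."""
    return 100.0 * c.n_green / c.n_total


def ddct_fold_change(q: QPCRMeasurement) -> float:
    """Relative expression 2^(-ddCt) against a reference gene and a
    calibrator sample; amplification efficiency fixed at perfect doubling."""
    dct_sample = q.Ct_target_sample - q.Ct_ref_sample
    dct_calibrator = q.Ct_target_calibrator - q.Ct_ref_calibrator
    return 2.0 ** (-(dct_sample - dct_calibrator))


def mean_ct(replicates: Sequence[float]) -> float:
    """Aggregate technical replicates by their mean Ct before ddCt."""
    if not replicates:
        raise ValueError("no replicates")
    return float(np.mean(replicates))


def summarize_biological_replicates(values: Sequence[float]) -> tuple[float, float]:
    """(mean, standard error of the mean) across biological replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 biological replicates")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
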
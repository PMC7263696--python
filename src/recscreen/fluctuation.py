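"""Recombination-rate estimation from fluctuation tests, and hit triage.

Workflow mirrors the bench protocol: several parallel cultures are grown to
saturation without selection; a small diluted aliquot of each is plated on
permissive medium (to count viable cells) and a less-dilute aliquot on
selective medium (to count recombinants).  Each culture's selective count is
normalized to recombinants per ``norm_cells`` (default 1e7) viable cells, the
sample median of the normalized counts is converted to an expected event
number ``m`` with the Lea–Coulson method of the median, and the rate is
``m / norm_cells``.

Candidate strains from a first-pass screen are triaged in two stages: a
rate cutoff (default 2e-5 per cell, about twice the wild-type rate), then a
one-sided pooled-variance Student's t-test of repeated rate measurements
against wild type (default alpha 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    InsufficientReplicatesError,
    InvalidParameterError,
    ViableCountError,
)

__all__ = [
    "PlatingDesign",
    "CultureCount",
    "FluctuationTest",
    "RateEstimate",
    "normalize_count",
    "lea_coulson_median",
    "estimate_rate",
    "estimate_rate_from_normalized",
    "one_sided_t",
    "triage",
    "LEA_COULSON_CONSTANT",
]

log = logging.getLogger(__name__)

#: Constant of the Lea–Coulson median relation  r/m - ln(m) = 1.24.
LEA_COULSON_CONSTANT = 1.24

#: Fraction of ``norm_cells`` above which a normalized count is a "jackpot".
JACKPOT_NORM_FRACTION = 0.5

#: A test is indeterminate when more than this fraction of cultures are jackpots.
JACKPOT_TEST_CEILING = 0.5


@dataclass(frozen=True)
class PlatingDesign:
    """Dilution/volume design of a fluctuation test.

    Defaults reproduce the standard bench design: 4 ml cultures; 100 ul of a
    1e5-fold dilution on permissive plates, 200 ul of a 1e2-fold dilution on
    selective plates; counts normalized per 1e7 viable cells.
    """

    culture_volume_ml: float = 4.0
    sel_dilution: float = 1e2
    sel_volume_ml: float = 0.2
    perm_dilution: float = 1e5
    perm_volume_ml: float = 0.1
    norm_cells: float = 1e7

    def __post_init__(self) -> None:
        for name in ("culture_volume_ml", "sel_volume_ml", "perm_volume_ml", "norm_cells"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("sel_dilution", "perm_dilution"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")

    @property
    def sel_plated_fraction(self) -> float:
        """Fraction of the culture's cells plated on the selective plate."""
        return self.sel_volume_ml / (self.culture_volume_ml * self.sel_dilution)

    @property
    def perm_plated_fraction(self) -> float:
        """Fraction of the culture's cells plated on the permissive plate."""
        return self.perm_volume_ml / (self.culture_volume_ml * self.perm_dilution)


@dataclass(frozen=True)
class CultureCount:
    """Colony counts for one culture (selective and permissive plates)."""

    sel_count: int
    perm_count: int

    def __post_init__(self) -> None:
        if self.sel_count < 0 or self.perm_count < 0:
            raise InvalidParameterError("colony counts must be >= 0")


@dataclass(frozen=True)
class FluctuationTest:
    """One fluctuation test: per-culture counts plus the plating design."""

    cultures: Sequence[CultureCount]
    design: PlatingDesign = field(default_factory=PlatingDesign)

    def __post_init__(self) -> None:
        if len(self.cultures) < 1:
            raise InvalidParameterError("a fluctuation test needs >= 1 culture")

    @property
    def n_cultures(self) -> int:
        return len(self.cultures)


@dataclass(frozen=True)
class RateEstimate:
    """Method-of-the-median rate estimate for one fluctuation test.

    ``rate = m_hat / norm_cells`` when ``status == "ok"``; otherwise the
    numeric fields are NaN.  ``jackpot_fraction`` is the fraction of usable
    cultures whose normalized count exceeded half of ``norm_cells``.
    """

    rate: float
    m_hat: float
    median_r: float
    jackpot_fraction: float
    status: str  # "ok" | "indeterminate"
    n_cultures_used: int = 0


def normalize_count(sel_count: int, perm_count: int, design: PlatingDesign) -> float:
    """Recombinants per ``norm_cells`` viable cells for one culture.

    Back-calculates cells per ml of culture from each plate
    (count * dilution / plated volume) and rescales the ratio.  With the
    default design this reduces to ``5000 * sel_count / perm_count``.
    """
    if perm_count <= 0:
        raise ViableCountError(
            "permissive plate has no colonies; viable count undefined"
        )
    if sel_count < 0:
        raise InvalidParameterError("sel_count must be >= 0")
    sel_per_ml = sel_count * design.sel_dilution / design.sel_volume_ml
    perm_per_ml = perm_count * design.perm_dilution / design.perm_volume_ml
    return sel_per_ml / perm_per_ml * design.norm_cells


def lea_coulson_median(median_r: float) -> float:
    """Solve the Lea–Coulson median equation ``r/m - ln(m) = 1.24`` for m.

    The left-hand side is strictly decreasing in ``m``, so the root is unique;
    it is found by Brent's method on ``[1e-9, 1e6]`` to relative tolerance
    1e-9.  A non-positive median has no solution and returns NaN (an
    indeterminate-rate signal rather than an exception, so that batch
    processing can continue).
    """
    if median_r <= 0 or not math.isfinite(median_r):
        return math.nan
    def g(m: float) -> float:
        return median_r / m - math.log(m) - LEA_COULSON_CONSTANT
    lo, hi = 1e-9, 1e6
    if g(hi) > 0:  # median so large the root exceeds the bracket
        raise InvalidParameterError(f"median_r={median_r} out of solvable range")
    return float(optimize.brentq(g, lo, hi, rtol=1e-9))


def estimate_rate_from_normalized(
    normalized: Sequence[float], norm_cells: float = 1e7
) -> RateEstimate:
    """Method-of-the-median estimate from already-normalized counts.

    Takes the sample median (even n: mean of the two central values),
    converts it to ``m_hat`` via :func:`lea_coulson_median`, and reports
    ``rate = m_hat / norm_cells``.  The estimate is flagged indeterminate
    when the median is zero (no signal) or when more than half of the
    cultures are jackpots (normalized count above ``norm_cells / 2``), the
    regime where every colony carries a recombination event and the median
    no longer reflects the rate.
    """
    arr = np.asarray(list(normalized), dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("no usable cultures")
    median_r = float(np.median(arr))
    jackpot_fraction = float(np.mean(arr > JACKPOT_NORM_FRACTION * norm_cells))
    if median_r <= 0 or jackpot_fraction > JACKPOT_TEST_CEILING:
        return RateEstimate(
            rate=math.nan,
            m_hat=math.nan,
            median_r=median_r,
            jackpot_fraction=jackpot_fraction,
            status="indeterminate",
            n_cultures_used=int(arr.size),
        )
    m_hat = lea_coulson_median(median_r)
    return RateEstimate(
        rate=m_hat / norm_cells,
        m_hat=m_hat,
        median_r=median_r,
        jackpot_fraction=jackpot_fraction,
        status="ok",
        n_cultures_used=int(arr.size),
    )


def estimate_rate(test: FluctuationTest) -> RateEstimate:
    """Estimate the recombination rate of one fluctuation test.

    Cultures with a zero permissive count are dropped with a warning (their
    viable-cell density is unknowable); if every culture is dropped an error
    is raised.
    """
    normalized: List[float] = []
    dropped = 0
    for i, culture in enumerate(test.cultures):
        try:
            normalized.append(
                normalize_count(culture.sel_count, culture.perm_count, test.design)
            )
        except ViableCountError:
            dropped += 1
            log.warning("culture %d dropped: no colonies on permissive plate", i)
    if not normalized:
        raise ViableCountError("all cultures had zero permissive counts")
    return estimate_rate_from_normalized(normalized, test.design.norm_cells)


def one_sided_t(
    rates_mutant: Sequence[float], rates_wt: Sequence[float]
) -> float:
    """One-sided pooled-variance Student's t-test, alternative mutant > WT."""
    if len(rates_mutant) < 2 or len(rates_wt) < 2:
        raise InsufficientReplicatesError(
            "need >= 2 replicate rates in each group for the t-test"
        )
    res = stats.ttest_ind(
        np.asarray(rates_mutant, dtype=float),
        np.asarray(rates_wt, dtype=float),
        equal_var=True,
        alternative="greater",
    )
    return float(res.pvalue)


def triage(
    estimates: Mapping[str, Sequence[RateEstimate]],
    wt_rates: Sequence[float],
    rate_cutoff: float = 2e-5,
    alpha: float = 0.05,
) -> Dict[str, str]:
    """Two-stage validation of candidate hyper-recombination strains.

    Stage 1 keeps strains whose first-pass rate is at least ``rate_cutoff``.
    Stage 2 validates retained strains whose repeated determinate rates beat
    the wild-type reference rates in a one-sided t-test at ``alpha``.

    Returns a verdict per strain: ``validated``, ``rejected-stage1``,
    ``rejected-stage2``, or ``indeterminate`` (first-pass estimate
    indeterminate, or too few determinate repeats for the t-test).
    """
    if rate_cutoff <= 0:
        # rate_cutoff == 0 is allowed as the degenerate keep-everything stage 1
        if rate_cutoff < 0:
            raise InvalidParameterError("rate_cutoff must be >= 0")
    if not 0 < alpha <= 1:
        raise InvalidParameterError("alpha must be in (0, 1]")
    wt = [float(r) for r in wt_rates if math.isfinite(r)]
    if not wt:
        raise InvalidParameterError("wild-type reference rates are empty")
    verdicts: Dict[str, str] = {}
    for strain, ests in estimates.items():
        if not ests:
            raise InvalidParameterError(f"strain {strain} has no estimates")
        first = ests[0]
        if first.status != "ok":
            verdicts[strain] = "indeterminate"
            continue
        if first.rate < rate_cutoff:
            verdicts[strain] = "rejected-stage1"
            continue
        repeat = [e.rate for e in ests if e.status == "ok"]
        if len(repeat) < 2 or len(wt) < 2:
            verdicts[strain] = "indeterminate"
            continue
        p = one_sided_t(repeat, wt)
        verdicts[strain] = "validated" if p < alpha else "rejected-stage2"
    return verdicts
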
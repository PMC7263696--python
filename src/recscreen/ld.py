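"""Luria–Delbrück distribution mathematics and clonal-growth simulation.

A fluctuation assay grows many parallel cultures (or, in a pinning screen,
colonies) from small inocula without selection, then plates each on selective
medium.  Because a recombination event early in the growth of a clone is
amplified exponentially, the number of pre-existing recombinant cells ``r``
at sampling time is wildly over-dispersed relative to Poisson — the classic
"jackpot" phenomenon.  This module provides

* :func:`ld_pmf` — the exact probability mass function of ``r`` under the
  classical model via the Ma–Sandri–Sarkar recursion,
* :func:`simulate_clone` / :func:`sample_ld_counts` — a forward simulator of
  the same model (deterministic exponential growth, events uniform over the
  population increase, no death, no reversion, no phenotypic lag).

The single distributional parameter is ``m``, the expected number of
recombination events per clone; with a per-cell per-division rate ``mu`` and
growth from ``n0`` to ``nf`` cells, ``m = mu * (nf - n0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "LDModel",
    "CloneOutcome",
    "ld_pmf",
    "ld_cdf_median",
    "simulate_clone",
    "sample_ld_counts",
    "child_seed",
]

#: relative tolerance for the m / mu / (nf - n0) consistency check
_REL_TOL = 1e-12

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class LDModel:
    """Parameters of one clonal expansion.

    Parameters
    ----------
    m
        Expected number of recombination events per clone (dimensionless).
    n0, nf
        Initial and final viable cell counts; growth is ``n0 -> nf``.
    mu
        Optional per-cell per-division event rate.  When given it must be
        consistent with ``m = mu * (nf - n0)``.
    """

    m: float
    n0: int = 1
    nf: int = 10_000_000
    mu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m < 0:
            raise InvalidParameterError(f"m must be >= 0, got {self.m}")
        if not self.n0 >= 1:
            raise InvalidParameterError(f"n0 must be >= 1, got {self.n0}")
        if not self.nf > self.n0:
            raise InvalidParameterError(
                f"nf must exceed n0, got nf={self.nf}, n0={self.n0}"
            )
        if self.mu is not None:
            expected = self.mu * (self.nf - self.n0)
            if abs(self.m - expected) / max(self.m, 1e-300) > _REL_TOL and abs(
                self.m - expected
            ) > _REL_TOL:
                raise InvalidParameterError(
                    f"inconsistent parameters: m={self.m} but "
                    f"mu*(nf-n0)={expected}"
                )

    @classmethod
    def from_rate(cls, mu: float, n0: int = 1, nf: int = 10_000_000) -> "LDModel":
        """Build a model from a per-cell rate; ``m`` follows from the growth."""
        if mu < 0:
            raise InvalidParameterError(f"mu must be >= 0, got {mu}")
        return cls(m=mu * (nf - n0), n0=n0, nf=nf, mu=mu)


@dataclass(frozen=True)
class CloneOutcome:
    """Result of one simulated clonal expansion."""

    r: int  #: pre-existing recombinant cells at sampling time
    nf: int  #: total viable cells

    def __post_init__(self) -> None:
        if not 0 <= self.r <= self.nf:
            raise InvalidParameterError(f"need 0 <= r <= nf, got r={self.r}, nf={self.nf}")


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria–Delbrück pmf ``P(R = r)`` for ``r = 0..r_max``.

    Uses the Ma–Sandri–Sarkar recursion::

        p_0 = exp(-m)
        p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1)

    which is exact under the classical model (deterministic growth, no
    selection differential, complete plating).
    """
    if m < 0:
        raise InvalidParameterError(f"m must be >= 0, got {m}")
    if r_max < 0:
        raise InvalidParameterError(f"r_max must be >= 0, got {r_max}")
    p = np.zeros(int(r_max) + 1)
    p[0] = math.exp(-m)
    if m == 0:
        return p
    for r in range(1, int(r_max) + 1):
        weights = 1.0 / (r - np.arange(r) + 1.0)  # 1/(r-i+1), i = 0..r-1
        p[r] = (m / r) * float(np.dot(p[:r], weights))
    return p


def ld_cdf_median(m: float, r_start: int = 64, r_limit: int = 1 << 22) -> int:
    """Smallest ``r`` with ``P(R <= r) >= 1/2`` under the MSS pmf.

    The support is unbounded, so the pmf is extended geometrically until the
    median is bracketed.
    """
    r_max = r_start
    while r_max <= r_limit:
        cum = np.cumsum(ld_pmf(m, r_max))
        idx = np.searchsorted(cum, 0.5)
        if idx < len(cum):
            return int(idx)
        r_max *= 2
    raise InvalidParameterError(f"median of LD({m}) not found below r={r_limit}")


def child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    """Deterministic, collision-resistant per-stream seed derivation.

    Child streams are ``SeedSequence(entropy=seed, spawn_key=key)``; the
    scheme is stable across runs and platforms, so any element of a batch can
    be regenerated in isolation.
    """
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_clone(model: LDModel, seed: SeedLike) -> CloneOutcome:
    """Simulate one clonal expansion and return its recombinant count.

    The number of recombination events is ``K ~ Poisson(m)``.  Each event
    occurs at a uniformly random point of the population increase, so under
    deterministic exponential growth the resulting recombinant sub-clone has
    ``min(nf, floor(1/u))`` descendants at sampling time, ``u ~ Uniform(0,1]``.
    The total is capped at ``nf``.
    """
    rng = _as_rng(seed)
    k = int(rng.poisson(model.m))
    if k == 0:
        return CloneOutcome(0, model.nf)
    u = 1.0 - rng.random(k)  # Uniform(0, 1]
    sizes = np.minimum(float(model.nf), np.floor(1.0 / u))
    r = min(int(sizes.sum()), model.nf)
    return CloneOutcome(r, model.nf)


def sample_ld_counts(model: LDModel, n_cultures: int, seed: int) -> np.ndarray:
    """Recombinant counts for ``n_cultures`` independent cultures.

    Element ``i`` is exactly ``simulate_clone(model, child_seed(seed, i))``,
    so individual cultures are reproducible without regenerating the batch.
    """
    if n_cultures < 1:
        raise InvalidParameterError(f"n_cultures must be >= 1, got {n_cultures}")
    out = np.empty(int(n_cultures), dtype=np.int64)
    for i in range(int(n_cultures)):
        out[i] = simulate_clone(model, child_seed(seed, i)).r
    return out
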
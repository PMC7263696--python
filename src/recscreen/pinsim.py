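"""Forward simulation of the replica-pinning screen and fluctuation tests.

This is the package's synthetic-data generator: given known per-strain
recombination rates it produces (a) colony observation tables in the exact
input format of :mod:`recscreen.pinscore` and (b) fluctuation-test count
tables in the input format of :mod:`recscreen.fluctuation`, so that every
downstream stage can be tested end to end against known ground truth.

Model of one pinned colony
--------------------------
A colony grows clonally to ``cells_per_colony`` cells; recombinant cells
accumulate per the Luria–Delbrück model (:func:`recscreen.ld.simulate_clone`)
with ``m = rate * cells_per_colony``.  A pin then transfers a without-
replacement sample of ``round(transfer_fraction * cells_per_colony)`` cells
(exact hypergeometric) to the selective plate; the colony is positive if at
least one recombinant cell is transferred.  Colonies with no transferred
recombinant are still positive with ``background_positive_prob``, a channel
that models residual growth and post-pinning recombination — it is the only
way a recombination-dead strain can score ~21% of its pinnings positive, and
it is a parameter, not a claim about mechanism.

``cells_per_colony`` (1e6) and ``transfer_fraction`` (0.008) are calibration
constants chosen once so that a wild-type rate of 1.14e-5 events/cell lands
in the 0.40–0.60 recombinant-frequency band observed for wild type, with the
0.21 background; neither is a measured property of the pinning robot.

Array geometry follows the screen design: 1536-density plates (32 x 48),
each strain pinned as a 2 x 2 quadruplicate of its 384-format position, with
``replicates / 4`` replicate plates (48 replicates -> 12 replicate plates).
Areas and circularities are drawn from simple truncated-normal observation
models; a small pinning-failure rate leaves positions empty and a small
artifact rate produces low-circularity blobs, exercising the downstream
filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError
from .fluctuation import PlatingDesign
from .ld import LDModel, child_seed, simulate_clone
from .pinscore import COLONY_COLUMNS

__all__ = [
    "AreaModel",
    "CircModel",
    "SimConfig",
    "simulate_colony_positive",
    "simulate_screen",
    "simulate_fluctuation_tables",
    "FLUCTUATION_COLUMNS",
]

FLUCTUATION_COLUMNS = ("strain", "test", "culture", "sel_count", "perm_count")

#: strains per 384-format plate; quadrupled to 1536 density (32 x 48)
_STRAINS_PER_PLATE = 384
_ROWS_384, _COLS_384 = 16, 24


@dataclass(frozen=True)
class AreaModel:
    """Pixel-area observation model (normal, truncated below).

    ``mean/sd`` describe healthy colonies; ``neg_mean/neg_sd`` the residual
    haze at selective positions whose pinning carried no recombinant.
    """

    mean: float = 400.0
    sd: float = 60.0
    neg_mean: float = 5.0
    neg_sd: float = 3.0


@dataclass(frozen=True)
class CircModel:
    """Circularity observation model (normal, clipped to [0, 1]).

    Circularity is the usual 4*pi*area/perimeter^2 shape score; true colonies
    sit near 0.95, pinning artifacts (smears, doubles) well below 0.8.
    """

    mean: float = 0.95
    sd: float = 0.03
    artifact_mean: float = 0.60
    artifact_sd: float = 0.10


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to simulate one replica-pinning screen."""

    strain_rates: Mapping[str, float]
    cells_per_colony: int = 1_000_000
    transfer_fraction: float = 0.008
    background_positive_prob: float = 0.21
    replicates: int = 48
    pin_failure_prob: float = 0.02
    artifact_prob: float = 0.02
    area_model: AreaModel = field(default_factory=AreaModel)
    circ_model: CircModel = field(default_factory=CircModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strain_rates:
            raise ConfigError("strain_rates must name at least one strain")
        if any(r < 0 for r in self.strain_rates.values()):
            raise ConfigError("recombination rates must be >= 0")
        if not 0 < self.transfer_fraction <= 1:
            raise ConfigError("transfer_fraction must be in (0, 1]")
        if self.cells_per_colony < 2:
            raise ConfigError("cells_per_colony must be >= 2")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.replicates % 4 != 0:
            raise ConfigError(
                "replicates must be a multiple of 4 (quadruplicate placement)"
            )
        for name in ("background_positive_prob", "pin_failure_prob", "artifact_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


def simulate_colony_positive(rate: float, config: SimConfig, seed) -> bool:
    """Does one pinned colony of a strain with ``rate`` grow on selection?

    Runs the clonal-growth model, transfers a hypergeometric sample of the
    colony, and applies the background-positive channel to transfers that
    carried no recombinant.  Deterministic given ``seed`` (int, SeedSequence
    or Generator).
    """
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.cells_per_colony
    model = LDModel(m=rate * n, n0=1, nf=n)
    r = simulate_clone(model, rng).r
    n_sample = int(round(config.transfer_fraction * n))
    if r > 0 and n_sample > 0:
        transferred = int(rng.hypergeometric(r, n - r, n_sample))
    else:
        transferred = 0
    if transferred >= 1:
        return True
    return bool(rng.random() < config.background_positive_prob)


def _positions_1536(index_384: int) -> List[Tuple[int, int]]:
    """Quadruplicate 1536-density positions of one 384-format slot (1-based)."""
    r384, c384 = divmod(index_384, _COLS_384)
    top, left = 2 * r384 + 1, 2 * c384 + 1
    return [(top, left), (top, left + 1), (top + 1, left), (top + 1, left + 1)]


def simulate_screen(config: SimConfig) -> pd.DataFrame:
    """Simulate a full screen; returns one tidy colony table for both media.

    Strains are laid out in batches of 384; batch ``b`` is pinned to
    ``replicates / 4`` replicate plates named ``B{b}R{j}``, each carrying the
    quadruplicate of every strain in the batch on both the permissive and the
    selective medium (paired positions share ``plate_id, row, col``).  Output
    is byte-identical for identical configs: all randomness flows from
    ``config.seed`` through per-plate child streams.
    """
    strains = list(config.strain_rates)
    n_plates = config.replicates // 4
    rows: List[tuple] = []
    am, cm = config.area_model, config.circ_model
    for b in range(0, len(strains), _STRAINS_PER_PLATE):
        batch = strains[b : b + _STRAINS_PER_PLATE]
        batch_idx = b // _STRAINS_PER_PLATE
        for j in range(n_plates):
            plate_id = f"B{batch_idx}R{j}"
            rng = np.random.default_rng(child_seed(config.seed, batch_idx, j))
            for slot, strain in enumerate(batch):
                rate = float(config.strain_rates[strain])
                for row, col in _positions_1536(slot):
                    if rng.random() < config.pin_failure_prob:
                        continue  # pin did not take: absent on both media
                    positive = simulate_colony_positive(rate, config, rng)
                    if rng.random() < config.artifact_prob:
                        p_area = max(1.0, rng.normal(am.mean / 4, am.sd))
                        p_circ = float(
                            np.clip(rng.normal(cm.artifact_mean, cm.artifact_sd), 0, 1)
                        )
                    else:
                        p_area = max(1.0, rng.normal(am.mean, am.sd))
                        p_circ = float(np.clip(rng.normal(cm.mean, cm.sd), 0, 1))
                    rows.append(
                        (plate_id, row, col, strain, "permissive", p_area, p_circ)
                    )
                    if positive:
                        s_area = max(1.0, rng.normal(am.mean, am.sd))
                    else:
                        s_area = max(0.0, rng.normal(am.neg_mean, am.neg_sd))
                    s_circ = float(np.clip(rng.normal(cm.mean, cm.sd), 0, 1))
                    rows.append(
                        (plate_id, row, col, strain, "selective", s_area, s_circ)
                    )
    return pd.DataFrame(rows, columns=list(COLONY_COLUMNS))


def simulate_fluctuation_tables(
    rates: Mapping[str, float],
    design: PlatingDesign,
    n_cultures: int = 5,
    n_tests: int = 1,
    seed: int = 0,
    culture_cells: int = 400_000_000,
) -> pd.DataFrame:
    """Simulate fluctuation-test count tables for the rate estimator.

    Each culture grows to ``culture_cells`` viable cells (default 4e8: a
    4 ml culture at ~1e8 cells/ml) accumulating recombinants per the
    Luria–Delbrück model; plating is binomial subsampling at the design's
    plated fractions (selective plates sample the recombinants, permissive
    plates the whole culture).  Output columns:
    ``strain, test, culture, sel_count, perm_count``.
    """
    if n_cultures < 1 or n_tests < 1:
        raise InvalidParameterError("n_cultures and n_tests must be >= 1")
    if culture_cells < 2:
        raise InvalidParameterError("culture_cells must be >= 2")
    frac_sel = min(design.sel_plated_fraction, 1.0)
    frac_perm = min(design.perm_plated_fraction, 1.0)
    rows: List[tuple] = []
    for s_idx, (strain, rate) in enumerate(rates.items()):
        if rate < 0:
            raise InvalidParameterError(f"negative rate for strain {strain}")
        model = LDModel(m=rate * culture_cells, n0=1, nf=culture_cells)
        for t in range(n_tests):
            for c in range(n_cultures):
                rng = np.random.default_rng(child_seed(seed, s_idx, t, c))
                r = simulate_clone(model, rng).r
                sel = int(rng.binomial(r, frac_sel)) if r > 0 else 0
                perm = int(rng.binomial(culture_cells, frac_perm))
                rows.append((strain, t, c, sel, perm))
    return pd.DataFrame(rows, columns=list(FLUCTUATION_COLUMNS))
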
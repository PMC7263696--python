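"""Scoring of replica-pinning colony arrays into recombinant frequencies.

Input is a tidy colony table from paired plate scans — one row per pinned
position per medium with pixel ``area`` and a ``circularity`` shape score in
[0, 1] (the usual 4*pi*area/perimeter^2 convention; this module consumes the
score, it never recomputes it from images).  Permissive plates (rich medium
plus selection for the deletion cassette) count total viable pinnings;
selective plates (medium lacking leucine) count pinnings that carried or
acquired a recombination event.

The filter chain, applied in order:

1. drop colonies with circularity <= ``circularity_min`` (artifact removal);
2. score a permissive colony iff its area exceeds ``perm_area_frac`` (default
   50%) of the mean area of circularity-passing permissive colonies on the
   same plate;
3. score a selective colony iff its position-paired permissive colony was
   scored and its area exceeds ``sel_area_frac`` (default 10%) of the mean
   scored permissive area of its strain;
4. per strain, frequency = scored selective / scored permissive; strains with
   fewer than ``min_colonies`` scored permissive colonies are excluded, as
   are strains on an explicit exclusion list (e.g. deletion-collection
   strains carrying a confounding secondary msh3 mutation) — the latter keep
   a reported frequency for distribution analysis but are dropped from hit
   calling.

All area/circularity thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "ScreenConfig",
    "COLONY_COLUMNS",
    "filter_circularity",
    "score_permissive",
    "score_selective",
    "score_colonies",
    "strain_frequencies",
    "classify",
]

log = logging.getLogger(__name__)

#: canonical column order of a colony table
COLONY_COLUMNS = (
    "plate_id",
    "row",
    "col",
    "strain_id",
    "medium",
    "area",
    "circularity",
)

_POSITION_KEY = ["plate_id", "row", "col"]


@dataclass(frozen=True)
class ScreenConfig:
    """Every threshold and exclusion of the scoring pipeline."""

    circularity_min: float = 0.8
    perm_area_frac: float = 0.5
    sel_area_frac: float = 0.10
    min_colonies: int = 10
    exclusion_strains: FrozenSet[str] = field(default_factory=frozenset)
    hyper_cutoff: float = 0.87
    hypo_cutoff: float = 0.33

    def __post_init__(self) -> None:
        if not 0 <= self.hypo_cutoff < self.hyper_cutoff <= 1:
            raise ConfigError(
                f"need 0 <= hypo_cutoff < hyper_cutoff <= 1, got "
                f"{self.hypo_cutoff}, {self.hyper_cutoff}"
            )
        for name in ("perm_area_frac", "sel_area_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.circularity_min <= 1:
            raise ConfigError("circularity_min must be in [0, 1]")
        if self.min_colonies < 1:
            raise ConfigError("min_colonies must be >= 1")
        object.__setattr__(
            self, "exclusion_strains", frozenset(self.exclusion_strains)
        )


def _validate_colonies(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLONY_COLUMNS if c not in records.columns]
    if missing:
        raise InvalidParameterError(f"colony table missing columns: {missing}")
    bad_circ = records[(records.circularity < 0) | (records.circularity > 1)]
    if len(bad_circ):
        raise InvalidParameterError(
            f"circularity outside [0,1] at rows {list(bad_circ.index[:5])}"
        )
    if (records.area < 0).any():
        raise InvalidParameterError("negative colony area")
    return records


def filter_circularity(records: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Drop artifact colonies: keep circularity strictly above the minimum."""
    records = _validate_colonies(records)
    keep = records.circularity > config.circularity_min
    removed = records[~keep]
    if len(removed):
        for plate, n in removed.groupby("plate_id").size().items():
            log.debug("plate %s: removed %d low-circularity colonies", plate, n)
    return records[keep].copy()


def score_permissive(records: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Flag permissive colonies larger than ``perm_area_frac`` of the plate mean.

    ``records`` must already be circularity-filtered.  The reference mean is
    computed per plate over the filter-passing permissive colonies, which
    absorbs plate-to-plate pinning and imaging differences.  Plates with no
    passing colonies contribute nothing (logged).
    """
    perm = records[records.medium == "permissive"].copy()
    if perm.empty:
        perm["scored"] = pd.Series(dtype=bool)
        return perm
    plate_mean = perm.groupby("plate_id")["area"].transform("mean")
    perm["scored"] = perm["area"] > config.perm_area_frac * plate_mean
    return perm


def score_selective(
    records: pd.DataFrame,
    permissive_scored: pd.DataFrame,
    config: ScreenConfig,
) -> pd.DataFrame:
    """Flag selective colonies by the paired-position, strain-mean rule.

    A selective colony is scored iff (a) the permissive colony at the same
    (plate, row, col) was scored and (b) its own area strictly exceeds
    ``sel_area_frac`` times the mean area of its strain's *scored* permissive
    colonies.  Selective colonies without a scored permissive partner are
    never scored, which also guarantees frequency <= 1 downstream.
    """
    sel = records[records.medium == "selective"].copy()
    if sel.empty:
        sel["scored"] = pd.Series(dtype=bool)
        return sel
    scored_perm = permissive_scored[permissive_scored.scored]
    strain_mean = scored_perm.groupby("strain_id")["area"].mean()
    partner = permissive_scored.set_index(_POSITION_KEY)["scored"]
    idx = pd.MultiIndex.from_frame(sel[_POSITION_KEY])
    partner_vals = partner.reindex(idx).to_numpy(dtype=object)
    partner_scored = np.where(pd.isna(partner_vals), False, partner_vals).astype(bool)
    ref = sel["strain_id"].map(strain_mean).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        big_enough = sel["area"].to_numpy(dtype=float) > config.sel_area_frac * ref
    big_enough = np.where(np.isnan(ref), False, big_enough)
    sel["scored"] = partner_scored & big_enough
    return sel


def score_colonies(
    records: pd.DataFrame, config: ScreenConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full filter chain; returns (permissive, selective) scored tables."""
    kept = filter_circularity(records, config)
    perm = score_permissive(kept, config)
    sel = score_selective(kept, perm, config)
    return perm, sel


def strain_frequencies(
    permissive_scored: pd.DataFrame,
    selective_scored: pd.DataFrame,
    config: ScreenConfig,
) -> pd.DataFrame:
    """Per-strain recombinant frequencies with exclusion bookkeeping.

    Returns a DataFrame indexed 0..n-1 with columns ``strain_id, n_total,
    n_recombinant, frequency, excluded, exclusion_reason``.  Excluded strains
    (too few scored permissive colonies, or on the exclusion list) keep their
    frequency — list-excluded strains in particular remain usable for
    distribution analysis — but must not enter hit calling.
    """
    n_total = (
        permissive_scored.groupby("strain_id")["scored"].sum().astype(int)
    )
    n_rec = selective_scored.groupby("strain_id")["scored"].sum().astype(int)
    out = pd.DataFrame(
        {
            "n_total": n_total,
            "n_recombinant": n_rec.reindex(n_total.index).fillna(0).astype(int),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["frequency"] = np.where(
            out.n_total > 0, out.n_recombinant / out.n_total, np.nan
        )
    reason = np.full(len(out), "none", dtype=object)
    too_few = (out.n_total < config.min_colonies).to_numpy()
    reason[too_few] = "too-few-colonies"
    listed = out.index.isin(config.exclusion_strains)
    reason[listed & ~too_few] = "msh3-list"
    out["excluded"] = too_few | listed
    out["exclusion_reason"] = reason
    out.index.name = "strain_id"
    return out.reset_index()


def classify(frequencies: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Assign hyper / hypo / unclassified calls to non-excluded strains.

    ``frequency >= hyper_cutoff`` is a hyper-recombination call,
    ``frequency <= hypo_cutoff`` a recombination-deficient call.  Excluded
    strains get class ``excluded``.
    """
    out = frequencies.copy()
    cls = np.full(len(out), "unclassified", dtype=object)
    freq = out["frequency"].to_numpy(dtype=float)
    cls[freq >= config.hyper_cutoff] = "hyper"
    cls[freq <= config.hypo_cutoff] = "hypo"
    cls[out["excluded"].to_numpy(dtype=bool)] = "excluded"
    out["class"] = cls
    return out


def load_exclusion_list(path) -> FrozenSet[str]:
    """Read a plain-text exclusion list, one strain id per line, '#' comments."""
    strains = set()
    with open(path) as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                strains.add(name)
    return frozenset(strains)
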
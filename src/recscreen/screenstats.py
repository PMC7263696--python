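"""Screen-integration statistics: distributions, overlaps, hit lists.

Integrates the two screening arms (patch/replica-plating with fluctuation
validation; high-throughput replica pinning) into gene sets, quantifies the
agreement between them with a hypergeometric overlap test, summarizes
recombinant-frequency distributions (e.g. the contrast between strains
carrying a confounding secondary msh3 mutation and the rest of the deletion
collection), and counts human-ortholog coverage of the validated hit list.

The package ships tab-separated transcriptions of the published hit tables
as fixtures (``recscreen/data``): the 33 fluctuation-validated patch-screen
genes (plus the wild-type reference row), the 75 hyper- and 122
hypo-recombination pinning-screen genes at the 87%/33% frequency cutoffs,
and the 35 validated hyper-recombination genes with their human orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Iterable, Optional, Set

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import InvalidParameterError, ParseError

__all__ = [
    "GeneSet",
    "OverlapResult",
    "HitLists",
    "hypergeom_overlap",
    "hypergeom_tail",
    "assemble_hits",
    "ortholog_summary",
    "distribution_summary",
    "load_fixture",
    "DEFAULT_UNIVERSE",
]

#: default gene universe for the screen-overlap test: ~4500 deletion strains
#: actually obtained after introducing the recombination reporter.
DEFAULT_UNIVERSE = 4500

#: histogram bin width for frequency distributions on [0, 1]
HIST_BIN_WIDTH = 0.05

_CONTROL_NAMES = frozenset({"WT", "WILD-TYPE", "WILDTYPE"})


@dataclass(frozen=True)
class GeneSet:
    """A named set of yeast gene identifiers (uppercased, no controls)."""

    name: str
    genes: FrozenSet[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        cleaned = []
        for g in genes:
            g = str(g).strip().upper()
            if not g or g in _CONTROL_NAMES:
                continue
            cleaned.append(g)
        if len(cleaned) != len(set(cleaned)):
            dupes = sorted({g for g in cleaned if cleaned.count(g) > 1})
            raise InvalidParameterError(f"duplicate genes in set {name!r}: {dupes}")
        return cls(name=name, genes=frozenset(cleaned))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    """Intersection of two gene sets under a hypergeometric null.

    ``p_value`` is the upper tail P(X >= k) for drawing ``n`` genes from a
    universe of ``N`` containing ``K`` marked genes; ``log10_p`` is computed
    in log space and remains meaningful when ``p_value`` underflows.
    """

    k: int
    K: int
    n: int
    N: int
    p_value: float
    log10_p: float


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log C(K,i) + log C(N-K, n-i) - log C(N, n), vectorized over i."""

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, i) + logc(N - K, n - i) - logc(N, n)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """log10 of P(X >= k), X ~ Hypergeometric(N, K, n), summed in log space."""
    if k <= 0:
        return 0.0
    hi = min(K, n)
    if k > hi:
        raise InvalidParameterError("k exceeds min(K, n)")
    i = np.arange(k, hi + 1)
    return float(logsumexp(_log_hypergeom_pmf(i, N, K, n)) / math.log(10))


def hypergeom_overlap(
    set_a: GeneSet, set_b: GeneSet, universe: int = DEFAULT_UNIVERSE
) -> OverlapResult:
    """Overlap of two gene sets with an upper-tail hypergeometric p-value.

    The null: ``|B|`` genes drawn uniformly without replacement from a
    universe of ``universe`` genes of which ``|A|`` are marked; the observed
    statistic is ``k = |A & B|``.  The universe must contain both sets.
    """
    k = len(set_a.genes & set_b.genes)
    K, n = len(set_a), len(set_b)
    if universe < len(set_a.genes | set_b.genes):
        raise InvalidParameterError(
            f"universe {universe} smaller than |A u B| = "
            f"{len(set_a.genes | set_b.genes)}"
        )
    log10_p = hypergeom_tail(k, universe, K, n)
    return OverlapResult(
        k=k, K=K, n=n, N=universe, p_value=10.0 ** log10_p, log10_p=log10_p
    )


# ---------------------------------------------------------------------------
# fixtures / hit lists


def _validate_gene_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    if "gene" not in df.columns:
        raise ParseError(f"{label} lacks a 'gene' column")
    blank = df.index[df.gene.astype(str).str.strip() == ""]
    if len(blank):
        raise ParseError(f"{label}: empty gene name at row {blank[0] + 2}")
    return df


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged hit-table fixture by file name."""
    ref = resources.files("recscreen.data").joinpath(name)
    if not ref.is_file():
        raise ParseError(f"no packaged fixture named {name!r}")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _validate_gene_table(df, f"fixture {name!r}")


@dataclass(frozen=True)
class HitLists:
    """The assembled gene sets of the two screens.

    ``validated_union`` is the patch-validated set plus the pinning-screen
    genes additionally confirmed by fluctuation analysis; it equals the
    published validated hyper-recombination list, and ``extra_validated``
    holds the pinning-only members of that union.
    """

    patch_validated: GeneSet
    pinning_hyper: GeneSet
    pinning_hypo: GeneSet
    validated_union: GeneSet

    @property
    def extra_validated(self) -> FrozenSet[str]:
        return self.validated_union.genes - self.patch_validated.genes


def assemble_hits(
    patch: Optional[pd.DataFrame] = None,
    pinning_hyper: Optional[pd.DataFrame] = None,
    pinning_hypo: Optional[pd.DataFrame] = None,
    validated: Optional[pd.DataFrame] = None,
) -> HitLists:
    """Build the four gene sets from fixture tables (packaged by default)."""
    patch = load_fixture("patch_validated.tsv") if patch is None else patch
    pinning_hyper = (
        load_fixture("pinning_hyper.tsv") if pinning_hyper is None else pinning_hyper
    )
    pinning_hypo = (
        load_fixture("pinning_hypo.tsv") if pinning_hypo is None else pinning_hypo
    )
    validated = (
        load_fixture("validated_hyper_rec.tsv") if validated is None else validated
    )
    for label, df in (
        ("patch table", patch),
        ("pinning hyper table", pinning_hyper),
        ("pinning hypo table", pinning_hypo),
        ("validated table", validated),
    ):
        _validate_gene_table(df, label)
    lists = HitLists(
        patch_validated=GeneSet.from_iterable("patch-validated", patch.gene),
        pinning_hyper=GeneSet.from_iterable("pinning-hyper", pinning_hyper.gene),
        pinning_hypo=GeneSet.from_iterable("pinning-hypo", pinning_hypo.gene),
        validated_union=GeneSet.from_iterable("validated-union", validated.gene),
    )
    if not lists.patch_validated.genes <= lists.validated_union.genes:
        missing = sorted(lists.patch_validated.genes - lists.validated_union.genes)
        raise ParseError(
            f"patch-validated genes absent from the validated union: {missing}"
        )
    if lists.pinning_hyper.genes & lists.pinning_hypo.genes:
        raise ParseError("a gene appears in both pinning hyper and hypo lists")
    return lists


def ortholog_summary(table: pd.DataFrame) -> int:
    """Count genes with at least one human ortholog.

    ``table`` needs ``gene`` and ``human_orthologs`` columns; orthologs are a
    comma-separated (possibly empty) list per row, one row per gene.
    """
    for col in ("gene", "human_orthologs"):
        if col not in table.columns:
            raise ParseError(f"ortholog table lacks column {col!r}")
    if table.gene.duplicated().any():
        raise ParseError("ortholog table has duplicate gene rows")
    orth = table.human_orthologs.fillna("").astype(str).str.strip()
    return int((orth != "").sum())


# ---------------------------------------------------------------------------
# frequency distributions


def distribution_summary(
    frequencies: pd.DataFrame, group_flag: Set[str]
) -> Dict[str, object]:
    """Contrast recombinant frequencies of a flagged strain group vs the rest.

    ``frequencies`` is a per-strain table with ``strain_id`` and ``frequency``
    columns (the output of :func:`recscreen.pinscore.strain_frequencies`;
    exclusion flags are ignored here because list-excluded strains still
    belong in distribution plots).  Returns group/rest/overall medians plus
    histograms binned at 0.05 on [0, 1].
    """
    if "strain_id" not in frequencies.columns or "frequency" not in frequencies.columns:
        raise InvalidParameterError("need strain_id and frequency columns")
    group_flag = {str(s) for s in group_flag}
    if not group_flag:
        raise InvalidParameterError("group_flag is empty")
    freq = frequencies.dropna(subset=["frequency"])
    in_group = freq.strain_id.isin(group_flag)
    if not in_group.any():
        raise InvalidParameterError("no flagged strain has a defined frequency")
    bins = np.arange(0, 1 + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH)
    g = freq.loc[in_group, "frequency"].to_numpy(dtype=float)
    rest = freq.loc[~in_group, "frequency"].to_numpy(dtype=float)
    return {
        "group_median": float(np.median(g)),
        "rest_median": float(np.median(rest)) if rest.size else math.nan,
        "overall_median": float(np.median(freq.frequency.to_numpy(dtype=float))),
        "group_n": int(g.size),
        "rest_n": int(rest.size),
        "bins": bins,
        "group_hist": np.histogram(np.clip(g, 0, 1), bins=bins)[0],
        "rest_hist": np.histogram(np.clip(rest, 0, 1), bins=bins)[0],
    }
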
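"""Shared plumbing: strict table I/O, config loading, run manifests.

All tables are plain tab-separated text with a mandatory header that must
match the declared schema exactly (same columns, same order) — the formats
stay diffable and any drift between producer and consumer fails loudly with
a row/column-named error rather than silently coercing.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .errors import ConfigError, ParseError

__all__ = [
    "TableSchema",
    "COLONY_SCHEMA",
    "FLUCTUATION_SCHEMA",
    "FREQUENCY_SCHEMA",
    "RATE_SCHEMA",
    "read_table",
    "write_table",
    "load_config",
    "RunManifest",
    "file_digest",
    "run_pipeline",
]


@dataclass(frozen=True)
class TableSchema:
    """Column names -> dtypes, plus an optional uniqueness key.

    ``optional`` columns may be absent from a file; when present they are
    type-checked like any other.
    """

    name: str
    columns: Mapping[str, type]
    key: Tuple[str, ...] = ()
    optional: Tuple[str, ...] = ()

    @property
    def required(self) -> Tuple[str, ...]:
        return tuple(c for c in self.columns if c not in self.optional)


COLONY_SCHEMA = TableSchema(
    name="colony",
    columns={
        "plate_id": str,
        "row": int,
        "col": int,
        "strain_id": str,
        "medium": str,
        "area": float,
        "circularity": float,
    },
    key=("plate_id", "row", "col", "medium"),
)

FLUCTUATION_SCHEMA = TableSchema(
    name="fluctuation",
    columns={
        "strain": str,
        "test": int,
        "culture": int,
        "sel_count": int,
        "perm_count": int,
    },
    key=("strain", "test", "culture"),
    optional=("test",),
)

FREQUENCY_SCHEMA = TableSchema(
    name="frequency",
    columns={
        "strain_id": str,
        "n_total": int,
        "n_recombinant": int,
        "frequency": float,
        "excluded": bool,
        "exclusion_reason": str,
        "class": str,
    },
    key=("strain_id",),
    optional=("class",),
)

RATE_SCHEMA = TableSchema(
    name="rate",
    columns={
        "strain": str,
        "rate": float,
        "m_hat": float,
        "median_r": float,
        "status": str,
        "p_value": float,
        "verdict": str,
    },
    key=("strain",),
    optional=("p_value", "verdict"),
)


_DTYPE_CHECKS = {
    int: pd.api.types.is_integer_dtype,
    float: pd.api.types.is_numeric_dtype,
    bool: pd.api.types.is_bool_dtype,
    str: pd.api.types.is_object_dtype,
}


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a tab-separated table against ``schema``.

    The header must contain exactly the schema's columns in order (optional
    columns may be omitted from the tail of the permitted set).  Fields are
    type-checked and the uniqueness key enforced; errors name the offending
    column and 1-based file row.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    header = header_line.split("\t") if header_line else []
    allowed = list(schema.columns)
    missing = [c for c in schema.required if c not in header]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing} in header")
    unknown = [c for c in header if c not in allowed]
    if unknown:
        raise ParseError(f"{path.name}: unknown column(s) {unknown} in header")
    expected_order = [c for c in allowed if c in header]
    if header != expected_order:
        raise ParseError(
            f"{path.name}: header order {header} != schema order {expected_order}"
        )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for col in header:
        want = schema.columns[col]
        raw = df[col]
        try:
            if want is int:
                out[col] = pd.to_numeric(raw).astype("int64")
            elif want is float:
                blanked = raw.mask(raw.str.strip() == "", other=None)
                out[col] = pd.to_numeric(blanked).astype(float)
            elif want is bool:
                lowered = raw.str.lower()
                bad = ~lowered.isin(["true", "false", "0", "1"])
                if bad.any():
                    raise ValueError(f"row {bad.idxmax() + 2}")
                out[col] = lowered.isin(["true", "1"])
            else:
                out[col] = raw
        except (ValueError, TypeError) as exc:
            first_bad = _first_bad_row(raw, want)
            raise ParseError(
                f"{path.name}: column {col!r} is not {want.__name__} "
                f"(first offending file row {first_bad})"
            ) from exc
    result = pd.DataFrame(out)
    if schema.key:
        key_cols = [c for c in schema.key if c in result.columns]
        dup = result.duplicated(subset=key_cols)
        if dup.any():
            row = int(dup.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path.name}: duplicate key {tuple(key_cols)} at file row {row}"
            )
    return result


def _first_bad_row(raw: pd.Series, want: type) -> int:
    for i, v in raw.items():
        try:
            (int if want is int else float)(v)
        except (ValueError, TypeError):
            return int(i) + 2
    return -1


def write_table(df: pd.DataFrame, path, schema: Optional[TableSchema] = None) -> None:
    """Write a table as tab-separated text; round trips with read_table."""
    if schema is not None:
        cols = [c for c in schema.columns if c in df.columns]
        missing = [c for c in schema.required if c not in df.columns]
        if missing:
            raise ParseError(f"cannot write {schema.name} table: missing {missing}")
        df = df[cols]
    df.to_csv(path, sep="\t", index=False)


def demo_config() -> dict:
    """The packaged demo screen configuration (see data/demo_config.yaml)."""
    from importlib import resources

    ref = resources.files("recscreen.data").joinpath("demo_config.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def file_digest(path) -> str:
    """sha256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output.

    Re-running the named command with the recorded config and seed must
    reproduce the outputs byte-identically; all randomness flows from
    ``seed``.
    """

    command: str
    config: dict
    seed: int
    input_digests: Dict[str, str] = field(default_factory=dict)
    output_digests: Dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: dict, out_dir, seed: int) -> RunManifest:
    """Run simulate -> score -> integrate end to end into ``out_dir``.

    ``config`` keys (all optional except ``strain_rates``):

    - ``strain_rates``: mapping strain -> per-cell recombination rate
    - ``sim``: overrides for :class:`recscreen.pinsim.SimConfig`
    - ``screen``: overrides for :class:`recscreen.pinscore.ScreenConfig`
    - ``universe``: gene universe for the self-check overlap test
    - ``truth_rate_min``: rate above which a simulated strain counts as a
      true hyper-recombinant for the overlap self-check (default 5x the
      minimum supplied rate, or 2e-5 if all rates are equal)

    Writes ``colonies.tsv``, ``frequencies.tsv``, ``summary.json`` and
    ``manifest.json``; returns the manifest.
    """
    from . import pinscore, pinsim, screenstats  # local import avoids cycles

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "strain_rates" not in config or not config["strain_rates"]:
        raise ConfigError("config must provide a non-empty strain_rates mapping")
    rates = {str(k): float(v) for k, v in config["strain_rates"].items()}

    stage = "simulate"
    try:
        sim_kwargs = dict(config.get("sim", {}))
        sim_cfg = pinsim.SimConfig(strain_rates=rates, seed=int(seed), **sim_kwargs)
        colonies = pinsim.simulate_screen(sim_cfg)
        write_table(colonies, out_dir / "colonies.tsv", COLONY_SCHEMA)

        stage = "score"
        screen_kwargs = dict(config.get("screen", {}))
        if "exclusion_strains" in screen_kwargs:
            screen_kwargs["exclusion_strains"] = frozenset(
                screen_kwargs["exclusion_strains"]
            )
        screen_cfg = pinscore.ScreenConfig(**screen_kwargs)
        perm, sel = pinscore.score_colonies(colonies, screen_cfg)
        freqs = pinscore.classify(
            pinscore.strain_frequencies(perm, sel, screen_cfg), screen_cfg
        )
        write_table(freqs, out_dir / "frequencies.tsv", FREQUENCY_SCHEMA)

        stage = "integrate"
        called = freqs[(freqs["class"] == "hyper")]
        truth_min = config.get("truth_rate_min")
        if truth_min is None:
            lo = min(rates.values())
            truth_min = 5 * lo if lo > 0 else 2e-5
        truth = {s for s, r in rates.items() if r >= float(truth_min)}
        universe = int(config.get("universe", len(rates)))
        summary: dict = {
            "n_strains": int(len(freqs)),
            "n_excluded": int(freqs.excluded.sum()),
            "class_counts": freqs["class"].value_counts().to_dict(),
        }
        if truth and len(called):
            ov = screenstats.hypergeom_overlap(
                screenstats.GeneSet.from_iterable("true-hyper", truth),
                screenstats.GeneSet.from_iterable("called-hyper", called.strain_id),
                universe=max(universe, len(rates)),
            )
            summary["hyper_call_overlap"] = {
                "k": ov.k, "K": ov.K, "n": ov.n, "N": ov.N,
                "p_value": ov.p_value, "log10_p": ov.log10_p,
            }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = RunManifest(
        command="run",
        config=config,
        seed=int(seed),
        output_digests={
            name: file_digest(out_dir / name)
            for name in ("colonies.tsv", "frequencies.tsv", "summary.json")
        },
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
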
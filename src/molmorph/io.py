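"""File formats: Newick trees, measurement/summary/trait CSV schemas, config.

All CSV schemas are versioned here in one place; every reader validates the
header and names the missing column in its error.  Coordinates are 0-based,
intervals half-open, CSVs UTF-8 with "." decimals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("molmorph")

SCHEMA_VERSION = 1

MEASUREMENT_COLUMNS = [
    "fly_id", "species", "sex", "segment", "side", "F_A", "F_B", "ratio",
]
SUMMARY_COLUMNS = [
    "species", "sex", "segment", "n", "N", "mean", "SEM", "min", "max",
]
TRAIT_COLUMNS = ["species", "state"]
COUNTS_COLUMNS = ["species", "fly_id", "fiber_count"]
NUCLEI_COLUMNS = ["fly_id", "species", "x", "y"]


class SchemaError(ValueError):
    """A CSV does not match its declared schema."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV is missing column(s): {', '.join(missing)}")


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, MEASUREMENT_COLUMNS, "measurement")
    if (df["F_A"] <= 0).any() or (df["F_B"] <= 0).any():
        raise SchemaError("measurement CSV contains non-positive Feret diameters")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, MEASUREMENT_COLUMNS, "measurement")
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_traits(path: str | Path) -> dict[str, object]:
    """Traits CSV species,state with state in {0, 1, ?}."""
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, TRAIT_COLUMNS, "trait")
    out: dict[str, object] = {}
    for _, row in df.iterrows():
        s = str(row["state"]).strip()
        if s not in {"0", "1", "?"}:
            raise SchemaError(
                f"trait state for {row['species']!r} must be 0, 1 or ?, got {s!r}"
            )
        out[str(row["species"])] = s if s == "?" else int(s)
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, COUNTS_COLUMNS, "fiber-count")
    return df


def read_nuclei(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, NUCLEI_COLUMNS, "nuclei")
    return df


# ---------------------------------------------------------------------------
# Newick


def read_newick(text_or_path: str | Path, *, is_path: bool | None = None) -> dendropy.Tree:
    """Parse one rooted Newick tree; missing branch lengths default to 1.0.

    Raises a parse error on malformed input; duplicate tip labels are
    rejected.
    """
    if is_path is None:
        is_path = isinstance(text_or_path, Path) or (
            isinstance(text_or_path, str)
            and "(" not in text_or_path
        )
    if is_path:
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.utility.error.DataParseError as err:
        if "Multiple occurrences" in str(err):
            raise ValueError(f"duplicate tip label: {err}") from err
        raise
    tree.is_rooted = True
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip label(s): {', '.join(dup)}")
    defaulted = False
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = 1.0
            defaulted = True
    if defaulted:
        warnings.warn("tree has missing branch lengths; defaulted to 1.0",
                      stacklevel=2)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree_list(path: str | Path) -> list[dendropy.Tree]:
    """A multi-tree file: one Newick string per line."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            trees.append(read_newick(line, is_path=False))
    return trees


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All module defaults in one plain-text (YAML key-value) config.

    CLI flags override config values; ``dump``/``load`` round-trip
    losslessly.
    """

    threshold_fraction: float = 0.14
    min_area: int = 50
    gap_factor: float = 3.0
    alpha: float = 0.05
    alpha_call: float = 0.001
    mcmc_generations: int = 50_000
    mcmc_chains: int = 4
    mcmc_sample_every: int = 100
    mcmc_burnin_fraction: float = 0.25
    mcmc_proposal_scale: float = 0.8
    seed: int = 20210727

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)
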
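"""Packaged reference tables and the consensus-topology fixture tree.

The dimorphism table holds, per montium-group species, the published
summary statistics of the standardized muscle-size ratio F_A/F_B for the
female A5, male A4 and male A5 groups (hemisegment count n, individual
count N, mean, SEM, min, max), the statistical test family used, the two
multiplicity-adjusted pairwise P values (as printed, e.g. "<0.001") and the
"+"/"−" dimorphism call.  The fiber table holds per-species fiber-count
summaries with compact-display letters for 19 dimorphic montium species
plus 2 outgroup species.  The fiber table's watanabei Min/Max pair is
printed transposed in the source and is stored corrected (1, 3).

The fixture tree is a 49-taxon rooted topology (42 montium species + 7
outgroup species) transcribed from the consensus figure and standard
montium-group relationships.  Branch lengths are unpublished; unit
placeholder lengths are used, so conclusions drawn on this tree are
qualitative (majority-state) only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

from .io import read_newick

__all__ = ["FixtureTables", "load_fixtures", "parse_printed_p", "data_path"]

N_MONTIUM = 42
N_FIBER_ROWS = 21
N_FIBER_INGROUP = 19
N_OUTGROUP = 7


class FixtureError(RuntimeError):
    """Packaged data failed its load-time validation."""


def data_path(name: str) -> Path:
    return Path(resources.files("molmorph").joinpath("data", name))


def parse_printed_p(p: str) -> float:
    """Numeric surrogate for a printed P value.

    "<x" becomes x/2, ">x" becomes (x+1)/2, plain numbers parse directly.
    The surrogates preserve the ordering used by the strict call rule:
    "<0.001" satisfies P < 0.001, "0.001" does not.
    """
    p = p.strip().replace(" ", "")
    if p.startswith("<"):
        return float(p[1:]) / 2.0
    if p.startswith(">"):
        return (float(p[1:]) + 1.0) / 2.0
    return float(p)


@dataclass(frozen=True)
class FixtureTables:
    table1: pd.DataFrame
    table2: pd.DataFrame
    outgroup_states: dict[str, int]
    outgroup_summaries: pd.DataFrame
    tree: dendropy.Tree

    def tip_states(self) -> dict[str, int]:
        """Binary dimorphism states for every fixture-tree tip."""
        states = {
            r.species: 1 if r.call == "+" else 0
            for r in self.table1.itertuples()
        }
        states.update(self.outgroup_states)
        return states


def _validate_stats_block(df: pd.DataFrame, prefix: str) -> None:
    bad = df[
        ~(
            (df[f"{prefix}_min"] <= df[f"{prefix}_mean"])
            & (df[f"{prefix}_mean"] <= df[f"{prefix}_max"])
        )
    ]
    if len(bad):
        raise FixtureError(
            f"min <= mean <= max violated in block {prefix} for "
            f"{', '.join(bad['species'])}"
        )


def load_fixtures() -> FixtureTables:
    """Load and validate all packaged reference data."""
    t1 = pd.read_csv(data_path("table1_dimorphism.csv"))
    if len(t1) != N_MONTIUM:
        raise FixtureError(f"dimorphism table must have {N_MONTIUM} rows, got {len(t1)}")
    for block in ("female_A5", "male_A4", "male_A5"):
        _validate_stats_block(t1, block)
    if not set(t1["call"]) <= {"+", "-"}:
        raise FixtureError("dimorphism calls must be '+' or '-'")
    t1 = t1.assign(
        p_f5_m5_value=t1["p_f5_m5"].map(parse_printed_p),
        p_m4_m5_value=t1["p_m4_m5"].map(parse_printed_p),
    )

    t2 = pd.read_csv(data_path("table2_fibers.csv"))
    if len(t2) != N_FIBER_ROWS or int(t2["ingroup"].sum()) != N_FIBER_INGROUP:
        raise FixtureError("fiber table row counts do not match the reference")
    if not ((t2["min"] <= t2["mean"]) & (t2["mean"] <= t2["max"])).all():
        raise FixtureError("fiber table violates min <= mean <= max")

    og = pd.read_csv(data_path("outgroup_states.csv"))
    if len(og) != N_OUTGROUP:
        raise FixtureError(f"expected {N_OUTGROUP} outgroup species")
    outgroup_states = dict(zip(og["species"], og["state"].astype(int)))

    out_sum = pd.read_csv(data_path("outgroup_summaries.csv"))

    tree = read_newick(data_path("consensus_tree.nwk"))
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    expected = set(t1["species"]) | set(outgroup_states)
    if tips != expected:
        raise FixtureError(
            "fixture tree tips do not match the packaged species tables"
        )

    return FixtureTables(
        table1=t1,
        table2=t2,
        outgroup_states=outgroup_states,
        outgroup_summaries=out_sum,
        tree=tree,
    )


# Named clades used for qualitative ancestral-state checks: each maps to the
# exact tip set whose MRCA is interrogated.
CLADES: dict[str, frozenset] = {
    "parvula_subgroup": frozenset({"kanapiae", "parvula"}),
    "seguyi_subgroup": frozenset(
        {"seguyi", "vulcana", "nikananu", "malagassya", "burlai", "jambulina",
         "diplacantha", "greeni", "tsacasi"}
    ),
    "punjabiensis_orosa": frozenset({"punjabiensis", "watanabei", "orosa"}),
    "auraria_rufa_complex": frozenset(
        {"auraria", "subauraria", "biauraria", "triauraria", "rufa", "tani",
         "asahinai", "neoasahinai"}
    ),
}
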
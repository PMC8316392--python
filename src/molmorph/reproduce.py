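"""End-to-end reproduction helpers built on the packaged reference tables.

Three levels of reproduction are distinguished:

* ``recompute_calls`` — re-applies the dimorphism call rule (male A5 mean >
  female A5 mean AND adjusted P < 0.001, strict) to the published summary
  statistics; a pure regression of the published "+"/"−" column.
* ``simulate_calls`` — draws fresh per-hemisegment ratio samples calibrated
  to the published group means/SEMs/n (SD = SEM * sqrt(n)) and pushes them
  through the full statistical battery; species whose published adjusted P
  sits at or near the 0.001 boundary may legitimately flip.
* ``ancestral_scorecard`` — runs the MCMC reconstruction on the fixture
  tree with the published presence/absence states and reports the posterior
  probability of absence at the four focal subgroup ancestors.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .ancestral import MCMCSettings, bbm_mcmc
from .dimorphism import GroupSummary, analyze_species, call_dimorphism
from .fixtures import CLADES, FixtureTables, load_fixtures
from .synthetic import SpeciesSpec, gen_measurements

__all__ = [
    "recompute_calls",
    "species_spec_from_table1",
    "simulate_calls",
    "call_concordance",
    "fiber_extrema",
    "ancestral_scorecard",
    "scorecard",
]


def _summary_from_row(row, block: str) -> GroupSummary:
    sex, segment = block.split("_")
    n = int(getattr(row, f"{block}_n"))
    sem = float(getattr(row, f"{block}_sem"))
    return GroupSummary(
        species=row.species,
        sex=sex,
        segment=segment,
        n=n,
        N=int(row.female_N if sex == "female" else row.male_N),
        mean=float(getattr(row, f"{block}_mean")),
        SEM=sem,
        SD=sem * np.sqrt(n),
        min=float(getattr(row, f"{block}_min")),
        max=float(getattr(row, f"{block}_max")),
    )


def recompute_calls(table1: pd.DataFrame) -> pd.DataFrame:
    """Re-apply the call rule to the published statistics of every species."""
    rows = []
    for row in table1.itertuples():
        call = call_dimorphism(
            _summary_from_row(row, "female_A5"),
            _summary_from_row(row, "male_A5"),
            _summary_from_row(row, "male_A4"),
            adjusted_p_f5_m5=float(row.p_f5_m5_value),
        )
        rows.append(
            {
                "species": row.species,
                "published_call": row.call,
                "recomputed_call": "+" if call.call == "+" else "-",
                "male_mean": call.male_mean,
                "female_mean": call.female_mean,
                "adjusted_p": float(row.p_f5_m5_value),
            }
        )
    df = pd.DataFrame(rows)
    df["match"] = df["published_call"] == df["recomputed_call"]
    return df


def species_spec_from_table1(row) -> SpeciesSpec:
    """Calibrate a simulation spec from one published table row."""
    groups = {}
    for block in ("female_A5", "male_A4", "male_A5"):
        sex, segment = block.split("_")
        n = int(getattr(row, f"{block}_n"))
        sem = float(getattr(row, f"{block}_sem"))
        groups[(sex, segment)] = (
            float(getattr(row, f"{block}_mean")),
            sem * float(np.sqrt(n)),
            n,
        )
    return SpeciesSpec(species=row.species, groups=groups)


def simulate_calls(table1: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Full pipeline on synthetic measurements calibrated from the table."""
    rows = []
    for i, row in enumerate(table1.itertuples()):
        spec = species_spec_from_table1(row)
        df = gen_measurements(spec, seed=(seed * 100_003 + i) % (2**31 - 1))
        groups = {
            key: df[(df.sex == key[0]) & (df.segment == key[1])]["ratio"].to_numpy()
            for key in [("female", "A5"), ("male", "A4"), ("male", "A5")]
        }
        res = analyze_species(
            groups[("female", "A5")],
            groups[("male", "A4")],
            groups[("male", "A5")],
            species=row.species,
        )
        rows.append(
            {
                "species": row.species,
                "published_call": row.call,
                "simulated_call": "+" if res["call"].call == "+" else "-",
                "test_family": res["test_family"],
                "adjusted_p_f5_m5": res["comparisons"][
                    ("female_A5", "male_A5")
                ].adjusted_p,
            }
        )
    df = pd.DataFrame(rows)
    df["match"] = df["published_call"] == df["simulated_call"]
    return df


def call_concordance(table1: pd.DataFrame, seed: int) -> int:
    """Number of species whose simulated call matches the published one."""
    return int(simulate_calls(table1, seed)["match"].sum())


def fiber_extrema(table2: pd.DataFrame) -> dict:
    ingroup = table2[table2["ingroup"]]
    return {
        "ingroup_mean_min": float(ingroup["mean"].min()),
        "ingroup_mean_max": float(ingroup["mean"].max()),
        "global_max_fibers": int(table2["max"].max()),
        "n_ingroup": int(len(ingroup)),
    }


def ancestral_scorecard(
    fixtures: FixtureTables,
    settings: MCMCSettings,
) -> dict:
    """Posterior absence probabilities at the four focal subgroup MRCAs."""
    res = bbm_mcmc(fixtures.tree, fixtures.tip_states(), settings)
    by_bip = {p.bipartition: p for p in res["node_posteriors"]}
    out = {}
    for name, clade in CLADES.items():
        post = by_bip.get(clade)
        out[name] = {
            "p_absent": post.p_absent if post else float("nan"),
            "p_present": post.p_present if post else float("nan"),
        }
    out["_acceptance"] = res["acceptance"]
    out["_pi1_posterior_mean"] = float(np.mean(res["pi1"]))
    return out


def scorecard(seed: int = 20210727, mcmc: MCMCSettings | None = None) -> dict:
    """Fixture-based end-to-end scorecard (the `reproduce` CLI command)."""
    fx = load_fixtures()
    calls = recompute_calls(fx.table1)
    sim = simulate_calls(fx.table1, seed)
    mcmc = mcmc or MCMCSettings(seed=seed)
    anc = ancestral_scorecard(fx, mcmc)
    return {
        "n_species": int(len(fx.table1)),
        "n_plus_calls_published": int((fx.table1["call"] == "+").sum()),
        "n_plus_calls_recomputed": int((calls["recomputed_call"] == "+").sum()),
        "call_regression_matches": int(calls["match"].sum()),
        "simulated_call_concordance": int(sim["match"].sum()),
        "max_male_A5_mean": float(fx.table1["male_A5_mean"].max()),
        **fiber_extrema(fx.table2),
        "ancestral": {
            k: v for k, v in anc.items() if not k.startswith("_")
        },
    }
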
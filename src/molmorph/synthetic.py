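"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed:

* ``gen_measurements`` — per-group Gaussian ratio samples calibrated from a
  species spec (mean, SD, hemisegment count), truncated at zero; two
  hemisegments per fly, left/right independent by default.
* ``gen_image`` — rasterized muscle primitives (rotated rectangles and
  capsules) with known exact Feret diameters, plus Gaussian blur and noise.
* ``gen_nuclei`` — rows of nuclei along a muscle axis with transverse
  jitter, the ground truth for fiber counting.
* ``gen_tree`` — Yule (pure-birth) trees with unit speciation rate; the
  final inter-speciation hold time is included so the expected root-to-tip
  depth is the closed form sum_{k=2..n} 1/k.
* ``sim_trait`` — forward simulation of the binary F81 process down a tree,
  recording every internal node state (calibration ground truth).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .ancestral import CTMCParams

__all__ = [
    "SpeciesSpec",
    "MusclePrimitive",
    "ImageLayout",
    "TraitSimResult",
    "gen_measurements",
    "gen_image",
    "gen_nuclei",
    "gen_tree",
    "sim_trait",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-(sex, segment) ratio distribution for one simulated species.

    ``groups`` maps (sex, segment) -> (mean, SD, n hemisegments).  When
    calibrated from a published summary table, SD = SEM * sqrt(n).
    """

    species: str
    groups: Mapping[tuple[str, str], tuple[float, float, int]]

    def __post_init__(self) -> None:
        for key, (mean, sd, n) in self.groups.items():
            if mean <= 0 or sd < 0 or n < 1:
                raise ValueError(f"invalid group spec for {key}: {(mean, sd, n)}")


def gen_measurements(
    spec: SpeciesSpec,
    seed: int,
    *,
    lognormal: bool = False,
    bilateral_correlation: float = 0.0,
) -> pd.DataFrame:
    """Draw hemisegment ratio measurements for one species.

    Ratios are Normal(mean, SD) truncated at > 0 (or log-normal with matched
    log-moments when ``lognormal``).  Flies receive two hemisegments (left,
    right); ``bilateral_correlation`` induces within-fly correlation between
    the sides (default 0: sides independent).  F_B is reported as 1 so that
    F_A carries the ratio directly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (sex, segment), (mean, sd, n) in sorted(spec.groups.items()):
        n_flies = (n + 1) // 2
        if lognormal:
            z = rng.standard_normal((n_flies, 2))
        else:
            z = rng.standard_normal((n_flies, 2))
        if bilateral_correlation:
            rho = bilateral_correlation
            z[:, 1] = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
        if lognormal:
            s2 = math.log(1 + (sd / mean) ** 2)
            vals = np.exp(math.log(mean) - s2 / 2 + math.sqrt(s2) * z)
        else:
            vals = mean + sd * z
            bad = vals <= 0
            while bad.any():  # truncate at > 0 by redrawing
                vals[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
                bad = vals <= 0
        flat = vals.reshape(-1)[:n]
        for i, ratio in enumerate(flat):
            rows.append(
                {
                    "fly_id": f"{spec.species}_{sex}_{segment}_{i // 2:03d}",
                    "species": spec.species,
                    "sex": sex,
                    "segment": segment,
                    "side": "left" if i % 2 == 0 else "right",
                    "F_A": float(ratio),
                    "F_B": 1.0,
                    "ratio": float(ratio),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MusclePrimitive:
    """A rotated capsule or rectangle standing in for one muscle.

    ``length`` is the end-to-end extent, ``width`` the transverse extent,
    ``angle`` the long-axis angle in degrees (0 = along image columns).
    Exact Feret diameter: rectangle sqrt(L^2 + W^2); capsule L.
    """

    center: tuple[float, float]  # (row, col)
    length: float
    width: float
    angle: float = 0.0
    intensity: float = 1.0
    shape: str = "capsule"  # or "rectangle"

    def __post_init__(self) -> None:
        if self.length < self.width:
            raise ValueError("length must be >= width")
        if self.shape not in ("capsule", "rectangle"):
            raise ValueError("shape must be 'capsule' or 'rectangle'")

    @property
    def feret(self) -> float:
        if self.shape == "rectangle":
            return math.hypot(self.length, self.width)
        return self.length


@dataclass(frozen=True)
class ImageLayout:
    shape: tuple[int, int]
    primitives: Sequence[MusclePrimitive]
    background: float = 0.0
    blur_sd: float = 0.0
    noise_sd: float = 0.0


def _rasterize(prim: MusclePrimitive, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    dy = rr - prim.center[0]
    dx = cc - prim.center[1]
    th = math.radians(prim.angle)
    # long-axis unit vector (drow, dcol) = (sin th, cos th)
    u = dy * math.sin(th) + dx * math.cos(th)
    v = -dy * math.cos(th) + dx * math.sin(th)
    if prim.shape == "rectangle":
        return (np.abs(u) <= prim.length / 2) & (np.abs(v) <= prim.width / 2)
    half = max(prim.length - prim.width, 0.0) / 2
    uc = np.clip(u, -half, half)
    return (u - uc) ** 2 + v**2 <= (prim.width / 2) ** 2


def gen_image(layout: ImageLayout, seed: int = 0) -> tuple[np.ndarray, list[dict]]:
    """Rasterize a muscle layout; return (image, per-primitive ground truth).

    Ground truth per primitive: exact Feret diameter, centroid, mask pixel
    count and bounding box of the clean rasterization.  Overlapping
    primitives trigger a warning (per-primitive Feret then unreliable).
    """
    rng = np.random.default_rng(seed)
    img = np.full(layout.shape, float(layout.background))
    occupancy = np.zeros(layout.shape, dtype=int)
    truth = []
    for prim in layout.primitives:
        mask = _rasterize(prim, layout.shape)
        occupancy += mask
        img[mask] = np.maximum(img[mask], prim.intensity)
        idx = np.argwhere(mask)
        truth.append(
            {
                "feret": prim.feret,
                "centroid": tuple(idx.mean(axis=0)) if idx.size else prim.center,
                "area": int(mask.sum()),
                "bbox": (
                    tuple(idx.min(axis=0)) + tuple(idx.max(axis=0))
                    if idx.size
                    else None
                ),
                "primitive": prim,
            }
        )
    if (occupancy > 1).any():
        warnings.warn("primitives overlap; per-primitive ground truth unreliable",
                      stacklevel=2)
    if layout.blur_sd > 0:
        img = ndi.gaussian_filter(img, layout.blur_sd)
    if layout.noise_sd > 0:
        img = img + layout.noise_sd * rng.standard_normal(layout.shape)
    return img, truth


def gen_nuclei(
    k_rows: int,
    per_row: int,
    row_spacing: float,
    axial_spacing: float,
    jitter_sd: float,
    seed: int,
    angle: float = 0.0,
) -> np.ndarray:
    """k rows of nuclei along the long axis with transverse jitter.

    Returns an (k_rows * per_row, 2) array of (row, col)-style coordinates;
    the long axis lies at ``angle`` degrees.  jitter_sd = 0 gives an exact
    grid.
    """
    if k_rows < 1 or per_row < 1:
        raise ValueError("k_rows and per_row must be >= 1")
    rng = np.random.default_rng(seed)
    axial = np.arange(per_row) * axial_spacing
    transverse = np.arange(k_rows) * row_spacing
    pts = []
    for tv in transverse:
        jitter = jitter_sd * rng.standard_normal(per_row)
        for a, j in zip(axial, jitter):
            pts.append((a, tv + j))
    pts = np.asarray(pts, dtype=float)
    th = math.radians(angle)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return pts @ rot.T


def gen_tree(n_tips: int, seed: int, model: str = "yule") -> dendropy.Tree:
    """Yule (pure-birth) tree with unit speciation rate.

    Lineages split after Exp(k) waiting times (k = current lineage count);
    the hold time at n lineages is included before stopping, so
    E[root-to-tip depth] = sum_{k=2..n} 1/k.
    """
    if model != "yule":
        raise ValueError("only the 'yule' model is supported")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    active = [tree.seed_node]
    while len(active) < n_tips:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for nd in active:
            nd.edge.length += dt
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        kids = [parent.new_child(edge_length=0.0), parent.new_child(edge_length=0.0)]
        active.extend(kids)
    dt = rng.exponential(1.0 / n_tips)
    for nd in active:
        nd.edge.length += dt
    for i, nd in enumerate(active):
        nd.taxon = taxa.new_taxon(label=f"T{i + 1}")
    tree.is_rooted = True
    return tree


@dataclass(frozen=True)
class TraitSimResult:
    tip_states: dict[str, int]
    node_states: dict[frozenset, int]  # internal nodes keyed by tip bipartition
    root_state: int
    params: CTMCParams
    seed: int


def sim_trait(tree: dendropy.Tree, params: CTMCParams, seed: int) -> TraitSimResult:
    """Forward-simulate the binary F81 process down a rooted tree.

    The root state is drawn from (pi0, pi1); each branch applies the exact
    transition kernel.  All internal-node states are recorded as ground
    truth for calibration studies.
    """
    rng = np.random.default_rng(seed)
    r = params.rate
    state: dict[int, int] = {}
    tip_states: dict[str, int] = {}
    node_states: dict[frozenset, int] = {}
    clade: dict[int, frozenset] = {}
    root = tree.seed_node
    state[id(root)] = int(rng.random() < params.pi1)
    for nd in tree.preorder_node_iter():
        if nd is not root:
            parent_state = state[id(nd.parent_node)]
            t = nd.edge.length if nd.edge.length is not None else 1.0
            e = math.exp(-r * t)
            if rng.random() < e:
                s = parent_state
            else:
                s = int(rng.random() < params.pi1)
            state[id(nd)] = s
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tip_states[nd.taxon.label] = state[id(nd)]
            clade[id(nd)] = frozenset([nd.taxon.label])
        else:
            clade[id(nd)] = frozenset().union(
                *(clade[id(c)] for c in nd.child_nodes())
            )
            node_states[clade[id(nd)]] = state[id(nd)]
    return TraitSimResult(
        tip_states=tip_states,
        node_states=node_states,
        root_state=state[id(root)],
        params=params,
        seed=seed,
    )
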
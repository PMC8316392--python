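"""Bayesian binary-character ancestral state reconstruction on rooted trees.

Model
-----
A two-state continuous-time Markov chain of the F81 family: stationary
frequencies (pi0, pi1) and overall rate ``mu`` (expected state changes per
unit branch length at stationarity).  With r = mu / (2 pi0 pi1) the
transition kernel over a branch of length t is

    P_ij(t) = exp(-r t) delta_ij + (1 - exp(-r t)) pi_j

so that one unit of branch length at mu = 1 carries one expected change.

Inference
---------
Tip presence/absence data enter via Felsenstein's pruning algorithm (with
per-node rescaling); per-node marginal posteriors of the ancestral state
come from the standard up-down (inside-outside) pass.  Parameters carry a
Dirichlet(0.5, 0.5) prior on (pi0, pi1) and a log-normal(0, 1) prior on
``mu`` (the published workflow estimates frequencies only; an explicit rate
with a weak prior is needed because branch-length scale is otherwise
unidentified on a fixed tree — a fixed-rate mode ``fix_mu=1`` emulates the
frequency-only analysis).  Sampling is Metropolis random-walk on
(logit pi1, log mu); node posteriors are averaged over post-burn-in samples
pooled across chains.  Unknown tip states ("?") contribute a partial
likelihood of (1, 1).  Multifurcations are handled natively.

Trees are ``dendropy.Tree`` objects; internal nodes are keyed by the
frozenset of descendant tip labels (their bipartition), which also drives
the equal-weight aggregation of node posteriors across a tree sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "CTMCParams",
    "MCMCSettings",
    "NodePosterior",
    "transition_matrix",
    "prune_loglik",
    "node_marginals",
    "bbm_mcmc",
    "summarize_over_trees",
    "mc_standard_error",
]

UNKNOWN = "?"


@dataclass(frozen=True)
class CTMCParams:
    """Binary F81 parameters: stationary frequency of state 1 and rate mu."""

    pi1: float
    mu: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError("pi1 must lie strictly in (0, 1)")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def rate(self) -> float:
        """Kernel rate r = mu / (2 pi0 pi1)."""
        return self.mu / (2.0 * self.pi0 * self.pi1)


@dataclass(frozen=True)
class MCMCSettings:
    generations: int = 50_000
    chains: int = 4
    sample_every: int = 100
    burnin_fraction: float = 0.25
    seed: int = 0
    proposal_scale: float = 0.8
    fix_mu: float | None = None

    def __post_init__(self) -> None:
        if self.generations < self.sample_every:
            raise ValueError("generations must be >= sample_every")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass(frozen=True)
class NodePosterior:
    node_id: int
    bipartition: frozenset
    p_present: float
    p_absent: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_present <= 1 and 0 <= self.p_absent <= 1):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if abs(self.p_present + self.p_absent - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")


def transition_matrix(params: CTMCParams, t: float) -> np.ndarray:
    """2x2 stochastic matrix P_ij(t) for the binary F81 kernel."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = math.exp(-params.rate * t)
    pi = np.array([params.pi0, params.pi1])
    return e * np.eye(2) + (1.0 - e) * pi[None, :]


# ---------------------------------------------------------------------------
# indexed tree + pruning


class _IndexedTree:
    """Post-order array view of a rooted dendropy tree (fast pruning)."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [
            [index[id(c)] for c in nd.child_nodes()] for nd in nodes
        ]
        self.blen = [
            float(nd.edge.length) if nd.edge.length is not None else 1.0
            for nd in nodes
        ]
        self.is_leaf = [len(c) == 0 for c in self.children]
        self.labels = [
            nd.taxon.label if nd.taxon is not None else None for nd in nodes
        ]
        self.root = self.n - 1
        clades: list[frozenset] = [frozenset()] * self.n
        for i in range(self.n):
            if self.is_leaf[i]:
                if self.labels[i] is None:
                    raise ValueError("every tip must be labeled")
                clades[i] = frozenset([self.labels[i]])
            else:
                clades[i] = frozenset().union(*(clades[c] for c in self.children[i]))
        self.clades = clades
        if len(clades[self.root]) != sum(self.is_leaf):
            raise ValueError("duplicate tip labels")

    def tip_partials(self, traits: Mapping[str, object]) -> list[tuple[float, float]]:
        out: list[tuple[float, float]] = [(1.0, 1.0)] * self.n
        for i in range(self.n):
            if not self.is_leaf[i]:
                continue
            label = self.labels[i]
            if label not in traits:
                raise KeyError(
                    f"tip {label!r} has no trait entry and is not marked unknown"
                )
            s = traits[label]
            if s in (UNKNOWN, None):
                out[i] = (1.0, 1.0)
            elif int(s) == 0:
                out[i] = (1.0, 0.0)
            elif int(s) == 1:
                out[i] = (0.0, 1.0)
            else:
                raise ValueError(f"trait state for {label!r} must be 0, 1 or '?'")
        return out


def _down_pass(it: _IndexedTree, tips, pi0: float, pi1: float, r: float):
    """Scaled down partials + per-branch messages; returns (d0, d1, m0, m1,
    logscale)."""
    n = it.n
    d0 = [0.0] * n
    d1 = [0.0] * n
    m0 = [0.0] * n  # message sent from node i to its parent
    m1 = [0.0] * n
    logscale = 0.0
    exp = math.exp
    for i in range(n):
        if it.is_leaf[i]:
            a, b = tips[i]
        else:
            a, b = 1.0, 1.0
            for c in it.children[i]:
                a *= m0[c]
                b *= m1[c]
            sc = a + b
            if sc <= 0.0:
                return None  # impossible data (e.g. mu = 0 with conflict)
            a, b = a / sc, b / sc
            logscale += math.log(sc)
        d0[i], d1[i] = a, b
        if i != it.root:
            e = exp(-r * it.blen[i])
            s = pi0 * a + pi1 * b
            m0[i] = e * a + (1.0 - e) * s
            m1[i] = e * b + (1.0 - e) * s
    return d0, d1, m0, m1, logscale


def prune_loglik(
    tree: dendropy.Tree | _IndexedTree,
    traits: Mapping[str, object],
    params: CTMCParams,
) -> float:
    """Log-likelihood of tip states by Felsenstein pruning with rescaling.

    The root is weighted by the stationary frequencies (pi0, pi1) — the root
    state is always one of the two states, never empty.
    """
    it = tree if isinstance(tree, _IndexedTree) else _IndexedTree(tree)
    tips = it.tip_partials(traits)
    res = _down_pass(it, tips, params.pi0, params.pi1, params.rate)
    if res is None:
        return -math.inf
    d0, d1, _, _, logscale = res
    lik = params.pi0 * d0[it.root] + params.pi1 * d1[it.root]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


def node_marginals(
    tree: dendropy.Tree | _IndexedTree,
    traits: Mapping[str, object],
    params: CTMCParams,
) -> list[NodePosterior]:
    """Marginal posterior P(state | tips, params) at every internal node.

    Up-down message passing: the down pass collects evidence below each
    node, the up pass propagates evidence from the rest of the tree; the
    node marginal is the normalized product.
    """
    it = tree if isinstance(tree, _IndexedTree) else _IndexedTree(tree)
    tips = it.tip_partials(traits)
    pi0, pi1, r = params.pi0, params.pi1, params.rate
    res = _down_pass(it, tips, pi0, pi1, r)
    if res is None:
        raise ValueError("data have zero likelihood under these parameters")
    d0, d1, m0, m1, _ = res
    u0 = [0.0] * it.n
    u1 = [0.0] * it.n
    u0[it.root], u1[it.root] = pi0, pi1
    exp = math.exp
    out: list[NodePosterior] = []
    for i in range(it.n - 1, -1, -1):
        if it.is_leaf[i]:
            continue
        w0 = u0[i] * d0[i]
        w1 = u1[i] * d1[i]
        tot = w0 + w1
        out.append(
            NodePosterior(
                node_id=i,
                bipartition=it.clades[i],
                p_present=w1 / tot,
                p_absent=w0 / tot,
            )
        )
        for c in it.children[i]:
            g0, g1 = u0[i], u1[i]
            for s in it.children[i]:
                if s != c:
                    g0 *= m0[s]
                    g1 *= m1[s]
            e = exp(-r * it.blen[c])
            tot_g = g0 + g1
            a = e * g0 + (1.0 - e) * pi0 * tot_g
            b = e * g1 + (1.0 - e) * pi1 * tot_g
            sc = a + b
            u0[c], u1[c] = a / sc, b / sc
    return out


# ---------------------------------------------------------------------------
# MCMC


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def bbm_mcmc(
    tree: dendropy.Tree,
    traits: Mapping[str, object],
    settings: MCMCSettings,
    compute_marginals: bool = True,
) -> dict:
    """Metropolis MCMC over (pi1, mu) with averaged node posteriors.

    Priors: Dirichlet(0.5, 0.5) on (pi0, pi1); log-normal(0, 1) on mu (or mu
    held at ``settings.fix_mu``).  Random-walk proposals on logit(pi1) and
    log(mu).  Deterministic given ``settings.seed``; chains use independent
    streams.  Node posteriors are the equal-weight average of
    ``node_marginals`` over post-burn-in samples pooled across chains.
    """
    it = _IndexedTree(tree)
    tips = it.tip_partials(traits)

    def loglik(pi1: float, mu: float) -> float:
        r = mu / (2.0 * pi1 * (1.0 - pi1))
        res = _down_pass(it, tips, 1.0 - pi1, pi1, r)
        if res is None:
            return -math.inf
        d0, d1, _, _, logscale = res
        lik = (1.0 - pi1) * d0[it.root] + pi1 * d1[it.root]
        return (math.log(lik) + logscale) if lik > 0 else -math.inf

    fixed_mu = settings.fix_mu
    chains: list[dict] = []
    for chain in range(settings.chains):
        rng = np.random.default_rng([settings.seed, chain])
        psi = 0.0  # logit(pi1)
        lam = 0.0  # log(mu)
        mu = fixed_mu if fixed_mu is not None else math.exp(lam)
        ll = loglik(_expit(psi), mu)

        def _target_psi(psi_: float, ll_: float) -> float:
            p = _expit(psi_)
            # Beta(0.5, 0.5) prior + logit Jacobian
            return ll_ + 0.5 * (math.log(p) + math.log(1.0 - p))

        def _target_lam(lam_: float, ll_: float) -> float:
            # log-normal(0,1) prior; Jacobian cancels the 1/mu factor
            return ll_ - 0.5 * lam_ * lam_

        acc = 0
        prop = 0
        pi_trace, mu_trace, ll_trace = [], [], []
        for gen in range(1, settings.generations + 1):
            psi_new = psi + settings.proposal_scale * rng.standard_normal()
            ll_new = loglik(_expit(psi_new), mu)
            prop += 1
            if math.log(rng.random()) < _target_psi(psi_new, ll_new) - _target_psi(
                psi, ll
            ):
                psi, ll = psi_new, ll_new
                acc += 1
            if fixed_mu is None:
                lam_new = lam + settings.proposal_scale * rng.standard_normal()
                ll_new = loglik(_expit(psi), math.exp(lam_new))
                prop += 1
                if math.log(rng.random()) < _target_lam(lam_new, ll_new) - _target_lam(
                    lam, ll
                ):
                    lam, ll = lam_new, ll_new
                    acc += 1
                mu = math.exp(lam)
            if gen % settings.sample_every == 0:
                pi_trace.append(_expit(psi))
                mu_trace.append(mu)
                ll_trace.append(ll)
        if acc == 0:
            warnings.warn(
                f"chain {chain}: zero Metropolis acceptances; check the "
                "proposal scale and data",
                stacklevel=2,
            )
        nburn = int(round(settings.burnin_fraction * len(pi_trace)))
        chains.append(
            {
                "pi1": np.array(pi_trace),
                "mu": np.array(mu_trace),
                "loglik": np.array(ll_trace),
                "acceptance": acc / prop if prop else 0.0,
                "n_burnin": nburn,
            }
        )

    pooled_pi = np.concatenate([c["pi1"][c["n_burnin"]:] for c in chains])
    pooled_mu = np.concatenate([c["mu"][c["n_burnin"]:] for c in chains])
    result = {
        "pi1": pooled_pi,
        "mu": pooled_mu,
        "chains": chains,
        "acceptance": [c["acceptance"] for c in chains],
        "settings": settings,
        "node_posteriors": None,
    }
    if compute_marginals:
        sums: dict[int, tuple[frozenset, float]] = {}
        count = 0
        for p1, m in zip(pooled_pi, pooled_mu):
            for np_ in node_marginals(it, traits, CTMCParams(pi1=float(p1), mu=float(m))):
                bip, acc1 = sums.get(np_.node_id, (np_.bipartition, 0.0))
                sums[np_.node_id] = (bip, acc1 + np_.p_present)
            count += 1
        result["node_posteriors"] = [
            NodePosterior(
                node_id=nid,
                bipartition=bip,
                p_present=tot / count,
                p_absent=1.0 - tot / count,
            )
            for nid, (bip, tot) in sorted(sums.items())
        ]
    return result


def summarize_over_trees(
    trees: Sequence[dendropy.Tree],
    traits: Mapping[str, object],
    settings: MCMCSettings,
    reference: dendropy.Tree | None = None,
) -> dict:
    """Aggregate node posteriors over a sample of trees, by bipartition.

    Every tree is analyzed independently (seeded per tree from
    ``settings.seed``) and weighted equally.  For each internal bipartition
    of the reference tree (default: the first tree), the averaged posterior
    is taken over the trees that contain that bipartition; the supporting
    fraction of trees is reported alongside.
    """
    if not trees:
        raise ValueError("need at least one tree")
    tipsets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    if len(set(tipsets)) != 1:
        raise ValueError("all trees must share the same tip set")
    reference = reference if reference is not None else trees[0]
    ref_bips = [
        p.bipartition
        for p in node_marginals(
            reference, {l: UNKNOWN for l in tipsets[0]}, CTMCParams(pi1=0.5, mu=1.0)
        )
    ]
    per_tree: list[dict[frozenset, NodePosterior]] = []
    for t in trees:
        # every tree reuses the same settings (and seed): identical trees
        # then contribute identical posteriors and the degenerate sample
        # reduces exactly to the single-tree analysis
        res = bbm_mcmc(t, traits, settings)
        per_tree.append({p.bipartition: p for p in res["node_posteriors"]})
    ntree = len(trees)
    out = {}
    for bip in ref_bips:
        hits = [pt[bip] for pt in per_tree if bip in pt]
        support = len(hits) / ntree
        p_present = float(np.mean([h.p_present for h in hits])) if hits else math.nan
        out[bip] = {
            "p_present": p_present,
            "p_absent": 1.0 - p_present if hits else math.nan,
            "support": support,
        }
    return {"bipartitions": out, "n_trees": ntree}


def mc_standard_error(samples: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the sample mean by batch means."""
    x = np.asarray(samples, dtype=float)
    nb = min(n_batches, max(2, x.size // 2))
    usable = (x.size // nb) * nb
    means = x[:usable].reshape(nb, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(nb))
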
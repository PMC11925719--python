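"""Simulation of phylogenies and traits with known a priori signal intensity.

These generators reproduce the validation setup used throughout this package:

* pure-birth (Yule) ultrametric trees, birth rate 0.05 per lineage;
* continuous traits by Brownian motion (root 0, sd 0.01 per unit sqrt branch
  length), then mixed with a random shuffle of themselves,
  ``trait = w * trait_BM + (1 - w) * trait_rand``;
* discrete traits by an equal-rates Mk model (rate 0.01), then degraded by
  shuffling the values of a random ``1 - w`` fraction of species.

The intensity coefficient ``w`` in [0, 1] is therefore the ground-truth
signal strength: ``w = 1`` leaves the evolved trait intact, ``w = 0`` reduces
it to an exchangeable shuffle with no phylogenetic structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import NO_NODE, Phylogeny

__all__ = [
    "SimulationConfig",
    "yule_tree",
    "bm_trait",
    "mix_continuous",
    "mk_trait",
    "degrade_discrete",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of the simulation-study settings (defaults are the study's)."""

    n_tips: int = 100
    birth_rate: float = 0.05
    death_rate: float = 0.0
    bm_sigma: float = 0.01
    bm_root: float = 0.0
    mk_rate: float = 0.01
    n_states: int = 2
    w: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate <= 0 or self.mk_rate < 0 or self.bm_sigma < 0:
            raise ValueError("rates must be positive")
        if self.death_rate != 0:
            raise ValueError("only pure-birth trees are supported (death rate 0)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def yule_tree(n_tips: int, birth_rate: float = 0.05, seed=None) -> Phylogeny:
    """Simulate an ultrametric pure-birth tree with exactly ``n_tips`` tips.

    Starting from the root's two daughter lineages, waiting times between
    successive birth events are Exponential(k * birth_rate) with k the current
    lineage count and the splitting lineage chosen uniformly.  After the count
    reaches ``n_tips`` one further waiting time is drawn and all extant tips
    are cut at that epoch, so every tip is equidistant from the root.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = _rng(seed)
    n_nodes = 2 * n_tips - 1
    left = np.full(n_nodes, NO_NODE, dtype=np.intp)
    right = np.full(n_nodes, NO_NODE, dtype=np.intp)
    parent = np.full(n_nodes, NO_NODE, dtype=np.intp)
    root = n_nodes - 1

    # simulate with lightweight lineage records, assign integer ids afterwards
    class _Rec:
        __slots__ = ("start", "children", "end")

        def __init__(self, start):
            self.start = start
            self.children = None
            self.end = None

    root_rec = _Rec(0.0)
    a, b = _Rec(0.0), _Rec(0.0)
    root_rec.children = (a, b)
    root_rec.start = None  # root has no branch
    lineages = [a, b]
    t = 0.0
    while len(lineages) < n_tips:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        parent_rec = lineages[idx]
        parent_rec.end = t
        c1, c2 = _Rec(t), _Rec(t)
        parent_rec.children = (c1, c2)
        lineages[idx] = c1
        lineages.append(c2)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for rec in lineages:
        rec.end = t

    labels: list[str] = []
    blen = np.full(n_nodes, np.nan)
    ids: dict[int, int] = {}
    counter = {"tip": 0, "internal": n_tips}

    def assign(rec: "_Rec") -> int:
        if rec.children is None:
            v = counter["tip"]
            counter["tip"] += 1
            labels.append(f"t{v + 1}")
        elif rec is root_rec:
            v = root
        else:
            v = counter["internal"]
            counter["internal"] += 1
        return v

    def build(rec: "_Rec") -> int:
        if rec.children is not None:
            lv = build(rec.children[0])
            rv = build(rec.children[1])
            v = assign(rec)
            left[v], right[v] = lv, rv
            parent[lv] = parent[rv] = v
        else:
            v = assign(rec)
        if rec.start is not None:
            blen[v] = rec.end - rec.start
        return v

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n_tips + 100))
    try:
        build(root_rec)
    finally:
        sys.setrecursionlimit(old)
    return Phylogeny(tuple(labels), left, right, parent, blen).validate()


def bm_trait(tree: Phylogeny, sigma: float = 0.01, root_value: float = 0.0,
             seed=None) -> pd.Series:
    """Brownian-motion trait: child = parent + Normal(0, sigma^2 * branch length)."""
    if np.isnan(tree.branch_length[: tree.n_tips]).any():
        raise ValueError("tree has missing branch lengths")
    rng = _rng(seed)
    val = np.zeros(tree.n_nodes)
    val[tree.root] = root_value
    bl = tree.branch_length
    for v in tree.postorder_internal[::-1]:  # preorder: parents first
        for c in (int(tree.left_child[v]), int(tree.right_child[v])):
            val[c] = val[v] + rng.normal(0.0, sigma * np.sqrt(bl[c]))
    return pd.Series(val[: tree.n_tips], index=list(tree.tip_labels), name="trait")


def mix_continuous(trait_bm: pd.Series, w: float, seed=None) -> pd.Series:
    """Blend a Brownian trait with a random shuffle of its own values.

    ``trait = w * trait_BM + (1 - w) * trait_rand`` where ``trait_rand`` is a
    uniform permutation of the Brownian values across species; ``w`` is the
    a priori signal intensity.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    rng = _rng(seed)
    rand = rng.permutation(trait_bm.to_numpy())
    return pd.Series(
        w * trait_bm.to_numpy() + (1.0 - w) * rand,
        index=trait_bm.index,
        name=trait_bm.name,
    )


def mk_trait(tree: Phylogeny, n_states: int = 2, rate: float = 0.01,
             seed=None) -> pd.Series:
    """Equal-rates Mk discrete trait along the tree.

    With off-diagonal rate q between every ordered state pair, the transition
    probability over a branch of length t is uniform-with-memory:
    with probability exp(-k q t) the child keeps the parent state, otherwise
    it is drawn uniformly from all k states.  Root state uniform.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if np.isnan(tree.branch_length[: tree.n_tips]).any():
        raise ValueError("tree has missing branch lengths")
    rng = _rng(seed)
    k = n_states
    state = np.zeros(tree.n_nodes, dtype=np.intp)
    state[tree.root] = rng.integers(k)
    bl = tree.branch_length
    for v in tree.postorder_internal[::-1]:
        for c in (int(tree.left_child[v]), int(tree.right_child[v])):
            keep = np.exp(-k * rate * bl[c])
            if rng.random() < keep:
                state[c] = state[v]
            else:
                state[c] = rng.integers(k)
    labels = [f"s{i + 1}" for i in range(k)]
    return pd.Series(
        [labels[s] for s in state[: tree.n_tips]],
        index=list(tree.tip_labels),
        name="trait",
    )


def degrade_discrete(trait_mk: pd.Series, w: float, seed=None) -> pd.Series:
    """Keep a random ``w`` fraction of species; shuffle the rest among themselves.

    ``round(w * n)`` species retain their evolved state; the remaining
    species' values are uniformly permuted among themselves, so the value
    multiset is always preserved.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    rng = _rng(seed)
    vals = trait_mk.to_numpy().copy()
    n = len(vals)
    n_keep = int(round(w * n))
    keep = rng.choice(n, size=n_keep, replace=False)
    shuffle_mask = np.ones(n, dtype=bool)
    shuffle_mask[keep] = False
    idx = np.flatnonzero(shuffle_mask)
    vals[idx] = vals[rng.permutation(idx)]
    return pd.Series(vals, index=trait_mk.index, name=trait_mk.name)
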
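"""Statistical-power experiments: detection-rate curves and surfaces for M.

Each experiment repeatedly simulates (tree, trait) pairs at a known signal
intensity ``w``, runs the M permutation test, and records the fraction of
replicates rejecting the no-signal null at level ``alpha`` — the detection
rate.  Curves scan ``w`` for a single trait; surfaces scan ``(w1, w2)`` for
two-trait combinations scored through their joint Gower distance.

Per-cell, per-replicate random streams are derived deterministically from the
master seed and the cell coordinates (via ``numpy.random.SeedSequence``), so
any cell can be recomputed independently and results do not depend on
execution order.

Default scale is deliberately desk-sized (20 replicates x 199 permutations);
pass ``n_replicates``/``n_perm`` explicitly for larger studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gower import TraitTable
from .mstat import permutation_test
from .simulate import bm_trait, degrade_discrete, mix_continuous, mk_trait, yule_tree

__all__ = [
    "PowerGrid",
    "power_curve_continuous",
    "power_curve_discrete",
    "power_surface_pairs",
]

BIRTH_RATE = 0.05
BM_SIGMA = 0.01
BM_ROOT = 0.0
MK_RATE = 0.01


@dataclass(frozen=True)
class PowerGrid:
    """Detection rates on a grid of signal intensities, as a tidy frame.

    ``table`` has one row per grid cell with the axis value(s), the number of
    replicates and the detection rate (fraction of replicates with
    ``p <= alpha``).  ``config`` echoes every setting needed to reproduce it.
    """

    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.config.items()):
                fh.write(f"# {k} = {v}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def rate_at(self, **axes) -> float:
        mask = np.ones(len(self.table), dtype=bool)
        for k, v in axes.items():
            mask &= np.isclose(self.table[k], v)
        sel = self.table[mask]
        if len(sel) != 1:
            raise KeyError(f"cell {axes} not unique in grid")
        return float(sel["detection_rate"].iloc[0])


def _cell_seed(master: int, *coords) -> np.random.SeedSequence:
    key = [int(master)] + [int(round(c * 1000)) for c in coords]
    return np.random.SeedSequence(key)


def _simulate_continuous(n_tips, w, rng) -> tuple:
    tree = yule_tree(n_tips, BIRTH_RATE, rng)
    trait = mix_continuous(bm_trait(tree, BM_SIGMA, BM_ROOT, rng), w, rng)
    return tree, trait


def _simulate_discrete(n_tips, n_states, w, rng) -> tuple:
    tree = yule_tree(n_tips, BIRTH_RATE, rng)
    trait = degrade_discrete(mk_trait(tree, n_states, MK_RATE, rng), w, rng)
    return tree, trait


def _detection_rate(make_one, n_replicates, n_perm, alpha, seedseq) -> float:
    hits = 0
    for rep, child in enumerate(seedseq.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        tree, table, cols = make_one(rng)
        test_seed = int(rng.integers(2**31 - 1))
        res = permutation_test(
            tree, table, cols, n_perm=n_perm, seed=test_seed, alpha=alpha
        )
        hits += res.significant
    return hits / n_replicates


def power_curve_continuous(
    n_tips: int,
    w_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_replicates: int = 20,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerGrid:
    """Detection rate of M over Brownian-motion weight ``w``, single trait."""
    rows = []
    for w in w_grid:
        def make_one(rng, w=w):
            tree, trait = _simulate_continuous(n_tips, w, rng)
            table = TraitTable(trait.to_frame(), {"trait": "continuous"})
            return tree, table, ["trait"]

        rate = _detection_rate(
            make_one, n_replicates, n_perm, alpha, _cell_seed(seed, w)
        )
        rows.append({"w": w, "n_replicates": n_replicates, "detection_rate": rate})
    return PowerGrid(
        pd.DataFrame(rows),
        {
            "kind": "continuous",
            "n_tips": n_tips,
            "n_perm": n_perm,
            "alpha": alpha,
            "seed": seed,
            "n_replicates": n_replicates,
            "birth_rate": BIRTH_RATE,
            "bm_sigma": BM_SIGMA,
        },
    )


def power_curve_discrete(
    n_tips: int,
    n_states: int,
    w_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_replicates: int = 20,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerGrid:
    """Detection rate of M over retained-signal proportion ``w``, Mk trait."""
    rows = []
    for w in w_grid:
        def make_one(rng, w=w):
            tree, trait = _simulate_discrete(n_tips, n_states, w, rng)
            table = TraitTable(trait.to_frame(), {"trait": "nominal"})
            return tree, table, ["trait"]

        rate = _detection_rate(
            make_one, n_replicates, n_perm, alpha, _cell_seed(seed, w, n_states)
        )
        rows.append({"w": w, "n_replicates": n_replicates, "detection_rate": rate})
    return PowerGrid(
        pd.DataFrame(rows),
        {
            "kind": "discrete",
            "n_tips": n_tips,
            "n_states": n_states,
            "n_perm": n_perm,
            "alpha": alpha,
            "seed": seed,
            "n_replicates": n_replicates,
            "birth_rate": BIRTH_RATE,
            "mk_rate": MK_RATE,
        },
    )


def power_surface_pairs(
    trait_kind: str,
    n_tips: int,
    w1_grid,
    w2_grid,
    n_states: int = 2,
    n_replicates: int = 20,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerGrid:
    """Detection-rate surface for a two-trait combination at (w1, w2).

    Two traits are simulated independently on the same tree at intensities
    ``w1`` and ``w2`` and tested jointly through their equal-weight Gower
    distance.
    """
    if trait_kind not in ("continuous", "discrete"):
        raise ValueError("trait_kind must be 'continuous' or 'discrete'")
    rows = []
    for w1 in w1_grid:
        for w2 in w2_grid:
            def make_one(rng, w1=w1, w2=w2):
                tree = yule_tree(n_tips, BIRTH_RATE, rng)
                if trait_kind == "continuous":
                    t1 = mix_continuous(bm_trait(tree, BM_SIGMA, BM_ROOT, rng), w1, rng)
                    t2 = mix_continuous(bm_trait(tree, BM_SIGMA, BM_ROOT, rng), w2, rng)
                    types = {"trait1": "continuous", "trait2": "continuous"}
                else:
                    t1 = degrade_discrete(mk_trait(tree, n_states, MK_RATE, rng), w1, rng)
                    t2 = degrade_discrete(mk_trait(tree, n_states, MK_RATE, rng), w2, rng)
                    types = {"trait1": "nominal", "trait2": "nominal"}
                df = pd.DataFrame({"trait1": t1, "trait2": t2})
                return tree, TraitTable(df, types), ["trait1", "trait2"]

            rate = _detection_rate(
                make_one, n_replicates, n_perm, alpha,
                _cell_seed(seed, w1, w2, n_states if trait_kind == "discrete" else 0),
            )
            rows.append(
                {
                    "w1": w1,
                    "w2": w2,
                    "n_replicates": n_replicates,
                    "detection_rate": rate,
                }
            )
    return PowerGrid(
        pd.DataFrame(rows),
        {
            "kind": f"pair_{trait_kind}",
            "n_tips": n_tips,
            "n_states": n_states if trait_kind == "discrete" else None,
            "n_perm": n_perm,
            "alpha": alpha,
            "seed": seed,
            "n_replicates": n_replicates,
            "birth_rate": BIRTH_RATE,
        },
    )
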
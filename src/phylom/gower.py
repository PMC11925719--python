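"""Mixed-type trait tables and Gower's distance.

Gower's coefficient averages per-trait dissimilarities so that traits of any
statistical type can enter one species-pairwise distance matrix, each scaled
to [0, 1]:

* continuous — ``|x_i - x_j| / range`` over the observed column range;
* nominal — simple mismatch, 0 if equal else 1;
* ordinal — values are replaced by midranks and then treated as continuous
  (Podani's convention, the default in the R implementations ``gowdis`` and
  ``daisy``).

Missing cells are handled by pairwise deletion: a pair's distance is the
weighted mean over the traits observed in *both* species, with weights
renormalised accordingly.  A pair sharing no observed trait is an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

__all__ = ["TraitTable", "gower_distance", "combine_columns", "read_trait_table"]

TRAIT_TYPES = ("continuous", "nominal", "ordinal")


@dataclass
class TraitTable:
    """Species x trait table with per-column type and weight metadata.

    ``data`` is indexed by species label; ``trait_types`` maps every column to
    ``continuous``/``nominal``/``ordinal``; ``trait_weights`` defaults to 1
    per column.  Missing values are ``NaN`` (continuous/ordinal) or ``None``/
    ``NaN`` (nominal).
    """

    data: pd.DataFrame
    trait_types: dict[str, str]
    trait_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species labels: {dupes}")
        for col in self.data.columns:
            t = self.trait_types.get(col)
            if t is None:
                raise ValueError(f"no type declared for trait column '{col}'")
            if t not in TRAIT_TYPES:
                raise ValueError(
                    f"trait '{col}': type must be one of {TRAIT_TYPES}, got '{t}'"
                )
            if self.data[col].isna().all():
                raise ValueError(f"trait '{col}' has no observed values")
        for col, w in self.trait_weights.items():
            if w < 0:
                raise ValueError(f"trait '{col}': weight must be >= 0, got {w}")
        self.trait_weights = {
            c: float(self.trait_weights.get(c, 1.0)) for c in self.data.columns
        }

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, species: list[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(
            self.data.loc[species], dict(self.trait_types), dict(self.trait_weights)
        )


def read_trait_table(path: str, types_path: str | None = None,
                     types: dict[str, str] | None = None,
                     weights: dict[str, float] | None = None,
                     sep: str | None = None) -> TraitTable:
    """Load a trait table from CSV/TSV (first column = species label).

    Column types come either from ``types``/``weights`` mappings or from a
    sidecar file with columns ``trait,type[,weight]``.  Empty cells and
    ``NA`` are read as missing.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    if types_path is not None:
        tsep = "\t" if str(types_path).endswith((".tsv", ".tab", ".txt")) else ","
        tdf = pd.read_csv(types_path, sep=tsep)
        tdf.columns = [c.strip().lower() for c in tdf.columns]
        types = dict(zip(tdf["trait"].astype(str), tdf["type"].astype(str)))
        if "weight" in tdf.columns:
            weights = dict(zip(tdf["trait"].astype(str), tdf["weight"].astype(float)))
    if types is None:
        raise ValueError("trait types must be given via `types` or `types_path`")
    return TraitTable(df, dict(types), dict(weights or {}))


def _column_dissimilarity(values: pd.Series, kind: str,
                          ordinal_as_continuous: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair dissimilarity matrix and observed mask for one trait column."""
    obs = ~values.isna().to_numpy()
    n = len(values)
    diss = np.zeros((n, n))
    if kind == "nominal":
        codes = pd.factorize(values, use_na_sentinel=True)[0]
        diss = (codes[:, None] != codes[None, :]).astype(float)
    else:
        x = pd.to_numeric(values, errors="raise").to_numpy(dtype=float)
        if kind == "ordinal" and not ordinal_as_continuous:
            # midranks over observed values (Podani), then range-normalised
            r = np.full(n, np.nan)
            r[obs] = rankdata(x[obs], method="average")
            x = r
        rng = np.nanmax(x) - np.nanmin(x) if obs.any() else 0.0
        if rng == 0:
            warnings.warn(
                f"trait '{values.name}' has zero range; it contributes distance 0",
                stacklevel=3,
            )
            diss = np.zeros((n, n))
        else:
            with np.errstate(invalid="ignore"):
                diss = np.abs(x[:, None] - x[None, :]) / rng
        diss = np.nan_to_num(diss, nan=0.0)
    return diss, obs


def gower_distance(table: TraitTable, columns: list[str] | None = None,
                   ordinal_as_continuous: bool = False) -> DistanceMatrix:
    """Species-pairwise Gower distance over the selected trait columns.

    Per pair, the weighted mean of per-trait dissimilarities over traits
    observed in both species.  Raises if any species pair shares no observed
    trait among the selected columns.
    """
    cols = list(columns) if columns is not None else table.columns
    if not cols:
        raise ValueError("no trait columns selected")
    unknown = [c for c in cols if c not in table.data.columns]
    if unknown:
        raise KeyError(f"trait columns not in table: {unknown}")
    n = len(table.data)
    if n < 2:
        raise ValueError("need >= 2 species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in cols:
        w = table.trait_weights[col]
        if w == 0:
            continue
        diss, obs = _column_dissimilarity(
            table.data[col], table.trait_types[col], ordinal_as_continuous
        )
        both = np.logical_and(obs[:, None], obs[None, :])
        num += w * diss * both
        den += w * both
    if (den == 0).any():
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        sp = table.species
        raise ValueError(
            f"species pair ({sp[i]}, {sp[j]}) shares no observed trait among "
            f"{cols}; cannot compute Gower distance"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # guard against fp asymmetry
    return DistanceMatrix(d, ids=table.species)


def combine_columns(table: TraitTable, group: list[str],
                    ordinal_as_continuous: bool = False) -> DistanceMatrix:
    """Equal-weight Gower distance over a group of traits.

    This is the multi-trait pathway of the M statistic: the combination of
    several traits is simply their joint Gower distance with equal weights.
    """
    sub = TraitTable(
        table.data[list(group)],
        {c: table.trait_types[c] for c in group},
        {c: 1.0 for c in group},
    )
    return gower_distance(sub, list(group), ordinal_as_continuous)
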
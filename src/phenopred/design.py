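"""Factorial mating-design layout and record-level incidence bookkeeping.

A complete factorial (NC-II) design crosses every female parent to every
male parent, giving ``n_female * n_male`` hybrids.  Hybrids are evaluated
in a set of environments, each with its own replicate count.  Everything
downstream (variance components, kernels, cross-validation) indexes records
through the :class:`DesignSpec` and :class:`IncidenceMap` defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "IncidenceMap", "hybrid_id"]


def hybrid_id(female: str, male: str) -> str:
    """Canonical hybrid label for a (female, male) cross."""
    return f"{female}x{male}"


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a female x male factorial trial.

    Parameters
    ----------
    n_female, n_male
        Number of female and male parents.  Every female is crossed to
        every male, so the design enumerates ``n_female * n_male`` hybrids.
    environments
        Mapping of environment label -> replicate count (>= 1).
    traits
        Trait names carried by the plot records.
    """

    n_female: int
    n_male: int
    environments: dict[str, int] = field(
        default_factory=lambda: {f"E{i + 1}": 2 for i in range(8)}
    )
    traits: tuple[str, ...] = ("trait",)

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("n_female and n_male must be >= 1")
        if not self.environments:
            raise ValueError("at least one environment is required")
        for env, reps in self.environments.items():
            if reps < 1:
                raise ValueError(f"environment {env!r} has replicate count {reps} < 1")

    @property
    def females(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_female)]

    @property
    def males(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_male)]

    @property
    def n_hybrids(self) -> int:
        return self.n_female * self.n_male

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def hybrid_table(self) -> pd.DataFrame:
        """Enumerate hybrids in female-major order.

        Each hybrid maps to exactly one (female, male) pair.
        """
        rows = [
            {"hybrid": hybrid_id(f, m), "female": f, "male": m}
            for f in self.females
            for m in self.males
        ]
        return pd.DataFrame(rows)

    @property
    def hybrids(self) -> list[str]:
        return [hybrid_id(f, m) for f in self.females for m in self.males]

    def plot_frame(self) -> pd.DataFrame:
        """All (environment, replicate, hybrid) plot rows, without responses."""
        hyb = self.hybrid_table()
        frames = []
        for env, reps in self.environments.items():
            for rep in range(1, reps + 1):
                block = hyb.copy()
                block.insert(0, "environment", env)
                block.insert(1, "replicate", f"R{rep}")
                frames.append(block)
        return pd.concat(frames, ignore_index=True)


class IncidenceMap:
    """Record -> factor-level assignments with 0/1 incidence matrices.

    Wraps a record table with columns such as ``female``, ``male``,
    ``hybrid``, ``environment``, ``replicate`` and produces, per factor,
    the incidence matrix Z whose rows are unit vectors (each record maps
    to exactly one level).
    """

    def __init__(self, records: pd.DataFrame, factors: list[str] | None = None):
        if factors is None:
            factors = [
                c
                for c in ("female", "male", "hybrid", "environment", "replicate")
                if c in records.columns
            ]
        missing = [c for c in factors if c not in records.columns]
        if missing:
            raise KeyError(f"record table lacks factor columns: {missing}")
        self.records = records.reset_index(drop=True)
        self.factors = list(factors)
        self._levels: dict[str, list] = {
            f: sorted(self.records[f].unique().tolist()) for f in self.factors
        }

    @property
    def n_records(self) -> int:
        return len(self.records)

    def levels(self, factor: str) -> list:
        return self._levels[factor]

    def indices(self, factor: str) -> np.ndarray:
        """Integer level index per record for ``factor``."""
        lut = {lev: i for i, lev in enumerate(self._levels[factor])}
        return self.records[factor].map(lut).to_numpy()

    def Z(self, factor: str, levels: list | None = None) -> np.ndarray:
        """Dense 0/1 incidence matrix (records x levels), unit row sums."""
        if levels is None:
            levels = self._levels[factor]
        lut = {lev: i for i, lev in enumerate(levels)}
        col = self.records[factor].map(lut)
        if col.isna().any():
            bad = self.records.loc[col.isna(), factor].unique()
            raise KeyError(f"records map to levels absent from {factor!r}: {list(bad)}")
        Z = np.zeros((len(self.records), len(levels)))
        Z[np.arange(len(self.records)), col.to_numpy(dtype=int)] = 1.0
        return Z

    def interaction_indices(self, *factors: str) -> np.ndarray:
        """Integer index for the crossed levels of several factors."""
        keys = list(zip(*(self.records[f] for f in factors)))
        lut: dict[tuple, int] = {}
        out = np.empty(len(keys), dtype=int)
        for i, k in enumerate(keys):
            out[i] = lut.setdefault(k, len(lut))
        return out
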
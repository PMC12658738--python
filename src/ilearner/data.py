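"""Tabular container for observational treatment-outcome data.

An :class:`ObservationTable` wraps a pandas DataFrame holding covariates L,
a binary treatment A, an outcome Y and a designated conditioning subset
Z of the covariates.  Every learner in the package consumes this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ObservationTable"]


@dataclass
class ObservationTable:
    df: pd.DataFrame
    a_col: str = "A"
    y_col: str = "Y"
    l_cols: list = None
    z_cols: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.l_cols is None:
            reserved = {self.a_col, self.y_col}
            self.l_cols = [c for c in self.df.columns if c not in reserved and not c.startswith("_")]
        if self.z_cols is None:
            self.z_cols = list(self.l_cols)
        for col in [self.a_col, self.y_col, *self.l_cols, *self.z_cols]:
            if col not in self.df.columns:
                raise ValueError(f"column {col!r} not found in table")
        a = self.df[self.a_col].to_numpy()
        bad = ~np.isin(a, (0, 1))
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise ValueError(f"treatment column must be binary 0/1; row {row} has value {a[row]!r}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def A(self) -> np.ndarray:
        return self.df[self.a_col].to_numpy(dtype=int)

    @property
    def Y(self) -> np.ndarray:
        return self.df[self.y_col].to_numpy(dtype=float)

    @property
    def L(self) -> np.ndarray:
        return self.df[self.l_cols].to_numpy(dtype=float)

    @property
    def Z(self) -> np.ndarray:
        return self.df[self.z_cols].to_numpy(dtype=float)

    def with_z(self, z_cols) -> "ObservationTable":
        return ObservationTable(
            self.df, a_col=self.a_col, y_col=self.y_col,
            l_cols=self.l_cols, z_cols=list(z_cols), meta=self.meta,
        )

    def relabeled(self) -> "ObservationTable":
        """Swap treatment labels (A -> 1-A) to target the control-arm counterfactual."""
        df = self.df.copy()
        df[self.a_col] = 1 - df[self.a_col].to_numpy(dtype=int)
        return ObservationTable(
            df, a_col=self.a_col, y_col=self.y_col,
            l_cols=self.l_cols, z_cols=self.z_cols, meta=dict(self.meta),
        )
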
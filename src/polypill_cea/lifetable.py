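"""Age-indexed annual all-cause mortality (life table).

A life table here is the minimal object the cohort engine needs:
contiguous one-year ages and the annual probability of death ``qx`` at
each age, with ``qx = 1`` at the terminal age so the model horizon closes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LifeTable"]


@dataclass(frozen=True)
class LifeTable:
    ages: np.ndarray  # contiguous integer years
    qx: np.ndarray  # annual death probabilities, (0, 1]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be matching non-empty 1-d arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous one-year steps")
        # zero qx is tolerated for degenerate test chains; real tables are
        # strictly positive at every adult age
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("qx at the terminal age must equal 1")

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """Annual death probability at ``age``."""
        if not self.start_age <= age <= self.terminal_age:
            raise ValueError(
                f"age {age} outside life table "
                f"[{self.start_age}, {self.terminal_age}]"
            )
        return float(self.qx[int(age) - self.start_age])

    def life_expectancy(self, age: int) -> float:
        """Remaining life expectancy at ``age`` (half-year convention).

        Sums survival over whole years and credits half a year in the
        year of death.
        """
        i = int(age) - self.start_age
        if not 0 <= i < self.ages.size:
            raise ValueError(f"age {age} outside life table")
        surv = np.cumprod(1.0 - self.qx[i:])
        # full years lived beyond `age` plus 0.5 for the death year
        return float(np.sum(surv) + 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "qx"} - set(df.columns)
        if missing:
            raise ValueError(f"life-table CSV missing columns: {sorted(missing)}")
        df = df.sort_values("age")
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())
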
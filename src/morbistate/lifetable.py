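"""Multistate life tables: life expectancy, healthy life expectancy, years lost.

A fitted intensity model yields one-year transition probability matrices at
each age; a synthetic cohort of ``radix`` persons (all in the starting state
by default) is pushed through them.  Occupancy ``l(x, s)`` counts survivors
in each living state at exact age ``x``; person-years use the linear
within-interval convention ``L(x, s) = (l(x, s) + l(x+1, s)) / 2``, and the
table closes at age omega by crediting survivors ``a_omega`` further years.

Life expectancy at age x is total remaining person-years over survivors at
x; healthy life expectancy restricts the person-years to a designated
healthy-state set, and the difference is the expected years of healthy life
lost to multimorbidity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .multistate import IntensityModel, MultistateResults, transition_probability

__all__ = [
    "age_specific_probabilities",
    "build_life_table",
    "MultistateLifeTable",
]

MIN_AGE = 45.0
DEFAULT_CLOSURE_AGE = 110


def age_specific_probabilities(
    fit: MultistateResults | IntensityModel,
    age_grid: Sequence[int],
    covariates: Mapping[str, float] | None = None,
    age_covariate: str | None = "age",
) -> np.ndarray:
    """One-year transition matrices P_x = expm(Q(z, age=x)) for each age x.

    ``age_covariate`` names the intensity-model covariate carrying age (set
    it to None for an age-homogeneous model, in which case all matrices are
    identical).
    """
    im = fit.intensity_model if isinstance(fit, MultistateResults) else fit
    ages = np.asarray(age_grid, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age grid")
    if np.any(np.diff(ages) != 1):
        raise ValueError("age grid must be consecutive integer years")
    if ages[0] < MIN_AGE or ages[-1] > DEFAULT_CLOSURE_AGE:
        raise ValueError(
            f"ages must lie within [{MIN_AGE:.0f}, {DEFAULT_CLOSURE_AGE}]"
        )
    covariates = dict(covariates or {})
    if age_covariate is not None and age_covariate not in im.covariate_names:
        raise KeyError(f"age covariate {age_covariate!r} not in the intensity model")
    out = []
    for x in ages:
        if age_covariate is not None:
            covariates[age_covariate] = float(x)
        Q = im.intensity_matrix(covariates)
        out.append(transition_probability(Q, 1.0))
    return np.stack(out)


@dataclass
class MultistateLifeTable:
    """Age-indexed state occupancies and person-years for one covariate profile."""

    start_age: int
    closure_age: int
    state_labels: tuple[str, ...]  # living states then death
    occupancy: np.ndarray  # l(x, s): (n_ages + 1, n_states) incl. death column
    person_years: np.ndarray  # L(x, s): (n_ages + 1, n_living); last row = closure
    radix: float
    group: str = ""

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.closure_age + 1)

    @property
    def n_living(self) -> int:
        return len(self.state_labels) - 1

    def _age_row(self, age: float) -> int:
        if not self.start_age <= age <= self.closure_age:
            raise ValueError(
                f"age {age} outside the table range [{self.start_age}, {self.closure_age}]"
            )
        return int(age - self.start_age)

    def life_expectancy(self, age: float) -> float:
        """Expected remaining years in any living state, conditional on being
        alive at ``age``."""
        r = self._age_row(age)
        alive = self.occupancy[r, : self.n_living].sum()
        if alive <= 0:
            raise ValueError(f"no survivors at age {age}")
        return float(self.person_years[r:].sum() / alive)

    def healthy_life_expectancy(self, age: float, healthy_states: Iterable[str]) -> float:
        """Expected remaining years spent in the designated healthy states."""
        healthy = list(healthy_states)
        if not healthy:
            raise ValueError("healthy state set must be non-empty")
        living = self.state_labels[: self.n_living]
        cols = []
        for s in healthy:
            if s not in living:
                raise ValueError(f"healthy state {s!r} is not a living state")
            cols.append(living.index(s))
        r = self._age_row(age)
        alive = self.occupancy[r, : self.n_living].sum()
        if alive <= 0:
            raise ValueError(f"no survivors at age {age}")
        return float(self.person_years[r:, cols].sum() / alive)

    def years_lost(self, age: float, healthy_states: Iterable[str]) -> float:
        """LE minus HLE: expected years of healthy life lost."""
        return self.life_expectancy(age) - self.healthy_life_expectancy(age, healthy_states)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (age, state, l, L) table; death row carries cumulative deaths."""
        rows = []
        for r, age in enumerate(self.ages):
            for j, s in enumerate(self.state_labels):
                rows.append(
                    {
                        "age": int(age),
                        "state": s,
                        "l": float(self.occupancy[r, j]),
                        "L": float(self.person_years[r, j]) if j < self.n_living else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(
        self,
        ages: Sequence[float] = (45, 55, 65, 75),
        healthy_states: Iterable[str] = ("S1",),
    ) -> pd.DataFrame:
        healthy = tuple(healthy_states)
        rows = []
        for age in ages:
            le = self.life_expectancy(age)
            hle = self.healthy_life_expectancy(age, healthy)
            rows.append(
                {
                    "group": self.group,
                    "age": age,
                    "LE": le,
                    "HLE": hle,
                    "years_lost": le - hle,
                    "healthy_states": "+".join(healthy),
                }
            )
        return pd.DataFrame(rows)


def build_life_table(
    per_age_matrices: np.ndarray,
    radix: float = 100_000.0,
    start_age: int = 45,
    start_distribution: Sequence[float] | None = None,
    state_labels: Sequence[str] | None = None,
    a_omega: float = 0.5,
    group: str = "",
) -> MultistateLifeTable:
    """Run the life-table recursion over per-age one-year matrices.

    ``per_age_matrices`` covers ages ``start_age .. omega - 1`` where
    ``omega = start_age + n_ages`` is the closure age; survivors at omega are
    credited ``a_omega`` years each in their current state.  The starting
    cohort is all in the first living state unless ``start_distribution``
    (over living states, summing to 1) says otherwise.
    """
    M = np.asarray(per_age_matrices, dtype=float)
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("per_age_matrices must be (n_ages, n_states, n_states)")
    n_ages, n_states, _ = M.shape
    rowsums = M.sum(axis=2)
    if not np.allclose(rowsums, 1.0, atol=1e-8):
        raise ValueError("transition matrices must be row-stochastic")
    if np.any(M < -1e-12):
        raise ValueError("transition matrices must be non-negative")
    n_living = n_states - 1
    if state_labels is None:
        state_labels = tuple(f"S{i + 1}" for i in range(n_states))
    if start_distribution is None:
        start = np.zeros(n_living)
        start[0] = 1.0
    else:
        start = np.asarray(start_distribution, dtype=float)
        if start.shape != (n_living,) or not np.isclose(start.sum(), 1.0):
            raise ValueError("start_distribution must cover living states and sum to 1")
    l = np.zeros((n_ages + 1, n_states))
    l[0, :n_living] = radix * start
    for a in range(n_ages):
        l[a + 1] = l[a] @ M[a]
    L = np.zeros((n_ages + 1, n_living))
    L[:n_ages] = 0.5 * (l[:n_ages, :n_living] + l[1:, :n_living])
    L[n_ages] = l[n_ages, :n_living] * a_omega
    return MultistateLifeTable(
        start_age=int(start_age),
        closure_age=int(start_age + n_ages),
        state_labels=tuple(state_labels),
        occupancy=l,
        person_years=L,
        radix=float(radix),
        group=group,
    )
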
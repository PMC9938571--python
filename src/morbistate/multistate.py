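"""Progressive continuous-time Markov multistate model for panel data.

States are ordered burden levels S1 < S2 < ... < Sk plus an absorbing death
state; an individual may stay put or move to a strictly more severe living
state, or die, but never recover.  Living states are observed only at survey
waves (interval censoring); death times are exactly dated.

Transition intensities are log-linear in covariates (msm-style proportional
intensities):

    q_rs(z) = q0_rs * exp(beta_rs . (z - offset)),

so ``exp(beta_rs)`` is the per-transition hazard ratio of a unit covariate
change.  The likelihood of an observation pair uses the transition
probability matrix ``P(t) = expm(Q t)``; an exactly dated death at time ``T``
after a last living observation in state ``r`` contributes

    sum over living s of  P_rs(T - t_last) * q_s,death(z).

Fitting follows the statsmodels shape: build a :class:`MultistateModel` from
a panel data frame, call :meth:`~MultistateModel.fit`, and read estimates,
standard errors and per-transition hazard ratios off the returned
:class:`MultistateResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.linalg import expm

__all__ = [
    "StateSpace",
    "IntensityModel",
    "MultistateModel",
    "MultistateResults",
    "build_intensity_matrix",
    "transition_probability",
    "panel_log_likelihood",
    "fit_multistate",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class StateSpace:
    """Ordered living states plus one absorbing death state.

    ``allowed`` holds the permitted transitions; by default every forward
    living-to-living move (r < s) plus death from every living state.
    """

    living: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
    death: str = "S6"
    allowed: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.living)) != len(self.living) or self.death in self.living:
            raise ValueError("state labels must be distinct")
        if self.allowed is None:
            full = {
                (r, s)
                for i, r in enumerate(self.living)
                for s in self.living[i + 1 :]
            }
            full |= {(r, self.death) for r in self.living}
            object.__setattr__(self, "allowed", frozenset(full))
        else:
            object.__setattr__(self, "allowed", frozenset(self.allowed))
            idx = self.index
            for r, s in self.allowed:
                if s == self.death:
                    continue
                if r == self.death or idx(r) >= idx(s):
                    raise ValueError(
                        f"transition {r}->{s} is not progressive (no reversals, "
                        "death absorbing)"
                    )

    @property
    def states(self) -> tuple[str, ...]:
        return self.living + (self.death,)

    @property
    def n_states(self) -> int:
        return len(self.living) + 1

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state label {state!r}") from None

    @property
    def transitions(self) -> tuple[tuple[str, str], ...]:
        """Allowed transitions in deterministic (from, to) index order."""
        return tuple(
            sorted(self.allowed, key=lambda t: (self.index(t[0]), self.index(t[1])))
        )

    def restrict(self, allowed: Sequence[tuple[str, str]]) -> "StateSpace":
        return StateSpace(self.living, self.death, frozenset(allowed))

    @classmethod
    def adjacent_plus_death(cls, n_living: int = 5) -> "StateSpace":
        """Stepwise progression S1->S2->...->Sk with death reachable from all."""
        living = tuple(f"S{i + 1}" for i in range(n_living))
        death = f"S{n_living + 1}"
        allowed = {(living[i], living[i + 1]) for i in range(n_living - 1)}
        allowed |= {(r, death) for r in living}
        return cls(living, death, frozenset(allowed))


@dataclass(frozen=True)
class IntensityModel:
    """Baseline log-intensities and log-linear covariate effects per transition."""

    state_space: StateSpace
    transitions: tuple[tuple[str, str], ...]
    log_baseline: np.ndarray  # (n_transitions,)
    beta: np.ndarray  # (n_transitions, n_covariates)
    covariate_names: tuple[str, ...] = ()
    covariate_offsets: np.ndarray = None  # type: ignore[assignment]
    covariate_scales: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.log_baseline, dtype=float))
        nt, nc = len(self.transitions), len(self.covariate_names)
        if lb.shape != (nt,):
            raise ValueError("log_baseline must have one entry per transition")
        b = np.asarray(self.beta, dtype=float).reshape(nt, nc) if nc else np.zeros((nt, 0))
        off = (
            np.zeros(nc)
            if self.covariate_offsets is None
            else np.asarray(self.covariate_offsets, dtype=float).reshape(nc)
        )
        for tr in self.transitions:
            if tr not in self.state_space.allowed:
                raise ValueError(f"transition {tr} is not allowed by the state space")
        object.__setattr__(self, "log_baseline", lb)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "covariate_offsets", off)
        sc = (
            np.ones(nc)
            if self.covariate_scales is None
            else np.asarray(self.covariate_scales, dtype=float).reshape(nc)
        )
        if np.any(sc <= 0):
            raise ValueError("covariate scales must be > 0")
        object.__setattr__(self, "covariate_scales", sc)

    @classmethod
    def from_rates(
        cls,
        state_space: StateSpace,
        rates: Mapping[tuple[str, str], float],
        beta: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
        covariate_names: Sequence[str] = (),
        covariate_offsets: Sequence[float] | None = None,
        covariate_scales: Sequence[float] | None = None,
    ) -> "IntensityModel":
        transitions = tuple(tr for tr in state_space.transitions if tr in rates)
        for tr, q in rates.items():
            if q <= 0:
                raise ValueError(f"baseline intensity for {tr} must be > 0")
        names = tuple(covariate_names)
        b = np.zeros((len(transitions), len(names)))
        if beta:
            for tr, effs in beta.items():
                for cov, val in effs.items():
                    if cov not in names:
                        raise KeyError(f"unknown covariate name {cov!r}")
                    b[transitions.index(tr), names.index(cov)] = val
        return cls(
            state_space=state_space,
            transitions=transitions,
            log_baseline=np.log([rates[tr] for tr in transitions]),
            beta=b,
            covariate_names=names,
            covariate_offsets=covariate_offsets,
            covariate_scales=covariate_scales,
        )

    def _z(self, covariates: Mapping[str, float]) -> np.ndarray:
        try:
            raw = np.array([float(covariates[c]) for c in self.covariate_names])
        except KeyError as err:
            raise KeyError(f"missing covariate {err.args[0]!r}") from None
        return (raw - self.covariate_offsets) / self.covariate_scales

    def rates(self, covariates: Mapping[str, float] | None = None) -> np.ndarray:
        z = self._z(covariates or {})
        # cap the log-rate: per-year intensities beyond ~e^5 are numerically
        # indistinguishable from instantaneous and would overflow expm during
        # line searches
        return np.exp(np.minimum(self.log_baseline + self.beta @ z, 5.0))

    def intensity_matrix(self, covariates: Mapping[str, float] | None = None) -> np.ndarray:
        """6x6 (generally (k+1)x(k+1)) generator matrix Q(z)."""
        sp = self.state_space
        n = sp.n_states
        Q = np.zeros((n, n))
        q = self.rates(covariates)
        for (r, s), rate in zip(self.transitions, q):
            Q[sp.index(r), sp.index(s)] = rate
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    def to_dict(self) -> dict:
        return {
            "living": list(self.state_space.living),
            "death": self.state_space.death,
            "transitions": [list(t) for t in self.transitions],
            "log_baseline": [float(v) for v in self.log_baseline],
            "beta": [[float(v) for v in row] for row in self.beta],
            "covariate_names": list(self.covariate_names),
            "covariate_offsets": [float(v) for v in self.covariate_offsets],
            "covariate_scales": [float(v) for v in self.covariate_scales],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "IntensityModel":
        transitions = tuple(tuple(t) for t in data["transitions"])
        space = StateSpace(
            living=tuple(data["living"]),
            death=data["death"],
            allowed=frozenset(transitions),
        )
        return cls(
            state_space=space,
            transitions=transitions,
            log_baseline=np.asarray(data["log_baseline"], dtype=float),
            beta=np.asarray(data["beta"], dtype=float),
            covariate_names=tuple(data["covariate_names"]),
            covariate_offsets=np.asarray(data.get("covariate_offsets", None), dtype=float)
            if data.get("covariate_offsets") is not None
            else None,
            covariate_scales=np.asarray(data.get("covariate_scales", None), dtype=float)
            if data.get("covariate_scales") is not None
            else None,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def build_intensity_matrix(
    intensity_model: IntensityModel, covariates: Mapping[str, float] | None = None
) -> np.ndarray:
    """Generator matrix Q(z) with diagonal = minus the row outflow."""
    return intensity_model.intensity_matrix(covariates)


def transition_probability(rate_matrix: np.ndarray, elapsed_years: float) -> np.ndarray:
    """P(t) = expm(Q t) via scaling and squaring; rows sum to one."""
    if elapsed_years < 0:
        raise ValueError(f"elapsed time must be >= 0, got {elapsed_years}")
    Q = np.asarray(rate_matrix, dtype=float)
    P = expm(Q * float(elapsed_years))
    P[(P < 0) & (P > -1e-9)] = 0.0
    return P


class MultistateModel:
    """Progressive multistate Markov model built from a panel data frame.

    Parameters
    ----------
    data
        One row per participant-observation with columns for participant id,
        years since baseline, state label, vital status and the covariates.
    state_space
        The ordered state space with its allowed transition set.
    covariate_names
        Covariates entering every transition intensity log-linearly; values
        are taken from each participant's first record (time-fixed).
    exact_death_times
        If true (default), a terminal record with ``vital_col == "dead"``
        contributes the exactly-dated death density; otherwise death is
        treated as interval-censored like any other state.
    age_covariate
        Name of a covariate holding age in years at baseline.  When set, the
        covariate is updated annually along each observation interval
        (piecewise-constant intensities within one-year segments) and is
        centred at ``age_center`` inside the log-linear predictor.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        state_space: StateSpace | None = None,
        covariate_names: Sequence[str] = (),
        *,
        id_col: str = "id",
        time_col: str = "years_since_baseline",
        state_col: str = "state",
        vital_col: str = "vital_status",
        dead_label: str = "dead",
        exact_death_times: bool = True,
        age_covariate: str | None = None,
        age_center: float = 60.0,
        age_scale: float = 10.0,
        drop_unsupported: bool = True,
    ):
        self.state_space = state_space or StateSpace()
        self.covariate_names = tuple(covariate_names)
        if age_covariate is not None and age_covariate not in self.covariate_names:
            raise ValueError("age_covariate must be listed in covariate_names")
        self.age_covariate = age_covariate
        self.age_center = float(age_center)
        self.age_scale = float(age_scale)
        if self.age_scale <= 0:
            raise ValueError("age_scale must be > 0")
        self.exact_death_times = exact_death_times
        self._offsets = np.array(
            [self.age_center if c == age_covariate else 0.0 for c in self.covariate_names]
        )
        self._scales = np.array(
            [self.age_scale if c == age_covariate else 1.0 for c in self.covariate_names]
        )
        self._build_contributions(
            data, id_col, time_col, state_col, vital_col, dead_label
        )
        self._select_transitions(drop_unsupported)

    # ------------------------------------------------------------------ data
    def _effective_z(self, z0: np.ndarray, t: float) -> tuple:
        """Covariate vector at interval time t (age updated at whole years)."""
        if self.age_covariate is None:
            return tuple(z0)
        z = z0.copy()
        i = self.covariate_names.index(self.age_covariate)
        z[i] = z0[i] + np.floor(t) / self._scales[i]
        return tuple(z)

    def _segments(self, z0: np.ndarray, t0: float, t1: float) -> tuple:
        """Split [t0, t1] at integer years since baseline (age updating)."""
        if self.age_covariate is None or t1 == t0:
            return ((self._effective_z(z0, t0), t1 - t0),)
        cuts = [t0]
        nxt = np.floor(t0) + 1.0
        while nxt < t1 - 1e-12:
            cuts.append(float(nxt))
            nxt += 1.0
        cuts.append(t1)
        return tuple(
            (self._effective_z(z0, a), b - a) for a, b in zip(cuts[:-1], cuts[1:])
        )

    def _build_contributions(self, data, id_col, time_col, state_col, vital_col, dead_label):
        sp = self.state_space
        needed = [id_col, time_col, state_col]
        for col in needed + list(self.covariate_names):
            if col not in data.columns:
                raise KeyError(f"panel data lacks required column {col!r}")
        has_vital = vital_col in data.columns
        df = data.sort_values([id_col, time_col], kind="mergesort")
        # contributions, grouped for vectorized evaluation
        single_pairs: dict[tuple, dict] = {}
        single_deaths: dict[tuple, list] = {}
        multi: dict[tuple, int] = {}
        n_participants = 0
        n_pairs = 0
        n_deaths = 0
        for pid, grp in df.groupby(id_col, sort=False):
            n_participants += 1
            times = grp[time_col].to_numpy(dtype=float)
            states = grp[state_col].to_numpy()
            vital = (
                grp[vital_col].to_numpy()
                if has_vital
                else np.array(["alive"] * len(grp))
            )
            z0 = (
                grp.iloc[0][list(self.covariate_names)].to_numpy(dtype=float)
                if self.covariate_names
                else np.zeros(0)
            )
            z0 = (z0 - self._offsets) / self._scales
            prev_idx = None
            last_living_t = None
            for t, s, v in zip(times, states, vital):
                is_dead = (v == dead_label) or (s == sp.death)
                si = sp.index(sp.death if is_dead else s)
                if prev_idx is not None and si < prev_idx:
                    raise ValueError(
                        f"participant {pid!r} has a decreasing state sequence "
                        f"({sp.states[prev_idx]} -> {sp.states[si]}); the model "
                        "is progressive"
                    )
                if prev_idx is not None:
                    segs = self._segments(z0, last_living_t, t)
                    if is_dead and self.exact_death_times:
                        n_deaths += 1
                        if len(segs) == 1:
                            key = (segs[0][0], prev_idx)
                            single_deaths.setdefault(key, []).append(segs[0][1])
                        else:
                            k = ("death", prev_idx, None, segs)
                            multi[k] = multi.get(k, 0) + 1
                    else:
                        n_pairs += 1
                        if len(segs) == 1:
                            key = (segs[0][0], prev_idx, si)
                            entry = single_pairs.setdefault(key, {})
                            entry[segs[0][1]] = entry.get(segs[0][1], 0) + 1
                        else:
                            k = ("pair", prev_idx, si, segs)
                            multi[k] = multi.get(k, 0) + 1
                if is_dead:
                    prev_idx = None  # absorbing: nothing after death
                    break
                prev_idx = si
                last_living_t = t
        self.n_participants = n_participants
        self.n_obs_pairs = n_pairs
        self.n_deaths = n_deaths
        self._single_pairs = {
            key: (np.array(list(d.keys())), np.array(list(d.values()), dtype=float))
            for key, d in single_pairs.items()
        }
        self._single_deaths = {
            key: np.array(v) for key, v in single_deaths.items()
        }
        self._multi = [(kind, a, b, segs, c) for (kind, a, b, segs), c in multi.items()]
        self._compile()

    def _compile(self) -> None:
        """Index the contributions for vectorized likelihood evaluation.

        Unique covariate vectors get one generator each; unique
        (covariate, elapsed-time) pairs get one probability matrix each,
        computed for the whole stack at once per likelihood call.
        """
        zmap: dict[tuple, int] = {}
        pdmap: dict[tuple, int] = {}

        def zid(z: tuple) -> int:
            return zmap.setdefault(z, len(zmap))

        def pdid(z: tuple, dt: float) -> int:
            return pdmap.setdefault((zid(z), float(dt)), len(pdmap))

        pair_pd, pair_a, pair_b, pair_w = [], [], [], []
        for (z, a, b), (dts, wts) in self._single_pairs.items():
            for dt, w in zip(dts, wts):
                pair_pd.append(pdid(z, dt))
                pair_a.append(a)
                pair_b.append(b)
                pair_w.append(w)
        death_pd, death_a, death_z = [], [], []
        for (z, a), dts in self._single_deaths.items():
            for dt in dts:
                death_pd.append(pdid(z, dt))
                death_a.append(a)
                death_z.append(zmap[z])
        multi_c = []
        for kind, a, b, segs, count in self._multi:
            pids = tuple(pdid(z, dt) for z, dt in segs)
            multi_c.append((kind, a, b, pids, zid(segs[-1][0]), count))
        nc = len(self.covariate_names)
        self._Z = (
            np.array(list(zmap.keys()), dtype=float).reshape(len(zmap), nc)
            if zmap
            else np.zeros((0, nc))
        )
        self._pd_z = np.array([k[0] for k in pdmap], dtype=np.intp)
        self._pd_t = np.array([k[1] for k in pdmap], dtype=float)
        self._pair_pd = np.array(pair_pd, dtype=np.intp)
        self._pair_a = np.array(pair_a, dtype=np.intp)
        self._pair_b = np.array(pair_b, dtype=np.intp)
        self._pair_w = np.array(pair_w, dtype=float)
        self._death_pd = np.array(death_pd, dtype=np.intp)
        self._death_a = np.array(death_a, dtype=np.intp)
        self._death_z = np.array(death_z, dtype=np.intp)
        self._multi_c = multi_c

    def _select_transitions(self, drop_unsupported: bool) -> None:
        """Keep allowed transitions with at least one supporting observed pair."""
        sp = self.state_space
        supported = set()
        pair_spans = []
        for (z, a, b), _ in self._single_pairs.items():
            pair_spans.append((a, b))
        for kind, a, b, segs, _ in self._multi:
            pair_spans.append((a, b if kind == "pair" else sp.n_states - 1))
        for (z, a), _ in self._single_deaths.items():
            pair_spans.append((a, sp.n_states - 1))
        for r, s in sp.transitions:
            ri, si = sp.index(r), sp.index(s)
            for a, b in pair_spans:
                if a <= ri and b >= si:
                    supported.add((r, s))
                    break
        dropped = [tr for tr in sp.transitions if tr not in supported]
        if dropped and drop_unsupported:
            warnings.warn(
                "dropping transitions with no supporting observed pair: "
                + ", ".join(f"{r}->{s}" for r, s in dropped),
                stacklevel=3,
            )
            self.transitions = tuple(tr for tr in sp.transitions if tr in supported)
        else:
            self.transitions = sp.transitions
        self.n_transitions = len(self.transitions)
        self.k_params = self.n_transitions * (1 + len(self.covariate_names))
        self.param_names = [f"logq({r}->{s})" for r, s in self.transitions] + [
            f"beta({r}->{s}):{c}"
            for r, s in self.transitions
            for c in self.covariate_names
        ]

    # ------------------------------------------------------------ likelihood
    def pack(self, intensity_model: IntensityModel) -> np.ndarray:
        """Parameter vector for an intensity model over this model's transitions."""
        im = intensity_model
        idx = [im.transitions.index(tr) for tr in self.transitions]
        lb = im.log_baseline[idx]
        if self.covariate_names:
            cols = [im.covariate_names.index(c) for c in self.covariate_names]
            b = im.beta[np.ix_(idx, cols)]
        else:
            b = np.zeros((len(idx), 0))
        return np.concatenate([lb, b.ravel()])

    def _generator_stack(self, params: np.ndarray) -> np.ndarray:
        """Generator matrix Q(z) for every unique covariate vector, stacked."""
        nt, nc = self.n_transitions, len(self.covariate_names)
        lb = params[:nt]
        beta = params[nt:].reshape(nt, nc) if nc else np.zeros((nt, 0))
        K = max(len(self._Z), 1)
        Z = self._Z if len(self._Z) else np.zeros((1, nc))
        logq = lb[None, :] + (Z @ beta.T if nc else 0.0)
        rates = np.exp(np.minimum(logq, 5.0))  # cap: see IntensityModel.rates
        sp = self.state_space
        n = sp.n_states
        r_idx = np.array([sp.index(r) for r, _ in self.transitions], dtype=np.intp)
        s_idx = np.array([sp.index(s) for _, s in self.transitions], dtype=np.intp)
        Qs = np.zeros((K, n, n))
        Qs[:, r_idx, s_idx] = rates
        d = np.arange(n)
        Qs[:, d, d] = -Qs.sum(axis=2)
        return Qs

    def _probability_stack(self, Qs: np.ndarray) -> np.ndarray:
        """expm(Q_z * dt) for every unique (covariate, elapsed-time) pair.

        One vectorized eigendecomposition of the whole generator stack;
        matrices whose decomposition does not reconstruct the generator to
        near machine precision (defective cases) fall back to direct expm.
        """
        n = Qs.shape[1]
        if len(self._pd_t) == 0:
            return np.zeros((0, n, n))
        with np.errstate(invalid="ignore"):
            w, V = np.linalg.eig(Qs)
            try:
                Vinv = np.linalg.inv(V)
                recon = (V * w[:, None, :]) @ Vinv
                scale = 1.0 + np.abs(Qs).max(axis=(1, 2))
                bad = np.abs(recon.real - Qs).max(axis=(1, 2)) > 1e-12 * scale
                bad |= np.abs(recon.imag).max(axis=(1, 2)) > 1e-12 * scale
            except np.linalg.LinAlgError:
                bad = np.ones(Qs.shape[0], dtype=bool)
        zi = self._pd_z
        E = np.exp(w[zi] * self._pd_t[:, None])
        P = ((V[zi] * E[:, None, :]) @ Vinv[zi]).real if not bad.all() else np.empty(
            (len(zi), n, n)
        )
        if bad.any():
            for k in np.flatnonzero(bad[zi]):
                P[k] = expm(Qs[zi[k]] * self._pd_t[k])
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def loglike(self, params: np.ndarray) -> float:
        """Interval-censored panel log-likelihood with exact death times."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.k_params,):
            raise ValueError(f"expected {self.k_params} parameters, got {params.shape}")
        sp = self.state_space
        nl = sp.n_states - 1
        Qs = self._generator_stack(params)
        P = self._probability_stack(Qs)
        total = 0.0
        if len(self._pair_pd):
            vals = P[self._pair_pd, self._pair_a, self._pair_b]
            total += float(self._pair_w @ np.log(np.maximum(vals, _LOG_FLOOR)))
        if len(self._death_pd):
            qdeath = Qs[:, :nl, nl]  # (K, n_living) intensities into death
            dens = np.einsum(
                "ij,ij->i", P[self._death_pd, self._death_a, :nl], qdeath[self._death_z]
            )
            total += float(np.sum(np.log(np.maximum(dens, _LOG_FLOOR))))
        prod_cache: dict[tuple, np.ndarray] = {}
        for kind, a, b, pids, z_last, count in self._multi_c:
            M = prod_cache.get(pids)
            if M is None:
                M = P[pids[0]]
                for pi in pids[1:]:
                    M = M @ P[pi]
                prod_cache[pids] = M
            if kind == "pair":
                val = M[a, b]
            else:
                val = M[a, :nl] @ Qs[z_last, :nl, nl]
            total += count * float(np.log(max(val, _LOG_FLOOR)))
        return total

    # ------------------------------------------------------------------- fit
    def _start_params(self) -> np.ndarray:
        sp = self.state_space
        # crude occurrence/exposure rates per retained transition
        py = np.zeros(sp.n_states)
        counts: dict[tuple[int, int], float] = {}
        for (z, a, b), (dts, wts) in self._single_pairs.items():
            py[a] += float(dts @ wts)
            counts[(a, b)] = counts.get((a, b), 0.0) + float(wts.sum())
        for (z, a), dts in self._single_deaths.items():
            py[a] += float(dts.sum())
            key = (a, sp.n_states - 1)
            counts[key] = counts.get(key, 0.0) + len(dts)
        for kind, a, b, segs, c in self._multi:
            py[a] += c * sum(dt for _, dt in segs)
            bi = b if kind == "pair" else sp.n_states - 1
            counts[(a, bi)] = counts.get(
                (a, bi), 0.0
            ) + c
        lb = []
        for r, s in self.transitions:
            a, b = sp.index(r), sp.index(s)
            rate = (counts.get((a, b), 0.0) + 0.5) / (py[a] + 1.0)
            lb.append(np.log(max(rate, 1e-4)))
        return np.concatenate(
            [np.array(lb), np.zeros(self.n_transitions * len(self.covariate_names))]
        )

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 500,
        compute_cov: bool = True,
    ) -> "MultistateResults":
        """Maximize the panel likelihood by quasi-Newton (L-BFGS-B).

        Parameters are boxed (log-rates in [-15, 5], effects in [-10, 10]) so
        that monotone-likelihood directions — a transition with no supporting
        events in one covariate group, whose MLE lies at infinity — stop at
        the box instead of stalling the line search; such parameters surface
        with hazard ratios ~0 (or huge) and unbounded Wald intervals.
        """
        x0 = self._start_params() if start_params is None else np.asarray(start_params)
        nll = lambda p: -self.loglike(p)
        nt = self.n_transitions
        bounds = [(-15.0, 5.0)] * nt + [(-10.0, 10.0)] * (self.k_params - nt)
        res = optimize.minimize(
            nll,
            np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            jac="3-point",
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 400000, "ftol": 1e-11, "gtol": 1e-6},
        )
        cov = None
        singular = np.zeros(self.k_params, dtype=bool)
        if compute_cov:
            H = _fd_hessian(nll, res.x)
            try:
                cov = np.linalg.inv(H)
                if not np.all(np.diag(cov) > 0):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
                diag = np.diag(cov)
                singular = ~(diag > 0)
        return MultistateResults(
            model=self,
            params=res.x,
            loglike_value=-res.fun,
            converged=bool(res.success),
            n_iter=int(res.nit),
            message=str(res.message),
            cov_params=cov,
            singular_params=singular,
        )


def _fd_hessian(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian on the working (log/linear) scale."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.zeros((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        for j in range(i, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


class MultistateResults:
    """Fitted multistate model: estimates, covariance, hazard ratios, summary."""

    def __init__(
        self,
        model: MultistateModel,
        params: np.ndarray,
        loglike_value: float,
        converged: bool,
        n_iter: int,
        message: str,
        cov_params: np.ndarray | None,
        singular_params: np.ndarray,
    ):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.loglike = float(loglike_value)
        self.converged = converged
        self.n_iter = n_iter
        self.message = message
        self.cov_params = cov_params
        self.singular_params = singular_params
        self.bse = (
            np.sqrt(np.maximum(np.diag(cov_params), 0.0))
            if cov_params is not None
            else np.full_like(self.params, np.nan)
        )

    @property
    def intensity_model(self) -> IntensityModel:
        m = self.model
        nt, nc = m.n_transitions, len(m.covariate_names)
        return IntensityModel(
            state_space=m.state_space,
            transitions=m.transitions,
            log_baseline=self.params[:nt],
            beta=self.params[nt:].reshape(nt, nc) if nc else np.zeros((nt, 0)),
            covariate_names=m.covariate_names,
            covariate_offsets=m._offsets,
            covariate_scales=m._scales,
        )

    def transition_probability(
        self, elapsed_years: float, covariates: Mapping[str, float] | None = None
    ) -> np.ndarray:
        Q = self.intensity_model.intensity_matrix(covariates)
        return transition_probability(Q, elapsed_years)

    def hazard_ratio_table(self, covariate: str | None = None) -> pd.DataFrame:
        """Tidy per-transition hazard-ratio table with Wald 95% CIs.

        One row per retained transition and covariate; ``covariate`` filters
        to a single covariate (e.g. the relationship-group indicator, whose
        reference level is the group coded 0).
        """
        from scipy import stats

        m = self.model
        nt = m.n_transitions
        rows = []
        for j, c in enumerate(m.covariate_names):
            if covariate is not None and c != covariate:
                continue
            for i, (r, s) in enumerate(m.transitions):
                k = nt + i * len(m.covariate_names) + j
                b, se = self.params[k], self.bse[k]
                zstat = b / se if se > 0 else np.nan
                p = 2 * stats.norm.sf(abs(zstat)) if np.isfinite(zstat) else np.nan
                rows.append(
                    {
                        "transition": f"{r}->{s}",
                        "covariate": c,
                        "coef": b,
                        "se": se,
                        "hr": np.exp(b),
                        "hr_lower": np.exp(b - 1.959963984540054 * se),
                        "hr_upper": np.exp(b + 1.959963984540054 * se),
                        "p": p,
                    }
                )
        return pd.DataFrame(rows)

    def baseline_rate_table(self) -> pd.DataFrame:
        m = self.model
        rows = []
        for i, (r, s) in enumerate(m.transitions):
            b, se = self.params[i], self.bse[i]
            rows.append(
                {
                    "transition": f"{r}->{s}",
                    "rate": np.exp(b),
                    "rate_lower": np.exp(b - 1.959963984540054 * se),
                    "rate_upper": np.exp(b + 1.959963984540054 * se),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Progressive multistate Markov model (interval-censored panel likelihood)",
            f"participants: {m.n_participants}   observation pairs: {m.n_obs_pairs}"
            f"   exact deaths: {m.n_deaths}",
            f"log-likelihood: {self.loglike:.4f}   converged: {self.converged}"
            f" ({self.n_iter} iterations)",
            "",
            self.baseline_rate_table().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        if m.covariate_names:
            lines += [
                "",
                self.hazard_ratio_table().to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                ),
            ]
        return "\n".join(lines)

    def to_yaml(self, path) -> None:
        data = {
            "param_names": list(self.model.param_names),
            "params": [float(v) for v in self.params],
            "bse": [float(v) for v in self.bse],
            "loglike": self.loglike,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "transitions": [f"{r}->{s}" for r, s in self.model.transitions],
            "covariate_names": list(self.model.covariate_names),
            "intensity_model": self.intensity_model.to_dict(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def panel_log_likelihood(
    intensity_model: IntensityModel,
    panel_dataset: pd.DataFrame,
    **model_kwargs,
) -> float:
    """Log-likelihood of a panel data set under a given intensity model."""
    model = MultistateModel(
        panel_dataset,
        state_space=intensity_model.state_space,
        covariate_names=intensity_model.covariate_names,
        drop_unsupported=False,
        **model_kwargs,
    )
    model.transitions = intensity_model.transitions
    model.n_transitions = len(model.transitions)
    model.k_params = model.n_transitions * (1 + len(model.covariate_names))
    return model.loglike(model.pack(intensity_model))


def fit_multistate(
    panel_dataset: pd.DataFrame,
    state_space: StateSpace | None = None,
    covariate_names: Sequence[str] = (),
    initial_values: np.ndarray | None = None,
    **model_kwargs,
) -> MultistateResults:
    """Convenience wrapper: build a :class:`MultistateModel` and fit it."""
    model = MultistateModel(
        panel_dataset, state_space=state_space, covariate_names=covariate_names, **model_kwargs
    )
    return model.fit(start_params=initial_values)
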
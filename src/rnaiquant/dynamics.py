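"""Six-species ODE model of RNA kinetics during RNAi.

Species (all concentrations in arbitrary units): trigger dsRNA (``ds``),
1° siRNA (``pri``), pUG RNA (``ug``), 2° siRNA (``sec``), pre-mRNA
(``p``), and mRNA (``m``).  Rate equations::

    d[ds]/dt  = -k1*ds
    d[pri]/dt =  k1*ds*(l_ds/22) - k2*pri*m - t_pri*pri
    d[ug]/dt  =  k3*pri*m - t_ug*ug
    d[sec]/dt =  k4*l_m*ug - k5*sec*m - k6*sec*p - t_sec*sec
    d[p]/dt   =  k9 - k8*sec*p - k6*sec*p - k7*p - t_p*p
    d[m]/dt   =  k7*p - k2*pri*m - k5*sec*m - t_m*m

k1: 1° siRNA processing from dsRNA (each trigger yields l_ds/22 siRNAs of
22 nt); k2: 1° siRNA binding to mRNA; k3: pUG RNA production upon target
recognition; k4: 2° siRNA production per pUG template (scaled by template
length l_m); k5/k6: 2° siRNA binding to mRNA/pre-mRNA; k7: export and
splicing; k8: transcriptional repression by pre-mRNA-bound 2° siRNA;
k9: transcription.  t_* are first-order turnover rates.

Without silencing species the pre-mRNA/mRNA balance reduces to
``dp/dt = k9 - (k7 + t_p)*p`` and ``dm/dt = k7*p - t_m*m`` with steady
state ``p* = k9/(k7 + t_p)``, ``m* = k7*p*/t_m``.

Integration uses classical RK4 with a per-step non-negativity bound: the
composed increment ``dx`` is applied only if ``x + dx > 0``; otherwise
the species is set to exactly 0.  Intermediate RK4 stage states are
evaluated on nonnegative projections so derivative preconditions hold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPECIES = ("ds", "pri", "ug", "sec", "p", "m")

#: Length of one siRNA in nucleotides; sets how many 1° siRNAs one
#: trigger molecule yields (l_ds / 22).
SIRNA_NT = 22.0


@dataclass(frozen=True)
class RateParameters:
    """Rate constants, turnover rates, and RNA lengths.

    Defaults are the reference parameter set used throughout: all
    turnover rates 0.05, k1=1, k2=0.01, k3=1, k4=0.05 (so k4*l_m=0.5
    with l_m=10), k5=0.01, k6=0.01, k7=0.1, k8=0.05, k9=7.5.
    """

    k1: float = 1.0
    k2: float = 0.01
    k3: float = 1.0
    k4: float = 0.05
    k5: float = 0.01
    k6: float = 0.01
    k7: float = 0.1
    k8: float = 0.05
    k9: float = 7.5
    t_pri: float = 0.05
    t_ug: float = 0.05
    t_sec: float = 0.05
    t_p: float = 0.05
    t_m: float = 0.05
    l_ds: float = 100.0
    l_m: float = 10.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if self.l_ds <= 0 or self.l_m <= 0:
            raise ValueError("l_ds and l_m must be > 0")

    def replace(self, **kwargs) -> "RateParameters":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def reference_parameters(**overrides) -> RateParameters:
    """The reference parameter set (see :class:`RateParameters`)."""
    return RateParameters(**overrides)


@dataclass(frozen=True)
class RNAState:
    """Concentrations of the six RNA species (arbitrary units)."""

    ds: float = 0.0
    pri: float = 0.0
    ug: float = 0.0
    sec: float = 0.0
    p: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "RNAState":
        return cls(**dict(zip(SPECIES, map(float, arr))))


def _derivatives_batch(S: np.ndarray, P: Mapping[str, np.ndarray]) -> np.ndarray:
    """Vectorized right-hand side; ``S`` has shape (n, 6)."""
    ds, pri, ug, sec, p, m = (S[:, i] for i in range(6))
    return np.stack(
        [
            -P["k1"] * ds,
            P["k1"] * ds * P["l_ds"] / SIRNA_NT - P["k2"] * pri * m - P["t_pri"] * pri,
            P["k3"] * pri * m - P["t_ug"] * ug,
            P["k4"] * P["l_m"] * ug - P["k5"] * sec * m - P["k6"] * sec * p
            - P["t_sec"] * sec,
            P["k9"] - P["k8"] * sec * p - P["k6"] * sec * p - P["k7"] * p
            - P["t_p"] * p,
            P["k7"] * p - P["k2"] * pri * m - P["k5"] * sec * m - P["t_m"] * m,
        ],
        axis=1,
    )


def derivatives(state: RNAState, params: RateParameters) -> dict[str, float]:
    """Instantaneous rate of change of each species."""
    arr = state.as_array()
    if (arr < 0).any():
        raise ValueError("state components must be >= 0")
    P = {k: np.asarray(v, dtype=float) for k, v in params.as_dict().items()}
    d = _derivatives_batch(arr[None, :], P)[0]
    return dict(zip(SPECIES, map(float, d)))


def _rk4_step_batch(S: np.ndarray, P: Mapping, dt: float) -> np.ndarray:
    a = _derivatives_batch(S, P)
    b = _derivatives_batch(np.maximum(S + 0.5 * dt * a, 0.0), P)
    c = _derivatives_batch(np.maximum(S + 0.5 * dt * b, 0.0), P)
    d = _derivatives_batch(np.maximum(S + dt * c, 0.0), P)
    out = S + (dt / 6.0) * (a + 2.0 * b + 2.0 * c + d)
    # bounding rule: x + dx kept only if positive, else the species is 0
    out[out <= 0.0] = 0.0
    return out


def step(state: RNAState, params: RateParameters, dt: float) -> RNAState:
    """One bounded RK4 step of size ``dt``."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    P = {k: np.asarray(v, dtype=float) for k, v in params.as_dict().items()}
    return RNAState.from_array(_rk4_step_batch(state.as_array()[None, :], P, dt)[0])


def baseline_steady_state(params: RateParameters) -> RNAState:
    """Pre-exposure steady state: silencing species absent.

    ``p* = k9/(k7 + t_p)``, ``m* = k7 p*/t_m``.  With ``t_m = 0`` and
    ``k9 > 0`` there is no finite steady state.
    """
    if params.k7 + params.t_p <= 0:
        if params.k9 > 0:
            raise ValueError("no finite steady state: k7 + t_p = 0 with k9 > 0")
        return RNAState()
    p_star = params.k9 / (params.k7 + params.t_p)
    if params.t_m <= 0:
        if params.k7 * p_star > 0:
            raise ValueError("no finite steady state: t_m = 0 with mRNA production > 0; "
                             "supply the initial state explicitly")
        m_star = 0.0
    else:
        m_star = params.k7 * p_star / params.t_m
    return RNAState(p=p_star, m=m_star)


@dataclass
class Trajectory:
    """Integration output on a uniform time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 6), columns in SPECIES order
    params: RateParameters
    dt: float
    dose: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        return df

    def peak_time(self, name: str) -> float:
        return float(self.times[np.argmax(self.species(name))])

    def knockdown_metrics(self, threshold_fraction: float = 0.10) -> "KnockdownMetrics":
        return knockdown_metrics(self, threshold_fraction)


@dataclass
class KnockdownMetrics:
    """Summary of one knockdown trajectory.

    ``tau_kd`` is the first time mRNA drops below the threshold
    ``m_kd = threshold_fraction * m(0)`` (None if never); ``t_kd`` the
    total time spent below it; ``m_min`` / ``sec_max`` the extreme mRNA
    and 2° siRNA concentrations.
    """

    threshold_fraction: float
    m_kd: float
    tau_kd: float | None
    t_kd: float
    m_min: float
    sec_max: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def knockdown_metrics(traj: Trajectory, threshold_fraction: float = 0.10) -> KnockdownMetrics:
    """Threshold-based knockdown metrics of a trajectory."""
    if not 0 < threshold_fraction < 1:
        raise ValueError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    if traj.states.shape[0] == 0:
        raise ValueError("empty trajectory")
    m = traj.species("m")
    m_kd = threshold_fraction * m[0]
    below = m < m_kd
    tau_kd = float(traj.times[np.argmax(below)]) if below.any() else None
    return KnockdownMetrics(
        threshold_fraction=threshold_fraction,
        m_kd=float(m_kd),
        tau_kd=tau_kd,
        t_kd=float(below.sum() * traj.dt),
        m_min=float(m.min()),
        sec_max=float(traj.species("sec").max()),
    )


class DynamicsModel:
    """RNAi kinetics simulator for a fixed parameter set.

    Parameters default to the reference set; ``simulate`` starts from the
    baseline steady state (or a supplied state) with the dsRNA dose added
    at t=0 and integrates with bounded RK4.
    """

    #: default dsRNA dose (molecules) for the reference trajectory
    DEFAULT_DOSE = 1.0

    def __init__(self, params: RateParameters | None = None,
                 dt: float = 0.01, t_end: float = 500.0) -> None:
        self.params = params if params is not None else reference_parameters()
        self.dt = dt
        self.t_end = t_end

    # -- single trajectories -------------------------------------------------

    def simulate(
        self,
        dose: float = DEFAULT_DOSE,
        t_end: float | None = None,
        dt: float | None = None,
        initial: RNAState | None = None,
    ) -> Trajectory:
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        dt = self.dt if dt is None else dt
        t_end = self.t_end if t_end is None else t_end
        if dt <= 0 or t_end <= 0:
            raise ValueError("dt and t_end must be > 0")
        if dt >= t_end:
            raise ValueError("dt must be smaller than t_end")
        init = initial if initial is not None else baseline_steady_state(self.params)
        s0 = init.as_array()
        s0[SPECIES.index("ds")] = dose
        P = {k: np.asarray(v, dtype=float) for k, v in self.params.as_dict().items()}
        n_steps = int(round(t_end / dt))
        states = np.empty((n_steps + 1, 6))
        states[0] = s0
        S = s0[None, :].copy()
        for i in range(n_steps):
            S = _rk4_step_batch(S, P, dt)
            states[i + 1] = S[0]
        times = np.arange(n_steps + 1) * dt
        return Trajectory(times, states, self.params, dt, dose)

    # -- batch machinery -----------------------------------------------------

    @staticmethod
    def _simulate_metrics_batch(
        param_table: pd.DataFrame,
        dose: float,
        t_end: float,
        dt: float,
        threshold_fraction: float = 0.10,
        initial: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Integrate many parameter sets at once, tracking metrics online."""
        n = len(param_table)
        P = {f.name: np.asarray(param_table[f.name], dtype=float)
             for f in dataclasses.fields(RateParameters)}
        if initial is None:
            p_star = P["k9"] / (P["k7"] + P["t_p"])
            with np.errstate(divide="ignore", invalid="ignore"):
                m_star = np.where(P["t_m"] > 0, P["k7"] * p_star / np.maximum(P["t_m"], 1e-300), 0.0)
            S = np.zeros((n, 6))
            S[:, SPECIES.index("p")] = p_star
            S[:, SPECIES.index("m")] = m_star
        else:
            S = np.array(initial, dtype=float)
        S[:, SPECIES.index("ds")] = dose
        m_col, sec_col = SPECIES.index("m"), SPECIES.index("sec")
        m0 = S[:, m_col].copy()
        m_kd = threshold_fraction * m0
        tau = np.full(n, np.nan)
        below_steps = np.zeros(n)
        m_min = m0.copy()
        sec_max = np.zeros(n)
        n_steps = int(round(t_end / dt))
        for i in range(n_steps):
            S = _rk4_step_batch(S, P, dt)
            m = S[:, m_col]
            below = m < m_kd
            newly = below & np.isnan(tau)
            tau[newly] = (i + 1) * dt
            below_steps += below
            np.minimum(m_min, m, out=m_min)
            np.maximum(sec_max, S[:, sec_col], out=sec_max)
        out = param_table.reset_index(drop=True).copy()
        out["tau_kd"] = tau  # NaN encodes "never crossed"
        out["t_kd"] = below_steps * dt
        out["m_min"] = m_min
        out["sec_max"] = sec_max
        out["m_final"] = S[:, m_col]
        return out

    # -- in-silico experiments ----------------------------------------------

    def run_sweep(
        self,
        varied: Mapping[str, Sequence[float]] | Sequence[str],
        n: int | None = None,
        seed: int = 0,
        dose: float = DEFAULT_DOSE,
        t_end: float | None = None,
        dt: float | None = None,
        span: float = 10.0,
    ) -> pd.DataFrame:
        """Knockdown metrics across varied parameters.

        Two modes:

        - grid: ``varied`` maps parameter names to explicit value lists;
          the full cartesian product is simulated (``n`` ignored).
        - random: ``varied`` is a sequence of parameter names; ``n``
          seeded draws multiply each base value by a log-uniform factor
          in ``[1/span, span]``.
        """
        if not varied:
            raise ValueError("empty sweep specification")
        t_end = self.t_end if t_end is None else t_end
        dt = self.dt if dt is None else dt
        base = self.params.as_dict()
        if isinstance(varied, Mapping):
            names = list(varied)
            grids = np.meshgrid(*[np.asarray(varied[k], dtype=float) for k in names],
                                indexing="ij")
            n_rows = grids[0].size
            table = pd.DataFrame({k: np.full(n_rows, v) for k, v in base.items()})
            for name, g in zip(names, grids):
                table[name] = g.ravel()
        else:
            if n is None or n < 1:
                raise ValueError("random sweep requires n >= 1")
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({k: np.full(n, v) for k, v in base.items()})
            for name in varied:
                if name not in base:
                    raise ValueError(f"unknown parameter {name!r}")
                factors = np.exp(rng.uniform(np.log(1.0 / span), np.log(span), n))
                table[name] = base[name] * factors
        return self._simulate_metrics_batch(table, dose, t_end, dt)

    def transcription_doubling(
        self,
        dose: float = DEFAULT_DOSE,
        t_end: float | None = None,
        dt: float | None = None,
    ) -> dict:
        """Fractional change in tau_kd and t_kd when transcription doubles.

        Both runs start from the SAME baseline steady state (computed
        with the original k9); the doubled k9 applies from t=0, modeling
        upregulation during dsRNA exposure.  Metrics are None when the
        threshold is never crossed.
        """
        t_end = self.t_end if t_end is None else t_end
        dt = self.dt if dt is None else dt
        init = baseline_steady_state(self.params)
        base_traj = self.simulate(dose, t_end, dt, initial=init)
        doubled = DynamicsModel(self.params.replace(k9=2 * self.params.k9), dt, t_end)
        doubled_traj = doubled.simulate(dose, t_end, dt, initial=init)
        mb = knockdown_metrics(base_traj)
        md = knockdown_metrics(doubled_traj)

        def frac(a, b):
            if a is None or b is None or a == 0:
                return None
            return (b - a) / a

        return {
            "base": mb,
            "doubled": md,
            "tau_kd_change": 0.0 if self.params.k9 == 0 else frac(mb.tau_kd, md.tau_kd),
            "t_kd_change": 0.0 if self.params.k9 == 0 else frac(mb.t_kd, md.t_kd),
        }

    def turnover_experiment(
        self,
        m_star: float = 100.0,
        t_m_values: Iterable[float] = (0.0, 0.05, 0.5),
        dose: float = 10.0,
        t_end: float | None = None,
        dt: float | None = None,
    ) -> pd.DataFrame:
        """Knockdown of genes with equal steady-state mRNA but different turnover.

        Post-transcriptional mode: pUG production is switched off
        (k3 = 0) so silencing acts only through 1° siRNA binding.  For
        each turnover rate, transcription is rescaled so the baseline
        mRNA equals ``m_star`` (k9 = m_star*t_m*(k7+t_p)/k7); for
        t_m = 0, k9 = 0 and mRNA starts at ``m_star``.
        """
        if m_star <= 0:
            raise ValueError(f"m_star must be > 0, got {m_star}")
        t_end = self.t_end if t_end is None else t_end
        dt = self.dt if dt is None else dt
        rows = []
        for t_m in t_m_values:
            if t_m < 0:
                raise ValueError(f"t_m must be >= 0, got {t_m}")
            if t_m == 0:
                params = self.params.replace(k3=0.0, t_m=0.0, k9=0.0)
                init = RNAState(m=m_star)
            else:
                k9 = m_star * t_m * (self.params.k7 + self.params.t_p) / self.params.k7
                params = self.params.replace(k3=0.0, t_m=t_m, k9=k9)
                init = baseline_steady_state(params)
            traj = DynamicsModel(params, dt, t_end).simulate(dose, t_end, dt, initial=init)
            rows.append({
                "t_m": t_m,
                "k9": params.k9,
                "m_min": float(traj.species("m").min()),
                "trajectory": traj,
            })
        return pd.DataFrame(rows)
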
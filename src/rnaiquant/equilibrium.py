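"""Sequential equilibrium model of RNAi.

Every reaction is assumed to have reached equilibrium, and the stages
complete strictly in sequence:

1. dicing       — the dsRNA dose is fully processed into 1° siRNAs:
                  ``pri = e_dice * dose * l_ds / 22``;
2. recognition  — 1° siRNAs recognize mRNAs; each recognized mRNA is
                  cleaved and converted into one pUG RNA:
                  ``ug = min(e_pri * pri, m)``;
3. amplification— each pUG RNA templates 2° siRNAs:
                  ``sec = amp * ug``;
4. depletion    — 2° siRNAs deplete the remaining mRNA and the pre-mRNA
                  pools with efficiencies ``e_sec_m`` and ``e_sec_p``:
                  ``m_i = max(m - ug - e_sec_m * sec, 0)``,
                  ``p_i = max(p - e_sec_p * sec, 0)``.

Model assumptions: (1) the stages are strictly sequential (1° siRNAs,
then pUG RNAs, then 2° siRNAs); (2) no 3° siRNAs; (3) no recycling of
full-length mRNA or pre-mRNA after small RNA binding, so consumption is
irreversible and residuals clamp at zero; (4) no other turnover of the
species considered on this timescale.

A parameter set "knocks down while remaining viable" when the residual
mRNA satisfies ``0 < m_i < m`` with ``p_i > 0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: Default uniform sampling ranges for :func:`sample_equilibrium`.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "dose": (0.0, 10.0),
    "e_dice": (0.0, 1.0),
    "e_pri": (0.0, 1.0),
    "amp": (0.0, 100.0),
    "e_sec_m": (0.0, 1.0),
    "e_sec_p": (0.0, 1.0),
}


@dataclass(frozen=True)
class EquilibriumParameters:
    """Initial pools, dose, and per-stage efficiencies."""

    m: float = 100.0       # initial mRNA pool
    p: float = 50.0        # initial pre-mRNA pool
    dose: float = 1.0      # dsRNA molecules added
    l_ds: float = 100.0    # trigger length (nt); dose yields dose*l_ds/22 1° siRNAs
    e_dice: float = 1.0    # dicing efficiency
    e_pri: float = 0.5     # mRNAs recognized (and converted to pUG) per 1° siRNA
    amp: float = 10.0      # 2° siRNAs per pUG template
    e_sec_m: float = 0.5   # mRNAs depleted per 2° siRNA
    e_sec_p: float = 0.5   # pre-mRNAs depleted per 2° siRNA

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if self.m <= 0 or self.p <= 0:
            raise ValueError("initial pools m and p must be > 0")
        if self.l_ds <= 0:
            raise ValueError("l_ds must be > 0")


@dataclass(frozen=True)
class EquilibriumOutcome:
    """Residual pools after the sequential stages."""

    m_initial: float
    p_initial: float
    m_i: float
    p_i: float

    @property
    def knocked_down(self) -> bool:
        return self.m_i < self.m_initial

    @property
    def viable(self) -> bool:
        return self.m_i > 0 and self.p_i > 0


def solve_equilibrium(params: EquilibriumParameters) -> EquilibriumOutcome:
    """Evaluate the four sequential stages once each."""
    pri = params.e_dice * params.dose * params.l_ds / 22.0
    ug = min(params.e_pri * pri, params.m)
    sec = params.amp * ug
    m_i = max(params.m - ug - params.e_sec_m * sec, 0.0)
    p_i = max(params.p - params.e_sec_p * sec, 0.0)
    return EquilibriumOutcome(params.m, params.p, m_i, p_i)


def classify(outcome: EquilibriumOutcome) -> bool:
    """True iff knocked down AND viable: 0 < m_i < m and p_i > 0."""
    return outcome.knocked_down and outcome.viable


def _solve_batch(table: pd.DataFrame, m0: float, p0: float, l_ds: float):
    """Vectorized stage evaluation; must mirror :func:`solve_equilibrium`."""
    pri = table["e_dice"].to_numpy() * table["dose"].to_numpy() * l_ds / 22.0
    ug = np.minimum(table["e_pri"].to_numpy() * pri, m0)
    sec = table["amp"].to_numpy() * ug
    m_i = np.maximum(m0 - ug - table["e_sec_m"].to_numpy() * sec, 0.0)
    p_i = np.maximum(p0 - table["e_sec_p"].to_numpy() * sec, 0.0)
    return m_i, p_i


def sample_equilibrium(
    n: int,
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    m: float = 100.0,
    p: float = 50.0,
    l_ds: float = 100.0,
) -> tuple[int, pd.DataFrame]:
    """Seeded uniform draws; returns (count accepted, accepted table).

    A draw is accepted when its outcome classifies as knocked down and
    viable.  The accepted table carries the sampled parameters plus the
    residuals ``m_i`` and ``p_i``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    use = dict(DEFAULT_RANGES)
    if ranges:
        use.update(ranges)
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in use.items()}
    )
    m_i, p_i = _solve_batch(table, m, p, l_ds)
    accepted_mask = (m_i < m) & (m_i > 0) & (p_i > 0)
    accepted = table[accepted_mask].reset_index(drop=True).copy()
    accepted["m_i"] = m_i[accepted_mask]
    accepted["p_i"] = p_i[accepted_mask]
    return int(accepted_mask.sum()), accepted


class EquilibriumModel:
    """Sequential equilibrium model with fixed pools and sampling ranges."""

    def __init__(
        self,
        m: float = 100.0,
        p: float = 50.0,
        l_ds: float = 100.0,
        ranges: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        self.m = m
        self.p = p
        self.l_ds = l_ds
        self.ranges = dict(DEFAULT_RANGES)
        if ranges:
            self.ranges.update(ranges)

    def solve(self, **efficiencies) -> EquilibriumOutcome:
        params = EquilibriumParameters(m=self.m, p=self.p, l_ds=self.l_ds, **efficiencies)
        return solve_equilibrium(params)

    def sample(self, n: int, seed: int = 0) -> "EquilibriumResults":
        count, accepted = sample_equilibrium(
            n, seed, self.ranges, self.m, self.p, self.l_ds
        )
        return EquilibriumResults(self, n, seed, count, accepted)


class EquilibriumResults:
    """Accepted parameter sets from one sampling run."""

    def __init__(self, model, n, seed, n_accepted, accepted: pd.DataFrame) -> None:
        self.model = model
        self.n_sampled = n
        self.seed = seed
        self.n_accepted = n_accepted
        self.accepted = accepted

    def summary(self) -> str:
        lines = [
            "Sequential equilibrium sampling",
            "-------------------------------",
            f"sampled parameter sets : {self.n_sampled}",
            f"knocked down & viable  : {self.n_accepted}"
            f" ({100 * self.n_accepted / self.n_sampled:.4f}%)",
            f"seed                   : {self.seed}",
        ]
        if self.n_accepted:
            resid = self.accepted["m_i"] / self.model.m
            ratio = (self.accepted["p_i"] / self.accepted["m_i"])
            lines += [
                f"residual mRNA fraction : [{resid.min():.4f}, {resid.max():.4f}]",
                f"pre-mRNA/mRNA ratio    : [{ratio.min():.3f}, {ratio.max():.3f}]"
                f" (baseline {self.model.p / self.model.m:.3f})",
            ]
        return "\n".join(lines)

    def run_summary(self) -> dict:
        return {
            "n_sampled": self.n_sampled,
            "n_accepted": self.n_accepted,
            "seed": self.seed,
            "m": self.model.m,
            "p": self.model.p,
            "l_ds": self.model.l_ds,
            "ranges": {k: list(v) for k, v in self.model.ranges.items()},
        }
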
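"""Intersecting-network model of gene-specific RNAi requirements.

After primary siRNA processing, silencing signal reaches the target
through four paths defined by which amplification factor (MUT-16 or
RDE-10) and which downstream Argonaute (NRDE-3 or another Argonaute)
carry it:

====  ==========  =================
path  amplifier   Argonaute
====  ==========  =================
Nm    MUT-16      NRDE-3
Nr    RDE-10      NRDE-3
Om    MUT-16      other Argonautes
Or    RDE-10      other Argonautes
====  ==========  =================

A genotype silences a target when the summed contribution of its intact
paths reaches the target's threshold.  The two exemplar targets differ
only in threshold: *unc-22* is sensitive (low threshold, fixed at 1 as
the gauge) while *bli-1* needs more signal (threshold = sampled ratio).
``NetworkModel.fit`` draws path contributions and threshold ratios
uniformly at random and keeps the sets consistent with the observed
genotype-phenotype table (wild type silences both targets, each single
mutant silences only *unc-22*, each double mutant silences neither).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGULATORS = frozenset({"MUT-16", "RDE-10", "NRDE-3", "OTHER_AGO"})

#: (path name, required amplifier, required Argonaute)
PATHS = (
    ("nm", "MUT-16", "NRDE-3"),
    ("nr", "RDE-10", "NRDE-3"),
    ("om", "MUT-16", "OTHER_AGO"),
    ("or_", "RDE-10", "OTHER_AGO"),
)


@dataclass(frozen=True)
class PathContributions:
    """Nonnegative weights of the four silencing paths."""

    nm: float
    nr: float
    om: float
    or_: float

    def __post_init__(self) -> None:
        for name in ("nm", "nr", "om", "or_"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"path contribution {name} must be finite and >= 0, got {v}")

    def total(self) -> float:
        return self.nm + self.nr + self.om + self.or_


@dataclass(frozen=True)
class Thresholds:
    """Gene-specific silencing thresholds.

    ``t_unc`` is the level of signal needed to produce a detectable
    *unc-22* defect (the gauge, 1 by default), ``t_bli`` the level for
    *bli-1*; ``ratio`` is ``t_bli / t_unc``.
    """

    t_unc: float
    t_bli: float

    def __post_init__(self) -> None:
        if self.t_unc <= 0:
            raise ValueError(f"t_unc must be > 0, got {self.t_unc}")
        if self.t_bli < 0:
            raise ValueError(f"t_bli must be >= 0, got {self.t_bli}")

    @property
    def ratio(self) -> float:
        return self.t_bli / self.t_unc

    def for_target(self, target: str) -> float:
        if target == "unc-22":
            return self.t_unc
        if target == "bli-1":
            return self.t_bli
        raise ValueError(f"unknown target {target!r}")


@dataclass(frozen=True)
class Genotype:
    """Set of functional regulators; OTHER_AGO is never mutated."""

    functional_regulators: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.functional_regulators) - REGULATORS
        if unknown:
            raise ValueError(f"unknown regulator(s): {sorted(unknown)}")
        if "OTHER_AGO" not in self.functional_regulators:
            raise ValueError("no mutant removing all other Argonautes is modeled; "
                             "OTHER_AGO must be functional")

    @classmethod
    def from_mutations(cls, *mutated: str) -> "Genotype":
        functional = frozenset(REGULATORS - set(mutated))
        name = " ".join(f"{m.lower()}(-)" for m in sorted(mutated)) or "wild type"
        return cls(functional, name)


#: The seven genotypes of the observed silencing table.
WILD_TYPE = Genotype.from_mutations()
GENOTYPES: tuple[Genotype, ...] = (
    WILD_TYPE,
    Genotype.from_mutations("MUT-16"),
    Genotype.from_mutations("RDE-10"),
    Genotype.from_mutations("NRDE-3"),
    Genotype.from_mutations("MUT-16", "RDE-10"),
    Genotype.from_mutations("MUT-16", "NRDE-3"),
    Genotype.from_mutations("RDE-10", "NRDE-3"),
)


@dataclass(frozen=True)
class ConstraintRow:
    genotype: Genotype
    target: str  # "bli-1" or "unc-22"
    expected_silenced: bool


@dataclass
class ConstraintTable:
    """Genotype x target silencing expectations used to cull parameter sets.

    The default table encodes the observed responses: wild type silences
    both targets, every single mutant silences *unc-22* but not *bli-1*,
    and every double mutant silences neither.  The wild-type *unc-22* row
    is implied by the single-mutant rows but kept for auditability.
    """

    rows: list[ConstraintRow] = field(default_factory=list)

    @classmethod
    def default(cls) -> "ConstraintTable":
        rows = []
        for g in GENOTYPES:
            n_mut = len(REGULATORS - g.functional_regulators)
            for target in ("bli-1", "unc-22"):
                if n_mut == 0:
                    expected = True
                elif n_mut == 1:
                    expected = target == "unc-22"
                else:
                    expected = False
                rows.append(ConstraintRow(g, target, expected))
        return cls(rows)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def silencing_signal(genotype: Genotype, contributions: PathContributions) -> float:
    """Summed weight of the paths whose two required regulators are intact."""
    functional = genotype.functional_regulators
    signal = 0.0
    for name, amplifier, argonaute in PATHS:
        if amplifier in functional and argonaute in functional:
            signal += getattr(contributions, name)
    return signal


def predict_silenced(signal: float, threshold: float) -> bool:
    """A target is silenced when the signal reaches its threshold.

    The boundary (signal exactly equal to the threshold) counts as
    silenced; under continuous sampling this is a measure-zero choice.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return signal >= threshold


def satisfies_constraints(
    contributions: PathContributions,
    thresholds: Thresholds,
    table: ConstraintTable | None = None,
) -> bool:
    """True iff the parameter set reproduces every observed response."""
    if table is None:
        table = ConstraintTable.default()
    for row in table:
        signal = silencing_signal(row.genotype, contributions)
        if predict_silenced(signal, thresholds.for_target(row.target)) != row.expected_silenced:
            return False
    return True


def _signals_matrix(nm, nr, om, or_):
    """Silencing signal of each of the seven genotypes, vectorized.

    Column order follows :data:`GENOTYPES`.
    """
    zeros = np.zeros_like(nm)
    return np.stack(
        [
            nm + nr + om + or_,  # wild type
            nr + or_,            # mut-16(-)
            nm + om,             # rde-10(-)
            om + or_,            # nrde-3(-)
            zeros,               # mut-16(-) rde-10(-)
            or_,                 # mut-16(-) nrde-3(-)
            om,                  # rde-10(-) nrde-3(-)
        ],
        axis=0,
    )


@dataclass
class SamplerResult:
    """Outcome of one Monte Carlo culling run."""

    n_sampled: int
    accepted: pd.DataFrame  # columns nm, nr, om, or_, ratio
    seed: int
    weight_range: tuple[float, float]
    ratio_range: tuple[float, float]
    t_unc: float

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def max_ratio(self) -> float | None:
        if self.accepted.empty:
            return None
        return float(self.accepted["ratio"].max())


def sample_parameter_sets(
    n: int,
    seed: int,
    weight_range: tuple[float, float] = (0.0, 2.0),
    ratio_range: tuple[float, float] = (0.0, 100.0),
    table: ConstraintTable | None = None,
    t_unc: float = 1.0,
) -> SamplerResult:
    """Draw ``n`` uniform parameter sets and keep those satisfying the table.

    The four path contributions are drawn from ``weight_range`` and the
    threshold ratio from ``ratio_range``; ``t_unc`` is the fixed gauge so
    ``t_bli = ratio * t_unc``.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if weight_range[1] < weight_range[0] or ratio_range[1] < ratio_range[0]:
        raise ValueError("empty sampling range")
    rng = np.random.default_rng(seed)
    nm, nr, om, or_ = rng.uniform(weight_range[0], weight_range[1], size=(4, n))
    ratio = rng.uniform(ratio_range[0], ratio_range[1], size=n)

    if table is None or _is_default_table(table):
        accepted_mask = _accept_default(nm, nr, om, or_, ratio, t_unc)
    else:
        accepted_mask = np.fromiter(
            (
                satisfies_constraints(
                    PathContributions(nm[i], nr[i], om[i], or_[i]),
                    Thresholds(t_unc, ratio[i] * t_unc),
                    table,
                )
                for i in range(n)
            ),
            dtype=bool,
            count=n,
        )

    accepted = pd.DataFrame(
        {
            "nm": nm[accepted_mask],
            "nr": nr[accepted_mask],
            "om": om[accepted_mask],
            "or_": or_[accepted_mask],
            "ratio": ratio[accepted_mask],
        }
    ).reset_index(drop=True)
    return SamplerResult(n, accepted, seed, tuple(weight_range), tuple(ratio_range), t_unc)


def _is_default_table(table: ConstraintTable) -> bool:
    default = ConstraintTable.default()
    if len(table) != len(default):
        return False
    key = lambda r: (r.genotype.functional_regulators, r.target, r.expected_silenced)
    return sorted(map(key, table.rows)) == sorted(map(key, default.rows))


def _accept_default(nm, nr, om, or_, ratio, t_unc):
    """Vectorized accept/reject for the default constraint table."""
    t_bli = ratio * t_unc
    signals = _signals_matrix(nm, nr, om, or_)
    wt, s_m16, s_r10, s_n3, d_mr, d_mn, d_rn = signals
    ok = (wt >= t_bli) & (wt >= t_unc)
    for s in (s_m16, s_r10, s_n3):
        ok &= (s >= t_unc) & (s < t_bli)
    for d in (d_mr, d_mn, d_rn):
        ok &= (d < t_unc) & (d < t_bli)
    return ok


def summarize_accepted(result: SamplerResult) -> pd.DataFrame:
    """Per-set summary of accepted parameter sets.

    Adds the MUT-16-requiring fraction ``(nm+om)/total`` and the
    NRDE-3-requiring fraction ``(nm+nr)/total`` of the silencing signal.
    Empty input yields an empty frame.
    """
    acc = result.accepted
    if acc.empty:
        return pd.DataFrame(
            columns=["nm", "nr", "om", "or_", "ratio", "mut16_fraction", "nrde3_fraction"]
        )
    total = acc[["nm", "nr", "om", "or_"]].sum(axis=1)
    out = acc.copy()
    out["mut16_fraction"] = (acc["nm"] + acc["om"]) / total
    out["nrde3_fraction"] = (acc["nm"] + acc["nr"]) / total
    return out


class NetworkModel:
    """Intersecting-network model constrained by a phenotype table.

    Parameters
    ----------
    table : ConstraintTable, optional
        Genotype x target silencing expectations; defaults to the
        observed *bli-1* / *unc-22* responses of the seven genotypes.
    weight_range, ratio_range : tuple of float
        Uniform sampling ranges for path contributions and threshold ratio.
    t_unc : float
        Gauge for the *unc-22* threshold.
    """

    def __init__(
        self,
        table: ConstraintTable | None = None,
        weight_range: tuple[float, float] = (0.0, 2.0),
        ratio_range: tuple[float, float] = (0.0, 100.0),
        t_unc: float = 1.0,
    ) -> None:
        self.table = table if table is not None else ConstraintTable.default()
        self.weight_range = tuple(weight_range)
        self.ratio_range = tuple(ratio_range)
        self.t_unc = t_unc

    def fit(self, n: int = 100_000, seed: int = 0) -> "NetworkResults":
        """Monte Carlo culling: sample ``n`` sets, keep the consistent ones."""
        result = sample_parameter_sets(
            n, seed, self.weight_range, self.ratio_range, self.table, self.t_unc
        )
        return NetworkResults(self, result)

    def enumerate_grid(
        self,
        weights: Sequence[float],
        ratios: Sequence[float],
    ) -> pd.DataFrame:
        """Exhaustive accept/reject over a coarse grid (brute-force check)."""
        grids = np.meshgrid(weights, weights, weights, weights, ratios, indexing="ij")
        nm, nr, om, or_ = (g.ravel().astype(float) for g in grids[:4])
        ratio = grids[4].ravel().astype(float)
        accepted = _accept_default(nm, nr, om, or_, ratio, self.t_unc)
        return pd.DataFrame(
            {"nm": nm, "nr": nr, "om": om, "or_": or_, "ratio": ratio, "accepted": accepted}
        )


class NetworkResults:
    """Accepted parameter sets with summary statistics."""

    def __init__(self, model: NetworkModel, result: SamplerResult) -> None:
        self.model = model
        self.result = result
        self.accepted = summarize_accepted(result)

    @property
    def n_sampled(self) -> int:
        return self.result.n_sampled

    @property
    def n_accepted(self) -> int:
        return self.result.n_accepted

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / self.n_sampled

    @property
    def max_ratio(self) -> float | None:
        return self.result.max_ratio

    def summary(self) -> str:
        lines = [
            "Intersecting-network constraint sampling",
            "----------------------------------------",
            f"sampled parameter sets : {self.n_sampled}",
            f"accepted               : {self.n_accepted}"
            f" ({100 * self.acceptance_fraction:.3f}%)",
            f"seed                   : {self.result.seed}",
            f"weight range           : {self.result.weight_range}",
            f"threshold ratio range  : {self.result.ratio_range}",
            f"t_unc gauge            : {self.result.t_unc}",
        ]
        if self.n_accepted:
            acc = self.accepted
            lines += [
                f"max accepted ratio     : {self.max_ratio:.3f}",
                f"MUT-16 fraction        : {acc['mut16_fraction'].mean():.3f}"
                f" (mean), [{acc['mut16_fraction'].min():.3f},"
                f" {acc['mut16_fraction'].max():.3f}]",
                f"NRDE-3 fraction        : {acc['nrde3_fraction'].mean():.3f}"
                f" (mean), [{acc['nrde3_fraction'].min():.3f},"
                f" {acc['nrde3_fraction'].max():.3f}]",
            ]
        return "\n".join(lines)

    def run_summary(self) -> dict:
        """JSON-serializable run metadata."""
        return {
            "n_sampled": self.n_sampled,
            "n_accepted": self.n_accepted,
            "max_ratio": self.max_ratio,
            "seed": self.result.seed,
            "weight_range": list(self.result.weight_range),
            "ratio_range": list(self.result.ratio_range),
            "t_unc": self.result.t_unc,
        }

    def to_tsv(self, path) -> None:
        self.accepted.to_csv(path, sep="\t", index=False)
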
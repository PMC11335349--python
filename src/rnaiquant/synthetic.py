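"""Seeded synthetic-data generators.

Fixtures with the statistical structure the analyses assume: binomial
fraction-silenced phenotype counts generated from a ground-truth network
parameter set, per-strain snpEff-annotated VCFs with planted
complementation groups over shared background variants, and random
parameter grids for the samplers.  All generators are pure functions of
their configuration and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rnaiquant.dynamics import RateParameters
from rnaiquant.equilibrium import DEFAULT_RANGES as EQ_RANGES
from rnaiquant.network import (
    GENOTYPES,
    ConstraintTable,
    PathContributions,
    Thresholds,
    predict_silenced,
    silencing_signal,
)
from rnaiquant.stats import SilencingCounts


@dataclass
class GroundTruth:
    """Generation truth shared by the phenotype and variant fixtures."""

    contributions: PathContributions = field(
        default_factory=lambda: PathContributions(1.2, 1.1, 0.8, 0.7)
    )
    thresholds: Thresholds = field(default_factory=lambda: Thresholds(1.0, 3.5))
    planted_groups: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def predicted_silenced(self) -> dict[tuple[str, str], bool]:
        """Truth table: genotype x target -> silenced."""
        out = {}
        for g in GENOTYPES:
            signal = silencing_signal(g, self.contributions)
            for target in ("bli-1", "unc-22"):
                out[(g.name, target)] = predict_silenced(
                    signal, self.thresholds.for_target(target)
                )
        return out


def make_phenotype_counts(
    truth: GroundTruth,
    n_per_group: int = 200,
    noise: float = 0.05,
    seed: int | None = None,
    noise_false_silenced: float | None = None,
) -> list[SilencingCounts]:
    """Binomial fraction-silenced counts for the seven genotypes x two targets.

    Silenced counts are drawn from Binomial(n, 1 - noise) where the
    truth predicts silencing and Binomial(n, noise) where it does not.
    ``noise_false_silenced`` makes the two error rates asymmetric.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    if not 0 <= noise < 0.5:
        raise ValueError(f"noise must be in [0, 0.5), got {noise}")
    fp = noise if noise_false_silenced is None else noise_false_silenced
    if not 0 <= fp < 0.5:
        raise ValueError(f"noise_false_silenced must be in [0, 0.5), got {fp}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for (genotype, target), silenced in truth.predicted_silenced().items():
        p = 1.0 - noise if silenced else fp
        x = int(rng.binomial(n_per_group, p))
        rows.append(SilencingCounts(genotype, target, n_per_group, x))
    return rows


# ---------------------------------------------------------------------------
# variant fixtures

_CHROMS = ("I", "II", "III", "IV", "V", "X")
_CHROM_LEN = 15_000_000
_BASES = ("A", "C", "G", "T")

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
    "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
    "Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | "
    "cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | "
    "Distance | ERRORS / WARNINGS / INFO'\">\n"
    + "".join(f"##contig=<ID={c},length={_CHROM_LEN}>\n" for c in _CHROMS)
    + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)

_EFFECT_BY_IMPACT = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intron_variant",
}


def _ann(alt: str, gene: str, impact: str) -> str:
    effect = _EFFECT_BY_IMPACT[impact]
    return (
        f"{alt}|{effect}|{impact}|{gene}|{gene}.1|transcript|{gene}.1.1|"
        f"protein_coding|1/5|c.100A>T|p.Lys34*|100/1500|100/1200|34/400||"
    )


def make_variant_fixtures(
    out_dir,
    n_strains: int = 5,
    n_shared: int = 10,
    planted: Mapping[str, Sequence[str]] | None = None,
    n_decoys: int = 5,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one snpEff-style annotated VCF per strain.

    Each strain carries: ``n_shared`` background variants identical
    across all strains (mixed impacts), one strain-unique HIGH or
    MODERATE variant per planted gene at a site distinct from every
    other strain's, and ``n_decoys`` strain-unique LOW/MODIFIER decoys.
    Positions are drawn without replacement per chromosome so planted
    sites never collide.  Returns strain -> path.
    """
    planted = dict(planted or {})
    strains = [f"strain{i + 1:02d}" for i in range(n_strains)]
    for gene, gene_strains in planted.items():
        if len(gene_strains) < 1:
            raise ValueError(f"planted gene {gene!r} must map to at least one strain")
        unknown = set(gene_strains) - set(strains)
        if unknown:
            raise ValueError(f"planted gene {gene!r} names unknown strain(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # distinct positions per chromosome across the whole fixture
    n_sites = n_shared + sum(len(s) for s in planted.values()) + n_decoys * n_strains
    chrom_of = rng.choice(len(_CHROMS), size=n_sites)
    pos_pool: dict[int, np.ndarray] = {}
    for ci in range(len(_CHROMS)):
        count = int((chrom_of == ci).sum())
        pos_pool[ci] = rng.choice(
            np.arange(1, _CHROM_LEN, dtype=np.int64), size=count, replace=False
        )
    cursors = {ci: 0 for ci in pos_pool}

    def next_site() -> tuple[str, int]:
        ci = int(chrom_of[next_site.idx])
        next_site.idx += 1
        pos = int(pos_pool[ci][cursors[ci]])
        cursors[ci] += 1
        return _CHROMS[ci], pos

    next_site.idx = 0

    def draw_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(4, size=2, replace=False)
        return _BASES[ref], _BASES[alt]

    variants: dict[str, list[tuple[str, int, str, str, str, str]]] = {s: [] for s in strains}

    impacts = ("HIGH", "MODERATE", "LOW", "MODIFIER")
    for i in range(n_shared):
        chrom, pos = next_site()
        ref, alt = draw_alleles()
        impact = impacts[int(rng.integers(len(impacts)))]
        gene = f"bg-{i + 1}"
        for s in strains:
            variants[s].append((chrom, pos, ref, alt, gene, impact))

    for gene in sorted(planted):
        for s in planted[gene]:
            chrom, pos = next_site()
            ref, alt = draw_alleles()
            impact = "HIGH" if rng.random() < 0.5 else "MODERATE"
            variants[s].append((chrom, pos, ref, alt, gene, impact))

    for s in strains:
        for j in range(n_decoys):
            chrom, pos = next_site()
            ref, alt = draw_alleles()
            impact = "LOW" if rng.random() < 0.5 else "MODIFIER"
            variants[s].append((chrom, pos, ref, alt, f"decoy-{s}-{j + 1}", impact))

    paths = {}
    order = {c: i for i, c in enumerate(_CHROMS)}
    for s in strains:
        path = out_dir / f"{s}.vcf"
        lines = [_VCF_HEADER]
        for chrom, pos, ref, alt, gene, impact in sorted(
            variants[s], key=lambda v: (order[v[0]], v[1])
        ):
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\tANN={_ann(alt, gene, impact)}\n"
            )
        path.write_text("".join(lines))
        paths[s] = path
    return paths


# ---------------------------------------------------------------------------
# parameter grids

#: Default uniform ranges for random dynamics parameter tables.
DYNAMICS_RANGES: dict[str, tuple[float, float]] = {
    f.name: (0.5 * f.default, 1.5 * f.default)
    for f in dataclasses.fields(RateParameters)
    if f.default > 0
}


def make_parameter_grid(
    model: str,
    n: int,
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    weight_range: tuple[float, float] = (0.0, 2.0),
    ratio_range: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Seeded uniform parameter draws in a sampler-compatible layout.

    ``model`` is one of ``network``, ``equilibrium``, ``dynamics``.  The
    network layout reproduces, draw for draw, the internal sampling of
    :func:`rnaiquant.network.sample_parameter_sets` at the same seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if model == "network":
        nm, nr, om, or_ = rng.uniform(weight_range[0], weight_range[1], size=(4, n))
        ratio = rng.uniform(ratio_range[0], ratio_range[1], size=n)
        return pd.DataFrame({"nm": nm, "nr": nr, "om": om, "or_": or_, "ratio": ratio})
    if model == "equilibrium":
        use = dict(EQ_RANGES)
        if ranges:
            use.update(ranges)
        return pd.DataFrame(
            {name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in use.items()}
        )
    if model == "dynamics":
        use = dict(DYNAMICS_RANGES)
        if ranges:
            use.update(ranges)
        table = {}
        for f in dataclasses.fields(RateParameters):
            if f.name in use:
                lo, hi = use[f.name]
                table[f.name] = rng.uniform(lo, hi, size=n)
            else:
                table[f.name] = np.full(n, f.default)
        return pd.DataFrame(table)
    raise ValueError(f"unknown model {model!r}; expected network, equilibrium, or dynamics")
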
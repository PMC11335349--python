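"""In silico complementation of mutagenized strains.

After whole-genome sequencing of strains from a mutagenesis screen,
variants annotated HIGH or MODERATE impact that are unique to one strain
are the candidate causal mutations; strains carrying *different*
mutations in the *same* gene form a complementation group — the
computational analogue of a genetic complementation test.

Pipeline: :func:`load_annotated_variants` (snpEff-annotated VCF per
strain) -> :func:`cull_strain_specific` (impact filter + drop variants
shared by two or more strains) -> :func:`complementation_groups`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
DEFAULT_IMPACTS = frozenset({"HIGH", "MODERATE"})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant in one strain (VCF coordinates, 1-based)."""

    strain: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    impact: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.impact not in IMPACTS:
            raise ValueError(f"impact must be one of {IMPACTS}, got {self.impact!r}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        """Variant identity used for the 'shared between strains' test."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ComplementationGroup:
    """Gene hit by distinct variants in two or more strains."""

    gene: str
    strains: frozenset[str]
    variants: tuple[VariantRecord, ...]


def load_annotated_variants(path, strain: str | None = None) -> list[VariantRecord]:
    """Read a snpEff-annotated VCF into variant records.

    One record per variant and alternate allele; gene and impact come
    from the first ANN entry matching the allele (first ANN entry
    overall as a fallback).  Records lacking a parseable ANN field are
    skipped with a logged warning.  ``strain`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    strain = strain if strain is not None else path.stem
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"not a readable VCF: {path}") from exc
    with vcf:
        for rec in vcf:
            ann = rec.info.get("ANN")
            if ann is None:
                logger.warning("variant %s:%s has no ANN field; skipped", rec.chrom, rec.pos)
                continue
            entries = [a.split("|") for a in ann]
            for alt in rec.alts or ():
                match = next(
                    (e for e in entries if e and e[0] == alt),
                    entries[0] if entries else None,
                )
                if match is None or len(match) < 4:
                    logger.warning(
                        "variant %s:%s has malformed ANN entry; skipped", rec.chrom, rec.pos
                    )
                    continue
                impact, gene = match[2], match[3]
                if impact not in IMPACTS:
                    logger.warning(
                        "variant %s:%s has unknown impact %r; skipped",
                        rec.chrom, rec.pos, impact,
                    )
                    continue
                records.append(
                    VariantRecord(strain, rec.chrom, rec.pos, rec.ref, alt, gene, impact)
                )
    return records


def cull_strain_specific(
    records: Mapping[str, Iterable[VariantRecord]],
    impacts: frozenset[str] | set[str] = DEFAULT_IMPACTS,
) -> dict[str, list[VariantRecord]]:
    """Keep deleterious variants unique to a single strain.

    A variant passes when its impact is in ``impacts`` (HIGH/MODERATE by
    default) and its site (chrom, pos, ref, alt) occurs in exactly one
    strain; sites in two or more strains are pre-existing background,
    not new mutations from mutagenesis, and are removed everywhere.
    """
    if not records:
        raise ValueError("at least one strain is required")
    impacts = frozenset(impacts)
    per_strain = {s: list(v) for s, v in records.items()}
    site_strains: dict[tuple, set[str]] = {}
    for strain, recs in per_strain.items():
        for r in recs:
            site_strains.setdefault(r.site, set()).add(strain)
    return {
        strain: [
            r for r in recs
            if r.impact in impacts and len(site_strains[r.site]) == 1
        ]
        for strain, recs in per_strain.items()
    }


def complementation_groups(
    culled: Mapping[str, Iterable[VariantRecord]],
) -> list[ComplementationGroup]:
    """Group strains whose surviving variants hit the same gene.

    Only genes mutated in two or more strains form groups; output is
    sorted by decreasing group size, then gene label, and is independent
    of strain input order.
    """
    gene_hits: dict[str, dict[str, list[VariantRecord]]] = {}
    for strain in sorted(culled):
        for r in culled[strain]:
            gene_hits.setdefault(r.gene, {}).setdefault(strain, []).append(r)
    groups = [
        ComplementationGroup(
            gene=gene,
            strains=frozenset(strains),
            variants=tuple(
                v for s in sorted(strains) for v in sorted(strains[s], key=lambda r: r.site)
            ),
        )
        for gene, strains in gene_hits.items()
        if len(strains) >= 2
    ]
    groups.sort(key=lambda g: (-len(g.strains), g.gene))
    return groups


def run_pipeline(
    vcf_paths: Mapping[str, "Path | str"],
    impacts: frozenset[str] | set[str] = DEFAULT_IMPACTS,
) -> list[ComplementationGroup]:
    """Full pipeline from per-strain VCF paths to complementation groups."""
    records = {s: load_annotated_variants(p, strain=s) for s, p in vcf_paths.items()}
    return complementation_groups(cull_strain_specific(records, impacts))


def groups_to_frame(groups: Iterable[ComplementationGroup]) -> pd.DataFrame:
    """Flatten groups to a TSV-ready table."""
    rows = [
        {
            "gene": g.gene,
            "strain": v.strain,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "impact": v.impact,
        }
        for g in groups
        for v in g.variants
    ]
    return pd.DataFrame(rows, columns=["gene", "strain", "chrom", "pos", "ref", "alt", "impact"])
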
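"""Cross-family recurrence, cosegregation classification, brain expression.

Genes hit by candidate variants in at least ``min_families`` independent
families are aggregated into :class:`GeneReport` records.  Extended
carrier counts over all DNA-available relatives (BD-affected, other
psychiatric, unaffected) classify each gene's variants as showing full or
nearly full cosegregation (HIGH) or not (LOW).  The classification rule
formalizes a qualitative reading: a gene is HIGH when, in every family, at
most one BD-affected DNA-available member is a non-carrier and at most one
unaffected member carries; two or more unaffected carriers in any single
family ("several") demote the gene to LOW.  Other-psychiatric carriers are
neutral.  Both tolerances are exposed as parameters.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from famvarseg.core_io import BD_PHENOTYPES, BRAIN_REGIONS, Pedigree

__all__ = [
    "SegregationSummary",
    "GeneReport",
    "recurrence",
    "classify_penetrance",
    "classify_all",
    "brain_expression_flag",
    "summaries_from_genotypes",
    "attach_classification",
]


@dataclass(frozen=True)
class SegregationSummary:
    """Carrier counts for one variant in one family.

    The totals count individuals with available DNA in each phenotype
    category; carriers count those who harbor the variant.
    """

    gene: str
    family_id: str
    label: str
    bd_carriers: int
    bd_total: int
    psy_carriers: int
    psy_total: int
    unaff_carriers: int
    unaff_total: int
    penetrance_class: str | None = None

    def __post_init__(self) -> None:
        for car, tot, name in (
            (self.bd_carriers, self.bd_total, "bd"),
            (self.psy_carriers, self.psy_total, "psy"),
            (self.unaff_carriers, self.unaff_total, "unaffected"),
        ):
            if tot < 0 or not 0 <= car <= tot:
                raise ValueError(
                    f"{self.gene} {self.family_id}: {name} carriers {car} "
                    f"inconsistent with total {tot}"
                )


@dataclass(frozen=True)
class GeneReport:
    """A gene with candidate variants in >= min_families independent families."""

    gene: str
    families: tuple[str, ...]
    n_variants: int
    variant_level_recurrent: bool
    brain_expressed: bool | None = None
    penetrance_class: str | None = None


def recurrence(candidates: Iterable, min_families: int = 2) -> list[GeneReport]:
    """Aggregate per-family candidates into recurrent-gene reports.

    ``candidates`` may be any records exposing ``gene``, ``family_id`` and
    ``label`` (e.g. :class:`famvarseg.filters.CandidateVariant` or the
    bundled fixture records).  A gene is reported iff its candidates span at
    least ``min_families`` distinct families; ``variant_level_recurrent`` is
    true when one identical change recurs in two or more families.  The
    result is sorted by gene symbol and independent of input order.
    """
    by_gene: dict[str, list] = defaultdict(list)
    for c in candidates:
        by_gene[c.gene].append(c)
    reports: list[GeneReport] = []
    for gene in sorted(by_gene):
        group = by_gene[gene]
        families = sorted({c.family_id for c in group})
        if len(families) < min_families:
            continue
        label_families: dict[str, set[str]] = defaultdict(set)
        for c in group:
            label_families[c.label].add(c.family_id)
        reports.append(
            GeneReport(
                gene=gene,
                families=tuple(families),
                n_variants=len({(c.family_id, c.label) for c in group}),
                variant_level_recurrent=any(
                    len(f) >= 2 for f in label_families.values()
                ),
            )
        )
    return reports


def classify_penetrance(
    summaries: Sequence[SegregationSummary],
    max_affected_noncarriers: int = 1,
    max_unaffected_carriers: int = 1,
) -> str:
    """Classify one gene's segregation pattern as ``"HIGH"`` or ``"LOW"``.

    HIGH requires, in every family, ``bd_carriers >= bd_total -
    max_affected_noncarriers`` and ``unaff_carriers <=
    max_unaffected_carriers``.  Other-psychiatric carriers never penalize.
    """
    if not summaries:
        raise ValueError("need at least one segregation summary")
    genes = {s.gene for s in summaries}
    if len(genes) > 1:
        raise ValueError(f"summaries span multiple genes: {sorted(genes)}")
    for s in summaries:
        if s.bd_carriers < s.bd_total - max_affected_noncarriers:
            return "LOW"
        if s.unaff_carriers > max_unaffected_carriers:
            return "LOW"
    return "HIGH"


def classify_all(
    summaries: Iterable[SegregationSummary],
    max_affected_noncarriers: int = 1,
    max_unaffected_carriers: int = 1,
) -> dict[str, str]:
    """Per-gene HIGH/LOW classification over a mixed summary list."""
    by_gene: dict[str, list[SegregationSummary]] = defaultdict(list)
    for s in summaries:
        by_gene[s.gene].append(s)
    return {
        gene: classify_penetrance(
            group, max_affected_noncarriers, max_unaffected_carriers
        )
        for gene, group in sorted(by_gene.items())
    }


def brain_expression_flag(
    gene: str,
    expression: Mapping[str, float],
    threshold: float = 0.5,
    regions: Sequence[str] = BRAIN_REGIONS,
) -> bool:
    """True iff the mean expression over the configured brain regions
    strictly exceeds ``threshold``.

    ``expression`` must contain exactly the configured region set; a missing
    or unexpected region raises ``ValueError`` naming it.
    """
    missing = [r for r in regions if r not in expression]
    if missing:
        raise ValueError(f"gene {gene}: missing expression region {missing[0]!r}")
    extra = sorted(set(expression) - set(regions))
    if extra:
        raise ValueError(f"gene {gene}: unexpected expression region {extra[0]!r}")
    mean = sum(float(expression[r]) for r in regions) / len(regions)
    return mean > threshold


def summaries_from_genotypes(
    pedigrees: Mapping[str, Pedigree] | Sequence[Pedigree],
    genotypes: pd.DataFrame,
) -> list[SegregationSummary]:
    """Build carrier-count summaries from an extended genotype table.

    ``genotypes`` needs columns ``family``, ``gene``, ``label``,
    ``individual`` and ``carrier`` (0/1); rows exist only for DNA-available
    members, so the per-category totals are the row counts.  Individuals with
    unknown phenotype are excluded from all three categories.
    """
    if not isinstance(pedigrees, Mapping):
        pedigrees = {p.family_id: p for p in pedigrees}
    out: list[SegregationSummary] = []
    for (fam, gene, label), group in genotypes.groupby(
        ["family", "gene", "label"], sort=True
    ):
        ped = pedigrees[str(fam)]
        counts = {"bd": [0, 0], "psy": [0, 0], "unaff": [0, 0]}
        for row in group.itertuples(index=False):
            pheno = ped[str(row.individual)].phenotype
            if pheno in BD_PHENOTYPES:
                cat = "bd"
            elif pheno == "OTHER_PSY":
                cat = "psy"
            elif pheno == "UNAFFECTED":
                cat = "unaff"
            else:
                continue
            counts[cat][1] += 1
            counts[cat][0] += int(row.carrier)
        out.append(
            SegregationSummary(
                gene=str(gene),
                family_id=str(fam),
                label=str(label),
                bd_carriers=counts["bd"][0],
                bd_total=counts["bd"][1],
                psy_carriers=counts["psy"][0],
                psy_total=counts["psy"][1],
                unaff_carriers=counts["unaff"][0],
                unaff_total=counts["unaff"][1],
            )
        )
    return out


def attach_classification(
    reports: Sequence[GeneReport],
    classifications: Mapping[str, str],
    brain_flags: Mapping[str, bool] | None = None,
) -> list[GeneReport]:
    """Return reports with penetrance class and brain flags filled in."""
    out = []
    for r in reports:
        out.append(
            replace(
                r,
                penetrance_class=classifications.get(r.gene),
                brain_expressed=None
                if brain_flags is None
                else brain_flags.get(r.gene),
            )
        )
    return out
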
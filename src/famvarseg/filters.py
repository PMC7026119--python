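"""Per-family variant prioritization cascade.

A variant becomes a candidate in a family when

1. every sequenced member carries a heterozygous call passing the
   genotype-quality filter (allele balance within [0.25, 0.75], site depth
   >= 10x),
2. the consequence alters the protein or splicing,
3. the reference-panel minor allele frequency is below 0.1% (variants absent
   from the panel pass), and
4. an in-silico deleteriousness consensus is reached: for substitutions at
   least 3 of the 5 tools (SIFT, PolyPhen-2 HumDiv/HumVar, LRT,
   MutationTaster) call the variant damaging or possibly damaging; for
   InDels at least 1 of 3 tools; stop-gain substitutions require a damaging
   MutationTaster call, irrespective of the other tools.

All filters are conjunctive, so the cascade outcome does not depend on the
order of application.  ``NA``/``U`` calls count as non-damaging votes with
the denominator fixed at the panel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from famvarseg.core_io import (
    INDEL_TOOLS,
    PREDICTION_CALLS,
    PROTEIN_ALTERING,
    SNV_TOOLS,
    AnnotatedVariant,
    Pedigree,
    VariantCall,
)

__all__ = [
    "FilterConfig",
    "CandidateVariant",
    "het_call_filter",
    "consequence_filter",
    "maf_filter",
    "deleteriousness_filter",
    "shared_candidates",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the prioritization cascade.

    Allele-balance bounds are inclusive.  ``depth_in_all_members`` controls
    whether the >= ``min_depth`` coverage requirement applies to every
    sequenced member (default) or only needs to hold in at least one of them.
    """

    ab_min: float = 0.25
    ab_max: float = 0.75
    min_depth: int = 10
    maf_threshold: float = 0.001
    snv_min_damaging_votes: int = 3
    indel_min_damaging_votes: int = 1
    damaging_calls: frozenset[str] = frozenset({"D", "P"})
    depth_in_all_members: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ab_min < self.ab_max <= 1.0:
            raise ValueError("need 0 <= ab_min < ab_max <= 1")
        if self.min_depth < 0 or self.maf_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.damaging_calls <= PREDICTION_CALLS:
            raise ValueError("damaging_calls must be prediction-call symbols")


@dataclass
class CandidateVariant:
    """A variant surviving the full cascade in one family."""

    variant: AnnotatedVariant
    family_id: str
    carrier_samples: frozenset[str]
    filter_trail: tuple[tuple[str, bool], ...] = field(default_factory=tuple)

    @property
    def gene(self) -> str:
        return self.variant.gene

    @property
    def label(self) -> str:
        return self.variant.label

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.filter_trail)


def het_call_filter(call: VariantCall, config: FilterConfig = FilterConfig()) -> bool:
    """Heterozygous genotype-quality filter on one call.

    Passes iff the site depth meets ``min_depth`` and the alternate-allele
    read fraction lies within [``ab_min``, ``ab_max``] (bounds inclusive).
    Zero-depth calls fail rather than raising.
    """
    if call.total_depth < config.min_depth or call.total_depth == 0:
        return False
    return config.ab_min <= call.allele_balance <= config.ab_max


def consequence_filter(variant: AnnotatedVariant) -> bool:
    """True for consequences altering primary protein structure or splicing."""
    return variant.consequence in PROTEIN_ALTERING


def maf_filter(variant: AnnotatedVariant, config: FilterConfig = FilterConfig()) -> bool:
    """True iff the reference MAF is below threshold (strict) or unobserved."""
    return variant.ref_maf is None or variant.ref_maf < config.maf_threshold


def deleteriousness_filter(
    variant: AnnotatedVariant, config: FilterConfig = FilterConfig()
) -> bool:
    """Prediction-tool consensus rule.

    InDels: >= ``indel_min_damaging_votes`` of the 3-tool panel.  Stop-gain
    substitutions: MutationTaster must call D.  Other substitutions:
    >= ``snv_min_damaging_votes`` of the 5-tool panel.
    """
    for tool, call in variant.predictions.items():
        if call not in PREDICTION_CALLS:
            raise ValueError(f"malformed prediction call {call!r} for {tool}")
    if variant.is_indel:
        votes = sum(
            variant.predictions[t] in config.damaging_calls for t in INDEL_TOOLS
        )
        return votes >= config.indel_min_damaging_votes
    if variant.consequence == "nonsense":
        return variant.predictions["MutationTaster"] == "D"
    votes = sum(variant.predictions[t] in config.damaging_calls for t in SNV_TOOLS)
    return votes >= config.snv_min_damaging_votes


def shared_candidates(
    family: Pedigree,
    calls: dict[str, list[VariantCall]],
    annotations: dict[tuple[str, int, str, str], AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
    keep_failed: bool = False,
) -> list[CandidateVariant]:
    """Run the full cascade for one family.

    Parameters
    ----------
    family
        Pedigree with >= 1 sequenced member.
    calls
        Per-sample call lists; every sequenced member must have an entry.
    annotations
        Site annotations covering every shared call site.
    keep_failed
        Also return variants failing a downstream filter, with their trail
        (the sharing step itself is never relaxed).

    Returns candidates sorted by genomic position for determinism.
    """
    sequenced = family.sequenced_members
    if not sequenced:
        raise ValueError(f"family {family.family_id} has no sequenced member")
    for m in sequenced:
        if m.individual_id not in calls:
            raise ValueError(
                f"no calls supplied for sequenced member {m.individual_id} "
                f"of family {family.family_id}"
            )

    per_member: list[dict[tuple[str, int, str, str], VariantCall]] = []
    for m in sequenced:
        per_member.append({c.key: c for c in calls[m.individual_id]})

    shared_keys = set(per_member[0])
    for d in per_member[1:]:
        shared_keys &= set(d)

    out: list[CandidateVariant] = []
    for key in sorted(shared_keys):
        member_calls = [d[key] for d in per_member]
        if config.depth_in_all_members:
            het_ok = all(het_call_filter(c, config) for c in member_calls)
        else:
            relaxed = FilterConfig(
                ab_min=config.ab_min,
                ab_max=config.ab_max,
                min_depth=0,
                maf_threshold=config.maf_threshold,
                snv_min_damaging_votes=config.snv_min_damaging_votes,
                indel_min_damaging_votes=config.indel_min_damaging_votes,
                damaging_calls=config.damaging_calls,
            )
            het_ok = all(het_call_filter(c, relaxed) for c in member_calls) and any(
                c.total_depth >= config.min_depth for c in member_calls
            )
        if not het_ok and not keep_failed:
            continue
        try:
            variant = annotations[key]
        except KeyError:
            raise KeyError(
                f"no annotation for shared site {key[0]}:{key[1]} {key[2]}>{key[3]}"
            ) from None
        trail = [
            ("het_shared", het_ok),
            ("consequence", consequence_filter(variant)),
            ("maf", maf_filter(variant, config)),
            ("deleteriousness", deleteriousness_filter(variant, config)),
        ]
        cand = CandidateVariant(
            variant=variant,
            family_id=family.family_id,
            carrier_samples=frozenset(m.individual_id for m in sequenced),
            filter_trail=tuple(trail),
        )
        if cand.passed or keep_failed:
            out.append(cand)
    return out
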
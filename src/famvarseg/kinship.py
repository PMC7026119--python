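"""Rare-allele identity-by-state screening between sequenced individuals.

For every unordered sample pair, the fraction of shared rare alleles is
computed over the union of the pair's eligible variant sites.  Eligible
sites are rare against the reference panel (MAF < 0.1% or absent), lie
within a configurable distance of a capture-target interval, and - when a
VCF FILTER column is propagated - passed variant quality recalibration.
Alleles match on identical (chrom, pos, ref, alt); no dosage weighting.

A configurable alert threshold (default 3% sharing) flags pairs from
different families that look closer than expected for unrelateds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from famvarseg.core_io import AnnotatedVariant, Pedigree, VariantCall

__all__ = ["KinshipEstimate", "pairwise_sharing", "max_interfamily_sharing"]

#: Denominator convention used for shared_fraction (recorded for consumers).
DENOMINATOR = "union of the pair's eligible variant sites"


@dataclass(frozen=True)
class KinshipEstimate:
    sample_a: str
    sample_b: str
    n_shared: int
    n_union: int
    warning: bool = False  # set when the pair has no eligible site at all

    @property
    def shared_fraction(self) -> float:
        if self.n_union == 0:
            return 0.0
        return self.n_shared / self.n_union


def _eligible_sites(
    calls: Iterable[VariantCall],
    annotations: Mapping[tuple[str, int, str, str], AnnotatedVariant],
    targets: Mapping[str, IntervalTree] | None,
    maf_threshold: float,
    target_distance: int,
) -> set[tuple[str, int, str, str]]:
    sites: set[tuple[str, int, str, str]] = set()
    for c in calls:
        ann = annotations.get(c.key)
        if ann is None:
            continue
        if ann.ref_maf is not None and ann.ref_maf >= maf_threshold:
            continue
        if targets is not None:
            tree = targets.get(c.chrom)
            # variant occupies [pos-1, pos) in 0-based coordinates; pad by
            # target_distance on both sides
            if tree is None or not tree.overlap(
                c.pos - 1 - target_distance, c.pos + target_distance
            ):
                continue
        sites.add(c.key)
    return sites


def pairwise_sharing(
    calls_by_sample: Mapping[str, list[VariantCall]],
    annotations: Mapping[tuple[str, int, str, str], AnnotatedVariant],
    targets: Mapping[str, IntervalTree] | None = None,
    maf_threshold: float = 0.001,
    target_distance: int = 100,
) -> list[KinshipEstimate]:
    """Shared-rare-allele estimates for all unordered sample pairs.

    Pairs with an empty eligible-site union are reported with fraction 0 and
    ``warning=True`` rather than raising.  The result is symmetric in, and
    independent of, sample order.
    """
    if len(calls_by_sample) < 2:
        raise ValueError("need at least two samples")
    sites = {
        sid: _eligible_sites(
            calls, annotations, targets, maf_threshold, target_distance
        )
        for sid, calls in calls_by_sample.items()
    }
    out: list[KinshipEstimate] = []
    for a, b in combinations(sorted(sites), 2):
        union = sites[a] | sites[b]
        shared = sites[a] & sites[b]
        out.append(
            KinshipEstimate(
                sample_a=a,
                sample_b=b,
                n_shared=len(shared),
                n_union=len(union),
                warning=len(union) == 0,
            )
        )
    return out


def max_interfamily_sharing(
    estimates: Sequence[KinshipEstimate],
    pedigrees: Sequence[Pedigree] | Mapping[str, str],
) -> float:
    """Maximum shared fraction over pairs spanning different families.

    ``pedigrees`` may be Pedigree objects (sample -> family derived from
    membership) or a plain sample -> family mapping.  Raises when no
    cross-family pair exists.
    """
    if isinstance(pedigrees, Mapping):
        fam = dict(pedigrees)
    else:
        fam = {
            m.individual_id: p.family_id for p in pedigrees for m in p.members
        }
    best: float | None = None
    for est in estimates:
        fa, fb = fam.get(est.sample_a), fam.get(est.sample_b)
        if fa is None or fb is None or fa == fb:
            continue
        frac = est.shared_fraction
        if best is None or frac > best:
            best = frac
    if best is None:
        raise ValueError("no pair spanning two different families")
    return best
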
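"""Data model and file I/O for family-based rare-variant analysis.

File formats
------------
Pedigrees
    Whitespace-delimited text, 8 columns per row::

        family_id  individual_id  father_id  mother_id  sex  phenotype  dna  sequenced

    Unknown parents are coded ``0`` (both parents must be known or both
    unknown).  Sex: ``1`` male, ``2`` female, ``0`` unknown.  Phenotype codes:
    ``1`` unaffected, ``2`` bipolar disorder type I, ``3`` type II, ``4`` BD
    not otherwise specified, ``5`` other psychiatric disorder, ``6`` unknown.
    ``dna``/``sequenced`` are 0/1 flags (sequenced implies DNA available).

Variant calls
    VCF 4.x with per-sample ``DP`` and ``AD`` FORMAT fields.  Positions are
    1-based throughout the package; interval files (capture targets) are BED,
    0-based half-open.  Conversions happen only in :func:`read_targets` and
    the kinship eligibility check.

Gene sets
    GMT: tab-delimited, ``name<TAB>description<TAB>member...``.

Annotations, gene covariates, expression
    Plain TSV; see the reader docstrings for the column contracts.

Two bundled fixtures transcribe the published candidate-variant table
(16 rare variants in 8 genes recurring across two families each) and the
extended-segregation carrier counts for the same variants; a third, synthetic
table provides 12-brain-region expression values consistent with the
published brain-expression flags.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "Individual",
    "Pedigree",
    "VariantCall",
    "AnnotatedVariant",
    "FamilyVariant",
    "GeneSet",
    "GeneCovariates",
    "PedigreeError",
    "read_pedigrees",
    "write_pedigrees",
    "read_calls",
    "read_annotations",
    "write_annotations",
    "read_gene_sets",
    "write_gene_sets",
    "read_covariates",
    "read_expression",
    "read_targets",
    "load_table1_fixture",
    "load_table2_fixture",
    "load_table2_brain_flags",
    "load_brain_expression_fixture",
]

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("BD1", "BD2", "BD_NOS", "OTHER_PSY", "UNAFFECTED", "UNKNOWN")
#: BD diagnoses counted as affected in association testing.
BD_PHENOTYPES = frozenset({"BD1", "BD2", "BD_NOS"})

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}
PHENOTYPE_CODES = {
    "1": "UNAFFECTED",
    "2": "BD1",
    "3": "BD2",
    "4": "BD_NOS",
    "5": "OTHER_PSY",
    "6": "UNKNOWN",
}
PHENOTYPE_TO_CODE = {v: k for k, v in PHENOTYPE_CODES.items()}

#: Prediction-tool panel for single-nucleotide variants.
SNV_TOOLS = ("SIFT", "P2_HDIV", "P2_HVAR", "LRT", "MutationTaster")
#: Prediction-tool panel for insertions/deletions.
INDEL_TOOLS = ("MutationTaster", "PROVEAN", "SIFT")
PREDICTION_CALLS = frozenset({"D", "P", "N", "U", "NA"})

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice", "synonymous", "other"}
)
#: Consequences that alter the primary protein structure or splicing.
PROTEIN_ALTERING = frozenset({"missense", "nonsense", "frameshift", "inframe_indel", "splice"})

#: The 12 brain regions averaged for the expression flag (spinal cord excluded).
BRAIN_REGIONS = (
    "Amygdala",
    "Anterior_cingulate_cortex",
    "Caudate",
    "Cerebellar_Hemisphere",
    "Cerebellum",
    "Cortex",
    "Frontal_Cortex",
    "Hippocampus",
    "Hypothalamus",
    "Nucleus_accumbens",
    "Putamen",
    "Substantia_nigra",
)


class PedigreeError(ValueError):
    """Structural problem in a pedigree or pedigree file."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member with phenotype category and sequencing flags."""

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    phenotype: str = "UNKNOWN"
    dna_available: bool = False
    sequenced: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r} for {self.individual_id}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"invalid phenotype {self.phenotype!r} for {self.individual_id}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id}: father and mother must both be "
                "known or both unknown"
            )
        if self.sequenced and not self.dna_available:
            raise ValueError(
                f"individual {self.individual_id}: sequenced requires dna_available"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def affected_bd(self) -> bool:
        return self.phenotype in BD_PHENOTYPES


@dataclass
class Pedigree:
    """A single family: acyclic directed graph of :class:`Individual`.

    Validated on construction: unique member ids, parent references resolve
    within the family, the parent relation is acyclic, and at least one
    founder exists.
    """

    family_id: str
    members: list[Individual]
    _by_id: dict[str, Individual] = field(init=False, repr=False)
    _kinship_cache: dict[tuple[str, str], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, Individual] = {}
        for m in self.members:
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"individual {m.individual_id} belongs to family {m.family_id}, "
                    f"not {self.family_id}"
                )
            if m.individual_id in by_id:
                raise PedigreeError(
                    f"duplicate individual id {m.individual_id} in family {self.family_id}"
                )
            by_id[m.individual_id] = m
        object.__setattr__(self, "_by_id", by_id)
        object.__setattr__(self, "_kinship_cache", {})
        for m in self.members:
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is not None and pid not in by_id:
                    raise PedigreeError(
                        f"individual {m.individual_id} in family {self.family_id} "
                        f"references missing {role} {pid}"
                    )
        if not any(m.is_founder for m in self.members):
            raise PedigreeError(f"family {self.family_id} has no founder")
        self.topological_order()  # raises on cycles

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __len__(self) -> int:
        return len(self.members)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def sequenced_members(self) -> list[Individual]:
        return [m for m in self.members if m.sequenced]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            m for m in self.members if individual_id in (m.father_id, m.mother_id)
        ]

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-children; raises on cycles."""
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, chain: tuple[str, ...]) -> None:
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise PedigreeError(
                    f"cycle in family {self.family_id} involving {iid}"
                )
            state[iid] = 0
            m = self._by_id[iid]
            if m.father_id is not None:
                visit(m.father_id, chain + (iid,))
                visit(m.mother_id, chain + (iid,))
            state[iid] = 1
            order.append(m)

        for m in self.members:
            visit(m.individual_id, ())
        return order

    def generation_depth(self, individual_id: str) -> int:
        """Number of ancestral generations above the individual (founder = 0)."""
        m = self._by_id[individual_id]
        if m.is_founder:
            return 0
        return 1 + max(
            self.generation_depth(m.father_id), self.generation_depth(m.mother_id)
        )

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) by the standard recursive algorithm.

        Founders are assumed unrelated and non-inbred; phi(i, i) = 1/2 for
        outbred individuals, phi = 1/4 for parent-offspring and full sibs.
        """
        key = (a, b) if a <= b else (b, a)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        ma, mb = self._by_id[a], self._by_id[b]
        if a == b:
            if ma.is_founder:
                phi = 0.5
            else:
                phi = 0.5 * (1.0 + self.kinship(ma.father_id, ma.mother_id))
        else:
            # Recurse on the individual further from the founders so the
            # recursion never ascends through the other argument.
            da, db = self.generation_depth(a), self.generation_depth(b)
            if da < db:
                ma, mb = mb, ma
            if ma.is_founder:
                phi = 0.0
            else:
                phi = 0.5 * (
                    self.kinship(ma.father_id, mb.individual_id)
                    + self.kinship(ma.mother_id, mb.individual_id)
                )
        self._kinship_cache[key] = phi
        return phi


@dataclass(frozen=True)
class VariantCall:
    """A non-reference call for one sample at one alternate allele."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    total_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, {self.total_depth}] "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_balance(self) -> float:
        """Alternate allele read fraction; 0 when the site has no coverage."""
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth


@dataclass(frozen=True)
class AnnotatedVariant:
    """Site-level annotation: gene, consequence, reference MAF, predictions.

    ``predictions`` maps tool name to a call in {D, P, N, U, NA}; the tool
    panel is :data:`SNV_TOOLS` for substitutions and :data:`INDEL_TOOLS` for
    length-changing variants.  ``ref_maf`` is ``None`` when the variant is
    absent from the reference exome panel.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    ref_maf: float | None
    predictions: Mapping[str, str]
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.ref_maf is not None and not 0.0 <= self.ref_maf <= 1.0:
            raise ValueError(f"ref_maf {self.ref_maf} outside [0, 1]")
        expected = INDEL_TOOLS if self.is_indel else SNV_TOOLS
        if set(self.predictions) != set(expected):
            raise ValueError(
                f"prediction grid {sorted(self.predictions)} does not match the "
                f"{'InDel' if self.is_indel else 'SNV'} tool panel {sorted(expected)}"
            )
        for tool, call in self.predictions.items():
            if call not in PREDICTION_CALLS:
                raise ValueError(f"malformed prediction call {call!r} for {tool}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        """Protein-level label when known, else a chrom:pos:ref>alt string."""
        return self.protein_change or f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class FamilyVariant:
    """An annotated variant tied to the family in which it segregates."""

    family_id: str
    variant: AnnotatedVariant

    @property
    def gene(self) -> str:
        return self.variant.gene

    @property
    def label(self) -> str:
        return self.variant.label


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class GeneCovariates:
    """Per-gene confounder metrics used for matched null sampling."""

    gene: str
    exon_length: int  # cumulative exonic bp
    coverage: float  # mean sequencing fold coverage
    constraint_z: float  # missense-intolerance z score

    def __post_init__(self) -> None:
        if self.exon_length <= 0:
            raise ValueError(f"exon_length must be positive for {self.gene}")
        if self.coverage < 0:
            raise ValueError(f"coverage must be non-negative for {self.gene}")


# ---------------------------------------------------------------------------
# Pedigree files


def read_pedigrees(path: str | Path) -> list[Pedigree]:
    """Read an 8-column pedigree file into one :class:`Pedigree` per family.

    Families are returned in order of first appearance.  Raises
    :class:`PedigreeError` for duplicate ids, dangling parent references, or
    malformed rows.
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 8:
                raise PedigreeError(
                    f"{path} line {lineno}: expected 8 columns, found {len(fields)}"
                )
            fam, iid, father, mother, sex, pheno, dna, seq = fields
            if sex not in SEX_CODES:
                raise PedigreeError(f"{path} line {lineno}: bad sex code {sex!r}")
            if pheno not in PHENOTYPE_CODES:
                raise PedigreeError(
                    f"{path} line {lineno}: bad phenotype code {pheno!r}"
                )
            ind = Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=SEX_CODES[sex],
                phenotype=PHENOTYPE_CODES[pheno],
                dna_available=dna == "1",
                sequenced=seq == "1",
            )
            rows.setdefault(fam, []).append(ind)
    return [Pedigree(family_id=fam, members=members) for fam, members in rows.items()]


def write_pedigrees(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            SEX_TO_CODE[m.sex],
                            PHENOTYPE_TO_CODE[m.phenotype],
                            "1" if m.dna_available else "0",
                            "1" if m.sequenced else "0",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# VCF


def read_calls(
    path: str | Path, sample_ids: list[str] | None = None
) -> list[VariantCall]:
    """Read non-reference calls from a VCF with per-sample AD and DP.

    One :class:`VariantCall` is emitted per sample x alternate allele present
    in the sample's genotype; multi-allelic records are decomposed, never
    dropped.  Raises ``ValueError`` when depth fields are missing.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(sample_ids) if sample_ids is not None else list(vcf.header.samples)
        for rec in vcf:
            for sid in samples:
                sample = rec.samples[sid]
                gt = sample.get("GT")
                if gt is None:
                    continue
                alt_indices = sorted(
                    {a for a in gt if a is not None and a > 0}
                )
                if not alt_indices:
                    continue
                ad = sample.get("AD")
                dp = sample.get("DP")
                if ad is None or all(a is None for a in ad):
                    raise ValueError(
                        f"{path}: sample {sid} at {rec.chrom}:{rec.pos} lacks AD"
                    )
                if dp is None:
                    raise ValueError(
                        f"{path}: sample {sid} at {rec.chrom}:{rec.pos} lacks DP"
                    )
                for ai in alt_indices:
                    calls.append(
                        VariantCall(
                            sample_id=sid,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=rec.alts[ai - 1],
                            total_depth=int(dp),
                            alt_depth=int(ad[ai]),
                        )
                    )
    return calls


# ---------------------------------------------------------------------------
# Annotation tables

_ANN_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "ref_maf",
    "protein_change",
    "SIFT",
    "P2_HDIV",
    "P2_HVAR",
    "LRT",
    "MutationTaster",
    "PROVEAN",
]


def read_annotations(path: str | Path) -> dict[tuple[str, int, str, str], AnnotatedVariant]:
    """Read a variant-annotation TSV keyed by (chrom, pos, ref, alt).

    The table carries one column per prediction tool; cells are calls in
    {D, P, N, U, NA} with ``.`` marking tools outside the variant's panel.
    ``ref_maf`` of ``NA`` means absent from the reference panel.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    out: dict[tuple[str, int, str, str], AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        is_indel = len(row.ref) != len(row.alt)
        tools = INDEL_TOOLS if is_indel else SNV_TOOLS
        predictions = {t: getattr(row, t) for t in tools}
        variant = AnnotatedVariant(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            consequence=row.consequence,
            ref_maf=None if row.ref_maf == "NA" else float(row.ref_maf),
            predictions=predictions,
            protein_change=row.protein_change or None,
        )
        out[variant.key] = variant
    return out


def write_annotations(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    all_tools = ("SIFT", "P2_HDIV", "P2_HVAR", "LRT", "MutationTaster", "PROVEAN")
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "ref_maf": "NA" if v.ref_maf is None else f"{v.ref_maf:.6g}",
            "protein_change": v.protein_change or "",
        }
        for t in all_tools:
            row[t] = v.predictions.get(t, ".")
        rows.append(row)
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file; membership is deduplicated, line order preserved."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path} line {lineno}: GMT lines need name, description "
                    f"and at least one member (found {len(fields)} fields)"
                )
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path} line {lineno}: empty member list")
            sets.append(GeneSet(name=fields[0], members=members))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Covariates, expression, capture targets


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Gene covariate TSV -> DataFrame indexed by gene symbol.

    Columns: ``exon_length`` (cumulative bp, > 0), ``coverage`` (mean fold,
    >= 0), ``constraint_z`` (missense-intolerance z).
    """
    df = pd.read_csv(path, sep="\t", index_col="gene")
    for col in ("exon_length", "coverage", "constraint_z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing covariate column {col!r}")
    if (df["exon_length"] <= 0).any():
        raise ValueError(f"{path}: exon_length must be positive")
    if (df["coverage"] < 0).any():
        raise ValueError(f"{path}: coverage must be non-negative")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene symbols")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x brain-region expression TSV -> DataFrame indexed by gene."""
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_targets(path: str | Path) -> dict[str, IntervalTree]:
    """BED capture targets -> per-chromosome interval trees (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path} line {lineno}: empty interval")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


# ---------------------------------------------------------------------------
# Bundled fixtures


def _data_path(name: str):
    return importlib.resources.files("famvarseg.data").joinpath(name)


def load_table1_fixture() -> list[FamilyVariant]:
    """The 16 recurrent-gene candidate variants with their family labels."""
    out: list[FamilyVariant] = []
    with importlib.resources.as_file(_data_path("table1_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for row in df.itertuples(index=False):
        variant = AnnotatedVariant(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            consequence=row.consequence,
            ref_maf=None if row.ref_maf == "NA" else float(row.ref_maf),
            predictions={t: getattr(row, t) for t in SNV_TOOLS},
            protein_change=row.protein_change,
        )
        out.append(FamilyVariant(family_id=row.family, variant=variant))
    return out


def load_table2_fixture() -> list:
    """Extended-segregation carrier counts for the 16 candidate variants.

    Returns :class:`famvarseg.segregation.SegregationSummary` records (one per
    variant) with BD / other-psychiatric / unaffected carrier and DNA-available
    totals.
    """
    from famvarseg.segregation import SegregationSummary

    with importlib.resources.as_file(_data_path("table2_segregation.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return [
        SegregationSummary(
            gene=row.gene,
            family_id=row.family,
            label=row.protein_change,
            bd_carriers=int(row.bd_carriers),
            bd_total=int(row.bd_total),
            psy_carriers=int(row.psy_carriers),
            psy_total=int(row.psy_total),
            unaff_carriers=int(row.unaff_carriers),
            unaff_total=int(row.unaff_total),
        )
        for row in df.itertuples(index=False)
    ]


def load_table2_brain_flags() -> dict[str, bool]:
    """Per-gene brain-expression flags accompanying the segregation table."""
    with importlib.resources.as_file(_data_path("table2_segregation.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return {
        row.gene: row.brain_expressed == "yes" for row in df.itertuples(index=False)
    }


def load_brain_expression_fixture() -> pd.DataFrame:
    """Synthetic 12-region expression values for the 8 candidate genes.

    The region-level values are invented; only the derived per-gene flags
    (mean > 0.5) are anchored to the published brain-expression calls.
    """
    with importlib.resources.as_file(_data_path("brain_expression_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="gene")
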
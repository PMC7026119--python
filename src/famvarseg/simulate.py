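"""Synthetic multiplex-cohort generator.

Emulates the study design the downstream stages assume: multigenerational
families densely affected with bipolar disorder, three affected members per
family sequenced (chosen as distantly related as possible), rare background
variation, and one injected candidate variant per family whose gene recurs
across families.  The generator writes every input format the pipeline
consumes (pedigree file, per-sample VCFs, annotation/covariate/expression
tables, capture-target BED, GMT gene sets, an extended genotype table for
the Sanger-style segregation step) plus a truth object for validation.

Model summary
-------------
* Pedigrees: a founding couple; each couple has 1 + Poisson(mean_children-1)
  children; lineages continue by marrying in founder spouses until the
  configured generation depth, with at least one continuing sibship per
  generation.
* Causal variants: one per family, introduced heterozygously at a single
  uniformly chosen founder and gene-dropped; the causal gene is drawn from a
  small recurrent set so that every causal gene segregates in >= 2 families.
* Phenotypes: carriers are affected with probability ``causal_penetrance``,
  non-carriers with ``phenocopy_rate``; affected diagnoses split
  BD-I : BD-II : BD-NOS at 69 : 9 : 3.  Non-affected members receive an
  other-psychiatric label at a small rate, the rest are unaffected.
* Background variation: founder-private introductions per gene
  (Poisson ``background_variant_rate`` per gene per founder) gene-dropped
  down the pedigree, plus a small cohort-wide pool of low-frequency alleles
  carried by founders at Hardy-Weinberg rates (these give unrelated families
  a non-zero rare-allele sharing signal).
* Annotations: reference-panel MAF from a point-mass-at-absent +
  log-uniform-tail spectrum; prediction-tool calls damaging with
  probability 0.2 per tool for background variants and 1 -
  ``prediction_error_rate`` for causal ones.
* Read evidence: per-carrier site depth Poisson(``depth_mean``), alternate
  reads Binomial(depth, 1/2).

Per-family random substreams are derived from the global seed with
``numpy.random.SeedSequence([seed, family_index])``, so adding families
never perturbs earlier ones; a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from famvarseg.core_io import (
    BD_PHENOTYPES,
    BRAIN_REGIONS,
    INDEL_TOOLS,
    SNV_TOOLS,
    GeneSet,
    Individual,
    Pedigree,
    write_gene_sets,
    write_pedigrees,
)

__all__ = [
    "MafSpectrum",
    "SimulationConfig",
    "CohortTruth",
    "SimulationError",
    "simulate_pedigree",
    "drop_variant",
    "assign_phenotypes",
    "select_sequenced_trio",
    "simulate_cohort",
]

_BASES = np.array(["A", "C", "G", "T"])
_BD_SPLIT = np.array([69.0, 9.0, 3.0]) / 81.0
_BG_CONSEQ = np.array(
    ["missense", "synonymous", "other", "splice", "nonsense", "frameshift", "inframe_indel"]
)
_BG_CONSEQ_P = np.array([0.55, 0.25, 0.08, 0.05, 0.03, 0.03, 0.01])
#: Per-tool damaging probability for background variants; chosen so the
#: 3-of-5 consensus filter is discriminative (pass rate ~6% for SNVs).
_BG_DAMAGING_P = 0.2
_ALL_TOOLS = ("SIFT", "P2_HDIV", "P2_HVAR", "LRT", "MutationTaster", "PROVEAN")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MafSpectrum:
    """Reference-MAF distribution: point mass at absent + log-uniform tail."""

    null_fraction: float = 0.3
    log10_min: float = -6.0
    log10_max: float = -2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_fraction <= 1.0:
            raise ValueError("null_fraction must lie in [0, 1]")
        if self.log10_min >= self.log10_max:
            raise ValueError("log10_min must be below log10_max")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    The defaults emulate the study conditions: 27 multiplex families, three
    sequenced affected members each, three-generation pedigrees, a handful
    of recurrent candidate genes, and a background-variant rate calibrated
    so the full prioritization cascade yields roughly 14 candidate variants
    per family (the published yield of 378 over 27 families).
    """

    n_families: int = 27
    n_sequenced_per_family: int = 3
    pedigree_depth: int = 3
    causal_gene_count: int = 8
    causal_penetrance: float = 0.9
    phenocopy_rate: float = 0.01
    background_variant_rate: float = 0.37  # introductions per gene per founder
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    prediction_error_rate: float = 0.05
    depth_mean: float = 60.0
    seed: int = 0
    # cohort-shape parameters
    n_genes: int = 4000
    n_shared_pool: int = 500
    mean_children: float = 2.6
    other_psy_rate: float = 0.08
    dna_available_rate: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "causal_penetrance",
            "phenocopy_rate",
            "prediction_error_rate",
            "other_psy_rate",
            "dna_available_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pedigree_depth < 2:
            raise ValueError("pedigree_depth must be >= 2")
        if self.n_sequenced_per_family < 1:
            raise ValueError("n_sequenced_per_family must be >= 1")
        if self.background_variant_rate < 0 or self.depth_mean <= 0:
            raise ValueError("rates must be non-negative, depth_mean positive")


@dataclass
class CohortTruth:
    """Ground truth for validating downstream stages.

    ``causal_carriers`` lists, per family, every member carrying that
    family's causal variant; each such variant traces to a single founder
    introduction.  ``true_maf`` covers the causal and shared-pool variants
    (family-private background alleles are singleton introductions whose
    population frequency is effectively zero).
    """

    causal_genes: set[str]
    causal_carriers: dict[str, set[str]]
    causal_variants: dict[str, tuple[str, int, str, str]]  # family -> key
    causal_gene_by_family: dict[str, str]
    true_maf: dict[tuple[str, int, str, str], float]


# ---------------------------------------------------------------------------
# Pedigree simulation


def simulate_pedigree(
    config: SimulationConfig,
    rng: np.random.Generator,
    family_id: str = "0001",
    children_per_couple: int | None = None,
) -> Pedigree:
    """Simulate one multigenerational pedigree.

    Founders (including married-in spouses) have unknown parents; every
    generation up to ``pedigree_depth`` contains at least one reproducing
    couple.  ``children_per_couple`` fixes sibship sizes (otherwise
    1 + Poisson(mean_children - 1)).
    """
    if config.pedigree_depth < 2:
        raise ValueError("pedigree_depth must be >= 2")
    members: list[Individual] = []
    counter = [0]

    def new_person(sex: str, father: str | None = None, mother: str | None = None) -> str:
        counter[0] += 1
        iid = f"{family_id}_{counter[0]:03d}"
        members.append(
            Individual(
                individual_id=iid,
                family_id=family_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                phenotype="UNKNOWN",
            )
        )
        return iid

    father0 = new_person("male")
    mother0 = new_person("female")
    couples: list[tuple[str, str, int]] = [(father0, mother0, 1)]
    while couples:
        fa, mo, gen = couples.pop(0)
        if children_per_couple is not None:
            n_children = children_per_couple
        else:
            n_children = 1 + int(rng.poisson(max(config.mean_children - 1.0, 0.0)))
        child_sexes = ["male" if rng.random() < 0.5 else "female" for _ in range(n_children)]
        children = [new_person(sx, father=fa, mother=mo) for sx in child_sexes]
        child_gen = gen + 1
        if child_gen < config.pedigree_depth and children:
            marrying = [c for c in children if rng.random() < 0.75]
            if not marrying:
                marrying = [children[0]]  # keep the lineage going
            for ch in marrying:
                ch_sex = members[[m.individual_id for m in members].index(ch)].sex
                spouse = new_person("female" if ch_sex == "male" else "male")
                fa2, mo2 = (ch, spouse) if ch_sex == "male" else (spouse, ch)
                couples.append((fa2, mo2, child_gen))
    return Pedigree(family_id=family_id, members=members)


def drop_variant(
    ped: Pedigree, founder_id: str, rng: np.random.Generator
) -> frozenset[str]:
    """Gene-drop a single heterozygous founder allele; return the carrier set.

    Each child of a carrier parent inherits the allele with probability 1/2,
    independently; non-descendants of the founder never carry.
    """
    if founder_id not in ped:
        raise ValueError(f"{founder_id} not in family {ped.family_id}")
    if not ped[founder_id].is_founder:
        raise ValueError(f"{founder_id} is not a founder of family {ped.family_id}")
    carriers = {founder_id}
    for m in ped.topological_order():
        if m.is_founder:
            continue
        inherits = (m.father_id in carriers and rng.random() < 0.5) or (
            m.mother_id in carriers and rng.random() < 0.5
        )
        if inherits:
            carriers.add(m.individual_id)
    return frozenset(carriers)


def assign_phenotypes(
    ped: Pedigree,
    carriers: frozenset[str] | set[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Pedigree:
    """Assign diagnoses given carrier status.

    Carriers are affected with probability ``causal_penetrance``,
    non-carriers with ``phenocopy_rate``; affected diagnoses split across
    BD-I/BD-II/BD-NOS at 69:9:3.  The remaining members are labelled
    other-psychiatric at ``other_psy_rate``, else unaffected.
    """
    unknown = set(carriers) - {m.individual_id for m in ped.members}
    if unknown:
        raise ValueError(f"carriers not in pedigree: {sorted(unknown)}")
    new_members = []
    for m in ped.members:
        p_aff = config.causal_penetrance if m.individual_id in carriers else config.phenocopy_rate
        if rng.random() < p_aff:
            pheno = ("BD1", "BD2", "BD_NOS")[int(rng.choice(3, p=_BD_SPLIT))]
        elif rng.random() < config.other_psy_rate:
            pheno = "OTHER_PSY"
        else:
            pheno = "UNAFFECTED"
        new_members.append(replace(m, phenotype=pheno))
    return Pedigree(family_id=ped.family_id, members=new_members)


def select_sequenced_trio(ped: Pedigree, n: int = 3) -> list[str]:
    """Choose ``n`` DNA-available BD-affected members, maximally distant.

    Minimizes the summed pairwise kinship coefficient over all subsets;
    ties broken by lexicographic member ids (subsets are enumerated in
    lexicographic order and strict improvement is required to switch).
    """
    from itertools import combinations

    eligible = sorted(
        m.individual_id
        for m in ped.members
        if m.affected_bd and m.dna_available
    )
    if len(eligible) < n:
        raise SimulationError(
            f"family {ped.family_id}: only {len(eligible)} DNA-available "
            f"affected members, need {n}"
        )
    best: tuple[float, tuple[str, ...]] | None = None
    for combo in combinations(eligible, n):
        score = sum(ped.kinship(a, b) for a, b in combinations(combo, 2))
        if best is None or score < best[0] - 1e-12:
            best = (score, combo)
    return list(best[1])


# ---------------------------------------------------------------------------
# Cohort simulation


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, family_index]))


def _gene_catalog(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    idx = np.arange(n)
    exon_length = np.clip(
        np.round(np.exp(rng.normal(np.log(1500.0), 0.8, size=n))).astype(int), 200, 100_000
    )
    coverage = np.clip(rng.normal(68.0, 8.0, size=n), 20.0, None).round(2)
    constraint_z = rng.normal(0.0, 1.5, size=n).round(3)
    return pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in idx],
            "chrom": [str((i % 22) + 1) for i in idx],
            "span_start": 1_000_000 + (idx // 22) * 200_000,
            "exon_length": exon_length,
            "coverage": coverage,
            "constraint_z": constraint_z,
        }
    ).set_index("gene")


def _drop_matrix(
    ped: Pedigree, founder_init: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, int]]:
    """Vectorized gene-dropping of many independent alleles down one pedigree.

    ``founder_init``: (n_members, V) carrier states with only founder rows
    set.  Returns the completed carrier matrix and the member->row index.
    """
    topo = ped.topological_order()
    index = {m.individual_id: i for i, m in enumerate(topo)}
    carrier = np.zeros((len(topo), founder_init.shape[1]), dtype=bool)
    for mi, m in enumerate(ped.members):
        carrier[index[m.individual_id]] = founder_init[mi]
    v = founder_init.shape[1]
    for m in topo:
        if m.is_founder:
            continue
        fa, mo = index[m.father_id], index[m.mother_id]
        carrier[index[m.individual_id]] |= (carrier[fa] & (rng.random(v) < 0.5)) | (
            carrier[mo] & (rng.random(v) < 0.5)
        )
    return carrier, index


def _background_predictions(
    n: int, is_indel: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, 6) call matrix over _ALL_TOOLS; '.' outside the variant's panel."""
    damaging = rng.random((n, 6)) < _BG_DAMAGING_P
    dp = np.where(rng.random((n, 6)) < 0.8, "D", "P")
    nn = np.asarray(["N", "U", "NA"])[rng.integers(0, 3, size=(n, 6))]
    calls = np.where(damaging, dp, nn).astype(object)
    for j, tool in enumerate(_ALL_TOOLS):
        snv_panel = tool in SNV_TOOLS
        indel_panel = tool in INDEL_TOOLS
        if not snv_panel:
            calls[~is_indel, j] = "."
        if not indel_panel:
            calls[is_indel, j] = "."
    return calls


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, Path], CohortTruth]:
    """Simulate the cohort and write every pipeline input under ``out_dir``.

    Returns the output paths and the :class:`CohortTruth`.  Raises
    :class:`SimulationError` when a family cannot produce the required
    number of DNA-available affected members within 100 redraws.
    """
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    cohort_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    genes = _gene_catalog(config, cohort_rng)
    gene_names = genes.index.to_numpy()
    n_causal = min(config.causal_gene_count, config.n_genes)
    causal_genes = sorted(
        cohort_rng.choice(gene_names, size=n_causal, replace=False)
    ) if n_causal else []

    # cohort-wide shared pool of low-frequency alleles
    pool = []
    if config.n_shared_pool:
        pool_gene_idx = cohort_rng.integers(0, config.n_genes, size=config.n_shared_pool)
        pool_maf = 10 ** cohort_rng.uniform(-4.0, np.log10(5e-3), size=config.n_shared_pool)
        pool_preds = _background_predictions(
            config.n_shared_pool,
            np.zeros(config.n_shared_pool, dtype=bool),
            cohort_rng,
        )
        per_gene_counter: dict[int, int] = {}
        for j in range(config.n_shared_pool):
            gi = int(pool_gene_idx[j])
            k = per_gene_counter.get(gi, 0)
            per_gene_counter[gi] = k + 1
            row = genes.iloc[gi]
            pos = int(row["span_start"]) + 150_000 + 10 * k
            ref, alt = _draw_snv_alleles(cohort_rng)
            pool.append(
                {
                    "key": (str(row["chrom"]), pos, ref, alt),
                    "gene": str(gene_names[gi]),
                    "true_maf": float(pool_maf[j]),
                    "consequence": str(
                        _BG_CONSEQ[:2][int(cohort_rng.random() < 0.45)]
                    ),  # mostly missense/synonymous
                    "pred": pool_preds[j],
                }
            )

    pedigrees: list[Pedigree] = []
    truth = CohortTruth(
        causal_genes=set(map(str, causal_genes)),
        causal_carriers={},
        causal_variants={},
        causal_gene_by_family={},
        true_maf={k["key"]: k["true_maf"] for k in pool},
    )
    ann_rows: list[dict] = []
    vcf_rows: dict[str, list[tuple]] = {}
    ext_rows: list[tuple] = []

    for fi in range(config.n_families):
        fam_id = f"{fi + 1:04d}"
        rng = _family_rng(config.seed, fi + 1)
        causal_gene = str(causal_genes[fi % n_causal]) if n_causal else None

        ped = carriers = None
        for _attempt in range(100):
            cand_ped = simulate_pedigree(config, rng, family_id=fam_id)
            founder_ids = sorted(f.individual_id for f in cand_ped.founders)
            if causal_gene is not None:
                founder = founder_ids[int(rng.integers(len(founder_ids)))]
                cand_carriers = drop_variant(cand_ped, founder, rng)
            else:
                cand_carriers = frozenset()
            cand_ped = assign_phenotypes(cand_ped, cand_carriers, config, rng)
            # DNA availability; the sequenced trio is forced available below
            cand_ped = Pedigree(
                family_id=fam_id,
                members=[
                    replace(m, dna_available=bool(rng.random() < config.dna_available_rate))
                    for m in cand_ped.members
                ],
            )
            n_eligible = sum(
                1 for m in cand_ped.members if m.affected_bd and m.dna_available
            )
            if n_eligible >= config.n_sequenced_per_family:
                ped, carriers = cand_ped, cand_carriers
                break
        if ped is None:
            raise SimulationError(
                f"family {fam_id}: no {config.n_sequenced_per_family} DNA-available "
                "affected members after 100 redraws"
            )

        trio = select_sequenced_trio(ped, config.n_sequenced_per_family)
        ped = Pedigree(
            family_id=fam_id,
            members=[
                replace(m, sequenced=m.individual_id in trio)
                if m.individual_id in trio
                else m
                for m in ped.members
            ],
        )
        pedigrees.append(ped)
        truth.causal_carriers[fam_id] = set(carriers)
        if causal_gene is not None:
            truth.causal_gene_by_family[fam_id] = causal_gene

        _simulate_family_variants(
            config,
            rng,
            ped,
            trio,
            genes,
            gene_names,
            causal_gene,
            carriers,
            fi,
            pool,
            truth,
            ann_rows,
            vcf_rows,
            ext_rows,
        )

    paths = _write_outputs(
        config, out, pedigrees, genes, causal_genes, pool, cohort_rng,
        ann_rows, vcf_rows, ext_rows, truth,
    )
    return paths, truth


def _draw_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return str(_BASES[i]), str(_BASES[j])


def _simulate_family_variants(
    config,
    rng,
    ped,
    trio,
    genes,
    gene_names,
    causal_gene,
    causal_carriers,
    family_index,
    pool,
    truth,
    ann_rows,
    vcf_rows,
    ext_rows,
) -> None:
    """Generate this family's variant data and append to the cohort buffers."""
    fam_id = ped.family_id
    members = ped.members
    member_ids = [m.individual_id for m in members]
    founder_rows = [i for i, m in enumerate(members) if m.is_founder]
    spans = genes["span_start"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    trio_set = set(trio)
    dna_ids = [m.individual_id for m in members if m.dna_available]

    variant_keys: list[tuple[str, int, str, str]] = []
    variant_gene: list[str] = []
    variant_conseq: list[str] = []
    variant_maf: list[float | None] = []
    variant_pred: list[np.ndarray] = []
    variant_label: list[str | None] = []
    carrier_cols: list[np.ndarray] = []  # per variant: bool over members

    # --- background founder-private introductions, vectorized per founder
    spectrum = config.maf_spectrum
    used_pos: dict[str, set[int]] = {}
    for fr in founder_rows:
        counts = rng.poisson(config.background_variant_rate, size=config.n_genes)
        v = int(counts.sum())
        if v == 0:
            continue
        gidx = np.repeat(np.arange(config.n_genes), counts)
        init = np.zeros((len(members), v), dtype=bool)
        init[fr] = True
        carrier, index = _drop_matrix(ped, init, rng)
        trio_rows = np.array([index[t] for t in sorted(trio_set)])
        seq_any = carrier[trio_rows].any(axis=0)
        # annotation draws consumed for every introduction to keep the
        # stream layout independent of who carries
        conseq = _BG_CONSEQ[
            rng.choice(len(_BG_CONSEQ), size=v, p=_BG_CONSEQ_P)
        ]
        is_indel = np.isin(conseq, ("frameshift", "inframe_indel"))
        maf_null = rng.random(v) < spectrum.null_fraction
        maf_val = 10 ** rng.uniform(spectrum.log10_min, spectrum.log10_max, size=v)
        preds = _background_predictions(v, is_indel, rng)
        offsets = rng.integers(0, 5000, size=v)
        base_draw = rng.integers(0, 4, size=v)
        alt_shift = rng.integers(0, 3, size=v)

        keep = np.flatnonzero(seq_any)
        member_order = np.array([index[i] for i in member_ids])
        for k in keep:
            gi = int(gidx[k])
            gene = str(gene_names[gi])
            pos_base = int(spans[gi]) + family_index * 5000
            pos = pos_base + int(offsets[k])
            taken = used_pos.setdefault(gene, set())
            while pos in taken:
                pos += 1
            taken.add(pos)
            ref = str(_BASES[int(base_draw[k])])
            if is_indel[k]:
                if conseq[k] == "frameshift":
                    alt = ref + "A"
                else:
                    alt = ref + "GCT"
            else:
                alt = str(_BASES[(int(base_draw[k]) + 1 + int(alt_shift[k])) % 4])
            variant_keys.append((str(chroms[gi]), pos, ref, alt))
            variant_gene.append(gene)
            variant_conseq.append(str(conseq[k]))
            variant_maf.append(None if maf_null[k] else float(maf_val[k]))
            variant_pred.append(preds[k])
            variant_label.append(None)
            carrier_cols.append(carrier[member_order, k])

    member_index = {iid: i for i, iid in enumerate(member_ids)}

    # --- shared-pool alleles: founders carry at Hardy-Weinberg rates
    if pool:
        npool = len(pool)
        init = np.zeros((len(members), npool), dtype=bool)
        for fr in founder_rows:
            init[fr] = rng.random(npool) < 2 * np.array([p["true_maf"] for p in pool])
        if init.any():
            carrier, index = _drop_matrix(ped, init, rng)
            member_order = np.array([index[i] for i in member_ids])
            trio_rows = np.array([index[t] for t in sorted(trio_set)])
            seq_any = carrier[trio_rows].any(axis=0)
            for k in np.flatnonzero(seq_any):
                p = pool[k]
                variant_keys.append(p["key"])
                variant_gene.append(str(p["gene"]))
                variant_conseq.append(p["consequence"])
                variant_maf.append(p["true_maf"])
                variant_pred.append(p["pred"])
                variant_label.append(None)
                carrier_cols.append(carrier[member_order, k])

    # --- the injected causal variant
    if causal_gene is not None:
        grow = genes.loc[causal_gene]
        pos = int(grow["span_start"]) + 158_000 + 10 * family_index
        ref, alt = _draw_snv_alleles(rng)
        key = (str(grow["chrom"]), pos, ref, alt)
        tools_d = rng.random(5) >= config.prediction_error_rate
        pred = np.array(
            ["D" if d else "N" for d in tools_d] + ["."], dtype=object
        )
        maf_null = rng.random() < 0.7
        maf = None if maf_null else float(10 ** rng.uniform(-6.0, -5.0))
        col = np.zeros(len(members), dtype=bool)
        for cid in causal_carriers:
            col[member_index[cid]] = True
        variant_keys.append(key)
        variant_gene.append(causal_gene)
        variant_conseq.append("missense")
        variant_maf.append(maf)
        variant_pred.append(pred)
        variant_label.append(f"c.{pos}{ref}>{alt}")
        carrier_cols.append(col)
        truth.causal_variants[fam_id] = key
        truth.true_maf[key] = 0.0

    if not variant_keys:
        return
    carrier_mat = np.stack(carrier_cols, axis=1)  # (n_members, V)

    # annotations (cohort-wide table is deduplicated later; pool variants
    # recur across families with identical annotations by construction)
    seen_local = set()
    for k, key in enumerate(variant_keys):
        if key in seen_local:
            continue
        seen_local.add(key)
        row = {
            "chrom": key[0],
            "pos": key[1],
            "ref": key[2],
            "alt": key[3],
            "gene": variant_gene[k],
            "consequence": variant_conseq[k],
            "ref_maf": "NA" if variant_maf[k] is None else f"{variant_maf[k]:.6g}",
            "protein_change": variant_label[k] or "",
        }
        for j, tool in enumerate(_ALL_TOOLS):
            row[tool] = str(variant_pred[k][j])
        ann_rows.append(row)

    # per-sample VCF rows with read-depth evidence
    for sid in sorted(trio_set):
        mrow = member_index[sid]
        which = np.flatnonzero(carrier_mat[mrow])
        depths = np.maximum(rng.poisson(config.depth_mean, size=len(which)), 1)
        alts = rng.binomial(depths, 0.5)
        alts = np.clip(alts, 1, depths)  # a carrier has at least one alt read
        rows = vcf_rows.setdefault(sid, [])
        for w, dp, ad in zip(which, depths, alts):
            key = variant_keys[int(w)]
            rows.append((key[0], key[1], key[2], key[3], int(dp), int(ad)))

    # extended genotypes for every variant shared by the whole trio
    trio_rows_local = np.array([member_index[t] for t in sorted(trio_set)])
    shared = np.flatnonzero(carrier_mat[trio_rows_local].all(axis=0))
    for w in shared:
        key = variant_keys[int(w)]
        label = variant_label[int(w)] or f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"
        for iid in dna_ids:
            ext_rows.append(
                (
                    fam_id,
                    key[0],
                    key[1],
                    key[2],
                    key[3],
                    variant_gene[int(w)],
                    label,
                    iid,
                    int(carrier_mat[member_index[iid], int(w)]),
                )
            )


def _write_outputs(
    config,
    out: Path,
    pedigrees,
    genes,
    causal_genes,
    pool,
    cohort_rng,
    ann_rows,
    vcf_rows,
    ext_rows,
    truth,
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    paths["ped"] = out / "cohort.ped"
    write_pedigrees(pedigrees, paths["ped"])

    # annotations: cohort-wide, deduplicated (pool variants recur), sorted
    ann = pd.DataFrame(ann_rows).drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    ann = ann.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    paths["annotations"] = out / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    # per-sample VCFs
    contigs = sorted({c for rows in vcf_rows.values() for c, *_ in rows}, key=_chrom_key)
    paths["vcf_dir"] = out / "vcf"
    for sid in sorted(vcf_rows):
        rows = sorted(vcf_rows[sid], key=lambda r: (_chrom_key(r[0]), r[1], r[2], r[3]))
        with open(out / "vcf" / f"{sid}.vcf", "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sid + "\n"
            )
            for chrom, pos, ref, alt, dp, ad in rows:
                fh.write(
                    f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                    f"GT:DP:AD\t0/1:{dp}:{dp - ad},{ad}\n"
                )

    # covariates
    paths["covariates"] = out / "covariates.tsv"
    genes[["exon_length", "coverage", "constraint_z"]].to_csv(
        paths["covariates"], sep="\t", index_label="gene"
    )

    # capture targets: one padded interval per gene span (BED, 0-based)
    paths["targets"] = out / "targets.bed"
    with open(paths["targets"], "w") as fh:
        for gene, row in genes.iterrows():
            start0 = int(row["span_start"]) - 1
            fh.write(f"{row['chrom']}\t{start0}\t{start0 + 160_000}\t{gene}\n")

    # gene sets: one spiked with the causal genes, one random
    gene_names = genes.index.to_numpy()
    non_causal = [g for g in gene_names if g not in set(map(str, causal_genes))]
    spike_fill = list(
        cohort_rng.choice(non_causal, size=max(0, 50 - len(causal_genes)), replace=False)
    )
    random_members = list(cohort_rng.choice(gene_names, size=50, replace=False))
    sets = [
        GeneSet("spiked_set", frozenset(map(str, list(causal_genes) + spike_fill))),
        GeneSet("random_set", frozenset(map(str, random_members))),
    ]
    paths["gene_sets"] = out / "sets.gmt"
    write_gene_sets(sets, paths["gene_sets"])

    # brain expression: log-normal levels, ~70% of genes brain-expressed
    level = 10 ** cohort_rng.normal(0.2, 0.7, size=len(gene_names))
    region_noise = cohort_rng.uniform(0.6, 1.4, size=(len(gene_names), len(BRAIN_REGIONS)))
    expr = pd.DataFrame(
        (level[:, None] * region_noise).round(4),
        index=pd.Index(gene_names, name="gene"),
        columns=list(BRAIN_REGIONS),
    )
    paths["expression"] = out / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t")

    # extended genotypes for the Sanger-style segregation stage
    paths["extended_genotypes"] = out / "extended_genotypes.tsv"
    ext = pd.DataFrame(
        ext_rows,
        columns=[
            "family",
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene",
            "label",
            "individual",
            "carrier",
        ],
    )
    ext.to_csv(paths["extended_genotypes"], sep="\t", index=False)

    # truth (causal portion only; background alleles are family-private)
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "causal_genes": sorted(truth.causal_genes),
                "causal_gene_by_family": dict(sorted(truth.causal_gene_by_family.items())),
                "causal_carriers": {
                    f: sorted(c) for f, c in sorted(truth.causal_carriers.items())
                },
                "causal_variants": {
                    f: list(k) for f, k in sorted(truth.causal_variants.items())
                },
                "config": {
                    **{k: v for k, v in asdict(config).items() if k != "maf_spectrum"},
                    "maf_spectrum": asdict(config.maf_spectrum),
                },
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)
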
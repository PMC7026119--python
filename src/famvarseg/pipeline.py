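"""End-to-end orchestration: simulate -> filter -> segregate -> kinship ->
association -> enrichment, with one YAML config, one seed and a run manifest.

Each stage writes its outputs into a numbered subdirectory of the run
directory and consumes only files written by earlier stages, so any stage
can be re-run standalone.  The manifest records the config snapshot, the
seed, SHA-256 digests of every stage file and per-stage wall times; a fixed
config + seed reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from famvarseg import association, enrichment, kinship, segregation
from famvarseg.core_io import (
    Pedigree,
    read_annotations,
    read_calls,
    read_covariates,
    read_expression,
    read_gene_sets,
    read_pedigrees,
    read_targets,
)
from famvarseg.filters import FilterConfig, shared_candidates
from famvarseg.simulate import MafSpectrum, SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_all", "report", "load_config"]


@dataclass
class PipelineConfig:
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_families: int = 2
    max_affected_noncarriers: int = 1
    max_unaffected_carriers: int = 1
    expression_threshold: float = 0.5
    kinship_maf_threshold: float = 0.001
    kinship_target_distance: int = 100
    kinship_alert_threshold: float = 0.03
    assoc_n_sims: int = 100_000
    enrich: enrichment.MatchingConfig = field(
        default_factory=enrichment.MatchingConfig
    )
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognized sections: ``simulate``, ``filter``, ``enrich`` (keys are the
    corresponding dataclass fields) plus the scalar pipeline options at top
    level.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kw = dict(raw.pop("simulate", {}) or {})
    if "maf_spectrum" in sim_kw:
        sim_kw["maf_spectrum"] = MafSpectrum(**sim_kw["maf_spectrum"])
    filt_kw = dict(raw.pop("filter", {}) or {})
    if "damaging_calls" in filt_kw:
        filt_kw["damaging_calls"] = frozenset(filt_kw["damaging_calls"])
    enr_kw = dict(raw.pop("enrich", {}) or {})
    seed = raw.get("seed", 0)
    sim_kw.setdefault("seed", seed)
    cfg = PipelineConfig(
        simulate=SimulationConfig(**sim_kw),
        filter=FilterConfig(**filt_kw),
        enrich=enrichment.MatchingConfig(**enr_kw),
        **{k: v for k, v in raw.items() if k in {
            "min_families", "max_affected_noncarriers", "max_unaffected_carriers",
            "expression_threshold", "kinship_maf_threshold",
            "kinship_target_distance", "kinship_alert_threshold",
            "assoc_n_sims", "seed",
        }},
    )
    return cfg


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], elapsed: float) -> None:
        self.stages[stage] = {
            "elapsed_s": round(elapsed, 3),
            "outputs": {
                name: {"path": str(p), "sha256": _digest(p)}
                for name, p in sorted(outputs.items())
                if Path(p).is_file()
            },
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["filter"]["damaging_calls"] = sorted(cfg.filter.damaging_calls)
    return d


def run_all(config: PipelineConfig | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute every stage in cascade order; abort on the first failure."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=_config_snapshot(config))

    # -- stage 1: simulate -------------------------------------------------
    t0 = time.perf_counter()
    sim_dir = out / "01_simulate"
    sim_paths, _truth = simulate_cohort(config.simulate, sim_dir)
    manifest.record("simulate", sim_paths, time.perf_counter() - t0)

    # -- stage 2: per-family filter cascade --------------------------------
    t0 = time.perf_counter()
    filt_dir = out / "02_filter"
    filt_dir.mkdir(exist_ok=True)
    pedigrees = read_pedigrees(sim_paths["ped"])
    annotations = read_annotations(sim_paths["annotations"])
    all_candidates = []
    for ped in pedigrees:
        calls = {
            m.individual_id: read_calls(sim_dir / "vcf" / f"{m.individual_id}.vcf")
            for m in ped.sequenced_members
        }
        all_candidates.extend(shared_candidates(ped, calls, annotations, config.filter))
    cand_path = filt_dir / "candidates.tsv"
    _write_candidates(all_candidates, cand_path)
    manifest.record("filter", {"candidates": cand_path}, time.perf_counter() - t0)

    # -- stage 3: recurrence + extended segregation ------------------------
    t0 = time.perf_counter()
    seg_dir = out / "03_segregate"
    seg_dir.mkdir(exist_ok=True)
    reports = segregation.recurrence(all_candidates, config.min_families)
    genotypes = pd.read_csv(sim_paths["extended_genotypes"], sep="\t", dtype={"family": str, "individual": str, "chrom": str, "gene": str, "label": str})
    recurrent_genes = {r.gene for r in reports}
    cand_keys = {
        (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt, c.family_id)
        for c in all_candidates
        if c.gene in recurrent_genes
    }
    if len(genotypes):
        mask = [
            (row.chrom, row.pos, row.ref, row.alt, row.family) in cand_keys
            for row in genotypes.itertuples(index=False)
        ]
        genotypes = genotypes.loc[mask]
    summaries = segregation.summaries_from_genotypes(pedigrees, genotypes)
    classifications = segregation.classify_all(
        summaries, config.max_affected_noncarriers, config.max_unaffected_carriers
    )
    expression = read_expression(sim_paths["expression"])
    brain_flags = {
        r.gene: segregation.brain_expression_flag(
            r.gene, expression.loc[r.gene].to_dict(), config.expression_threshold
        )
        for r in reports
        if r.gene in expression.index
    }
    reports = segregation.attach_classification(reports, classifications, brain_flags)
    genes_path = seg_dir / "genes.tsv"
    _write_gene_reports(reports, genes_path)
    summ_path = seg_dir / "segregation_summaries.tsv"
    _write_summaries(summaries, summ_path)
    manifest.record(
        "segregate",
        {"genes": genes_path, "summaries": summ_path},
        time.perf_counter() - t0,
    )
    if not reports:
        manifest.warnings.append(
            "no recurrent genes; association and segregation tables are empty"
        )

    # -- stage 4: kinship screening ----------------------------------------
    t0 = time.perf_counter()
    kin_dir = out / "04_kinship"
    kin_dir.mkdir(exist_ok=True)
    calls_by_sample = {}
    for ped in pedigrees:
        for m in ped.sequenced_members:
            calls_by_sample[m.individual_id] = read_calls(
                sim_dir / "vcf" / f"{m.individual_id}.vcf"
            )
    targets = read_targets(sim_paths["targets"])
    estimates = kinship.pairwise_sharing(
        calls_by_sample,
        annotations,
        targets,
        config.kinship_maf_threshold,
        config.kinship_target_distance,
    )
    kin_path = kin_dir / "kinship.tsv"
    _write_kinship(estimates, kin_path, pedigrees, config.kinship_alert_threshold)
    manifest.record("kinship", {"kinship": kin_path}, time.perf_counter() - t0)

    # -- stage 5: family-based association ----------------------------------
    t0 = time.perf_counter()
    assoc_dir = out / "05_assoc"
    assoc_dir.mkdir(exist_ok=True)
    ped_by_id = {p.family_id: p for p in pedigrees}
    assoc_results = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    tested = sorted(
        {
            (row.family, row.gene, row.label)
            for row in genotypes.itertuples(index=False)
        }
        if len(genotypes)
        else set()
    )
    for fam, gene, label in tested:
        sub = genotypes[
            (genotypes["family"] == fam)
            & (genotypes["gene"] == gene)
            & (genotypes["label"] == label)
        ]
        status = {str(r.individual): bool(r.carrier) for r in sub.itertuples(index=False)}
        if not any(status.values()):
            continue
        assoc_results.append(
            association.gene_drop_test(
                ped_by_id[str(fam)],
                status,
                n_sims=config.assoc_n_sims,
                rng=rng,
                gene=str(gene),
                label=str(label),
            )
        )
    n_tests = max(len(assoc_results), 1)
    assoc_results = [
        dataclasses.replace(
            r,
            p_corrected=association.bonferroni(r.p_nominal, n_tests),
            n_tests=n_tests,
        )
        for r in assoc_results
    ]
    assoc_path = assoc_dir / "assoc.tsv"
    _write_assoc(assoc_results, assoc_path)
    manifest.record("assoc", {"assoc": assoc_path}, time.perf_counter() - t0)

    # -- stage 6: gene-set enrichment ---------------------------------------
    t0 = time.perf_counter()
    enr_dir = out / "06_enrich"
    enr_dir.mkdir(exist_ok=True)
    candidate_genes = sorted({c.gene for c in all_candidates})
    enr_path = enr_dir / "enrichment.tsv"
    if candidate_genes:
        universe = read_covariates(sim_paths["covariates"])
        gene_sets = read_gene_sets(sim_paths["gene_sets"])
        enr_results = enrichment.enrich_all(
            candidate_genes,
            gene_sets,
            universe,
            config.enrich,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 6])),
        )
    else:
        enr_results = []
        manifest.warnings.append("no candidate genes; enrichment skipped")
    _write_enrichment(enr_results, enr_path)
    manifest.record("enrich", {"enrichment": enr_path}, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    report_text = report(
        candidates=all_candidates,
        gene_reports=reports,
        classifications=classifications,
        enrichment_results=enr_results,
        kinship_estimates=estimates,
        pedigrees=pedigrees,
    )
    (out / "report.txt").write_text(report_text)
    return manifest


# ---------------------------------------------------------------------------
# Writers


def _write_candidates(candidates, path: Path) -> None:
    rows = [
        {
            "family": c.family_id,
            "gene": c.gene,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "label": c.label,
            "consequence": c.variant.consequence,
            "ref_maf": "NA" if c.variant.ref_maf is None else f"{c.variant.ref_maf:.6g}",
            "carriers": ",".join(sorted(c.carrier_samples)),
            "filter_trail": ";".join(f"{n}={'pass' if ok else 'fail'}" for n, ok in c.filter_trail),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "family", "gene", "chrom", "pos", "ref", "alt", "label",
            "consequence", "ref_maf", "carriers", "filter_trail",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_gene_reports(reports, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "families": ",".join(r.families),
                "n_families": len(r.families),
                "n_variants": r.n_variants,
                "variant_level_recurrent": int(r.variant_level_recurrent),
                "penetrance_class": r.penetrance_class or "NA",
                "brain_expressed": "NA" if r.brain_expressed is None else int(r.brain_expressed),
            }
            for r in reports
        ],
        columns=[
            "gene", "families", "n_families", "n_variants",
            "variant_level_recurrent", "penetrance_class", "brain_expressed",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_summaries(summaries, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": s.gene,
                "family": s.family_id,
                "label": s.label,
                "bd": f"{s.bd_carriers}/{s.bd_total}",
                "other_psy": f"{s.psy_carriers}/{s.psy_total}",
                "unaffected": f"{s.unaff_carriers}/{s.unaff_total}",
            }
            for s in summaries
        ],
        columns=["gene", "family", "label", "bd", "other_psy", "unaffected"],
    ).to_csv(path, sep="\t", index=False)


def _write_kinship(estimates, path: Path, pedigrees, alert_threshold: float) -> None:
    fam = {m.individual_id: p.family_id for p in pedigrees for m in p.members}
    pd.DataFrame(
        [
            {
                "sample_a": e.sample_a,
                "sample_b": e.sample_b,
                "family_a": fam.get(e.sample_a, "NA"),
                "family_b": fam.get(e.sample_b, "NA"),
                "n_shared": e.n_shared,
                "n_union": e.n_union,
                "shared_fraction": f"{e.shared_fraction:.6f}",
                "denominator": kinship.DENOMINATOR,
                "alert": int(
                    fam.get(e.sample_a) != fam.get(e.sample_b)
                    and e.shared_fraction > alert_threshold
                ),
                "warning": int(e.warning),
            }
            for e in estimates
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_assoc(results, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "family": r.family_id,
                "gene": r.gene,
                "label": r.label,
                "statistic": r.statistic,
                "p_nominal": f"{r.p_nominal:.6g}",
                "p_corrected": f"{r.p_corrected:.6g}",
                "n_tests": r.n_tests,
                "n_sims": r.n_sims,
                "method": r.method,
            }
            for r in results
        ],
        columns=[
            "family", "gene", "label", "statistic", "p_nominal",
            "p_corrected", "n_tests", "n_sims", "method",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_enrichment(results, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_set": r.name,
                "size": r.size,
                "n_observed": r.n_observed,
                "n_expected": f"{r.n_expected:.2f}",
                "p_value": f"{r.p_empirical:.6g}",
                "p_value_adj": "NA" if r.p_adjusted is None else f"{r.p_adjusted:.6g}",
            }
            for r in results
        ],
        columns=["gene_set", "size", "n_observed", "n_expected", "p_value", "p_value_adj"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reporting


def report(
    candidates=None,
    gene_reports=None,
    classifications=None,
    enrichment_results=None,
    kinship_estimates=None,
    pedigrees: list[Pedigree] | None = None,
) -> str:
    """Deterministic human-readable summary of whatever stage outputs exist."""
    lines: list[str] = ["# Cohort analysis summary", ""]
    if pedigrees is not None:
        n_seq = sum(len(p.sequenced_members) for p in pedigrees)
        lines.append(f"Families analysed: {len(pedigrees)} ({n_seq} sequenced members)")
    if candidates is not None:
        fams = {c.family_id for c in candidates}
        genes = {c.gene for c in candidates}
        lines += [
            f"Candidate variants surviving the cascade: {len(candidates)}",
            f"  spanning {len(genes)} genes in {len(fams)} families",
        ]
    if gene_reports is not None:
        lines.append(f"Recurrent genes (>=2 families): {len(gene_reports)}")
        n_var = sum(r.n_variants for r in gene_reports)
        lines.append(f"  variants in recurrent genes: {n_var}")
        if classifications:
            high = sorted(g for g, c in classifications.items() if c == "HIGH")
            low = sorted(g for g, c in classifications.items() if c == "LOW")
            lines.append(
                f"  cosegregation HIGH: {len(high)} ({', '.join(high) or '-'})"
            )
            lines.append(f"  cosegregation LOW: {len(low)} ({', '.join(low) or '-'})")
        flagged = [r for r in gene_reports if r.brain_expressed]
        if any(r.brain_expressed is not None for r in gene_reports):
            lines.append(
                f"  brain-expressed: {len(flagged)} of {len(gene_reports)}"
            )
    if kinship_estimates is not None and pedigrees is not None and kinship_estimates:
        try:
            mx = kinship.max_interfamily_sharing(kinship_estimates, pedigrees)
            lines.append(f"Max inter-family rare-allele sharing: {100 * mx:.2f}%")
        except ValueError:
            pass
    if enrichment_results is not None:
        lines.append(f"Gene sets tested: {len(enrichment_results)}")
        for r in sorted(enrichment_results, key=lambda r: r.p_empirical):
            adj = "NA" if r.p_adjusted is None else f"{r.p_adjusted:.4g}"
            lines.append(
                f"  {r.name}: observed {r.n_observed} vs expected "
                f"{r.n_expected:.1f}, p={r.p_empirical:.4g}, p_adj={adj}"
            )
    if candidates is not None and len(candidates) == 0:
        lines.append("No candidates at any level; downstream tables are empty.")
    return "\n".join(lines) + "\n"
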
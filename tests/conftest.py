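"""Shared fixtures: hand-built pedigrees, tiny VCFs, and a session cohort."""

from __future__ import annotations

import pytest
from hypothesis import settings

from famvarseg.core_io import Individual, Pedigree
from famvarseg.simulate import SimulationConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_nuclear(
    n_children: int = 4,
    child_phenos: tuple[str, ...] = ("BD1", "BD1", "UNAFFECTED", "BD2"),
    father_pheno: str = "UNAFFECTED",
    mother_pheno: str = "BD1",
    family_id: str = "fam",
) -> Pedigree:
    members = [
        Individual("F", family_id, None, None, "male", father_pheno, True, False),
        Individual("M", family_id, None, None, "female", mother_pheno, True, False),
    ]
    for i in range(n_children):
        members.append(
            Individual(
                f"C{i}", family_id, "F", "M",
                "male" if i % 2 == 0 else "female",
                child_phenos[i % len(child_phenos)], True, False,
            )
        )
    return Pedigree(family_id, members)


@pytest.fixture
def nuclear_family() -> Pedigree:
    return make_nuclear()


def write_vcf(path, sample_id: str, rows, extra_format: bool = True) -> None:
    """rows: (chrom, pos, ref, alts, gt, dp, ad-tuple)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({r[0] for r in rows})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if extra_format:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for chrom, pos, ref, alts, gt, dp, ad in rows:
            if extra_format:
                fmt = "GT:DP:AD"
                sample = f"{gt}:{dp}:{','.join(map(str, ad))}"
            else:
                fmt = "GT"
                sample = gt
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\t{fmt}\t{sample}\n"
            )


@pytest.fixture(scope="session")
def cohort27(tmp_path_factory):
    """Full-size deterministic synthetic cohort: 27 families, penetrance 1."""
    out = tmp_path_factory.mktemp("cohort27")
    config = SimulationConfig(
        n_families=27, causal_penetrance=1.0, phenocopy_rate=0.0, seed=11
    )
    paths, truth = simulate_cohort(config, out)
    return config, paths, truth


@pytest.fixture(scope="session")
def cohort_small(tmp_path_factory):
    """Small cohort for pipeline-level tests (6 families, 3 causal genes)."""
    out = tmp_path_factory.mktemp("cohort_small")
    config = SimulationConfig(
        n_families=6,
        causal_gene_count=3,
        causal_penetrance=1.0,
        phenocopy_rate=0.0,
        n_genes=1200,
        seed=3,
    )
    paths, truth = simulate_cohort(config, out)
    return config, paths, truth
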
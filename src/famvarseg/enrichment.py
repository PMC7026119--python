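"""Covariate-matched permutation gene-set enrichment.

For a candidate gene list, null gene lists of equal size are drawn from the
set of genes captured by the study, matching each candidate 1:1 on three
confounders: cumulative exon length (+/- 20% relative), mean sequencing
coverage (+/- 20% relative), and missense-constraint z score (+/- 0.5
absolute; the z window is widened geometrically when no match exists,
because z is unbounded and a relative window is ill-defined near zero).
The overlap of each null list with a gene set, over N permutations, yields
an add-one empirical p-value; Benjamini-Hochberg step-up FDR is applied
jointly across all tested sets.

Null genes are distinct within one permutation (sampling without
replacement) and independent across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from famvarseg.core_io import GeneSet

__all__ = [
    "MatchingConfig",
    "EnrichmentResult",
    "MatchingError",
    "match_candidates",
    "permutation_test",
    "enrich_all",
    "bh_adjust",
]


class MatchingError(ValueError):
    """No eligible matched gene for a candidate, even after relaxation."""


@dataclass(frozen=True)
class MatchingConfig:
    n_permutations: int = 10_000
    exon_length_tol: float = 0.2  # relative
    coverage_tol: float = 0.2  # relative
    constraint_z_tol: float = 0.5  # absolute
    z_relax_factor: float = 2.0
    z_relax_max: int = 3  # staged relaxations before giving up
    match_mode: str = "per_candidate"  # or "set_level"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for tol in (self.exon_length_tol, self.coverage_tol, self.constraint_z_tol):
            if tol <= 0:
                raise ValueError("tolerances must be positive")
        if self.match_mode not in ("per_candidate", "set_level"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    n_observed: int
    n_expected: float
    p_empirical: float
    p_adjusted: float | None = None


#: Per-stage widening of the proportional windows once the z window is
#: already at its maximum (stages z_relax_max+1 ...).
_PROPORTIONAL_RELAX = 1.5


def _eligibility(
    candidates: list[str],
    universe: pd.DataFrame,
    config: MatchingConfig,
) -> tuple[list[np.ndarray], list[int]]:
    """Matchable universe genes per candidate, with relaxation levels.

    The universe frame must be indexed by gene and contain ``exon_length``,
    ``coverage`` and ``constraint_z``; candidate genes themselves must have
    covariate rows too (they define the windows) but are excluded from the
    returned pools.

    Returns integer index arrays into the non-candidate pool and, per
    candidate, the relaxation stage used: 0 = nominal windows, 1..z_relax_max
    = z window doubled that many times, beyond that the proportional windows
    widen by 1.5x per extra stage (at most 3 extra stages; candidates with
    extreme covariates in a small universe would otherwise be unmatchable).
    """
    missing = [g for g in candidates if g not in universe.index]
    if missing:
        raise MatchingError(f"no covariates for candidate gene {missing[0]}")
    pool = universe.loc[~universe.index.isin(candidates)]
    exon = pool["exon_length"].to_numpy(dtype=float)
    cov = pool["coverage"].to_numpy(dtype=float)
    z = pool["constraint_z"].to_numpy(dtype=float)

    out: list[np.ndarray] = []
    stages: list[int] = []
    max_stage = config.z_relax_max + 3
    for gene in candidates:
        row = universe.loc[gene]
        e, c, zz = float(row["exon_length"]), float(row["coverage"]), float(
            row["constraint_z"]
        )
        eligible = None
        for stage in range(max_stage + 1):
            ztol = config.constraint_z_tol * config.z_relax_factor ** min(
                stage, config.z_relax_max
            )
            widen = _PROPORTIONAL_RELAX ** max(0, stage - config.z_relax_max)
            trial = (
                (np.abs(exon - e) <= config.exon_length_tol * widen * e)
                & (np.abs(cov - c) <= config.coverage_tol * widen * c)
                & (np.abs(z - zz) <= ztol)
            )
            if trial.any():
                eligible = trial
                stages.append(stage)
                break
        if eligible is None:
            raise MatchingError(
                f"no matchable gene for candidate {gene} "
                f"(windows relaxed {max_stage} times)"
            )
        out.append(np.flatnonzero(eligible))
    if config.match_mode == "set_level":
        union = np.unique(np.concatenate(out))
        out = [union for _ in candidates]
        stages = [max(stages)] * len(candidates)
    return out, stages


def _max_stage_pools(
    candidates: list[str],
    universe: pd.DataFrame,
    config: MatchingConfig,
) -> list[np.ndarray]:
    """Eligible pools at the fully relaxed windows (fallback for draws where
    a scarce pool was exhausted by earlier candidates in the same
    permutation)."""
    pool = universe.loc[~universe.index.isin(candidates)]
    exon = pool["exon_length"].to_numpy(dtype=float)
    cov = pool["coverage"].to_numpy(dtype=float)
    z = pool["constraint_z"].to_numpy(dtype=float)
    ztol = config.constraint_z_tol * config.z_relax_factor**config.z_relax_max
    widen = _PROPORTIONAL_RELAX**3
    out = []
    for gene in candidates:
        row = universe.loc[gene]
        e, c, zz = float(row["exon_length"]), float(row["coverage"]), float(
            row["constraint_z"]
        )
        out.append(
            np.flatnonzero(
                (np.abs(exon - e) <= config.exon_length_tol * widen * e)
                & (np.abs(cov - c) <= config.coverage_tol * widen * c)
                & (np.abs(z - zz) <= ztol)
            )
        )
    return out


def match_candidates(
    candidates: list[str],
    universe: pd.DataFrame,
    config: MatchingConfig = MatchingConfig(),
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Draw one covariate-matched null gene list (distinct genes)."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    eligible, _stages = _eligibility(candidates, universe, config)
    pool_genes = universe.index[~universe.index.isin(candidates)].to_numpy()
    idx = _draw_one(eligible, rng, candidates)
    return [str(pool_genes[i]) for i in idx]


def _draw_one(
    eligible: list[np.ndarray],
    rng: np.random.Generator,
    candidates: list[str],
    order: list[int] | None = None,
    fallback: list[np.ndarray] | None = None,
) -> list[int]:
    """Draw one distinct matched gene per candidate.

    Candidates are visited scarcest-pool-first (``order``) so that a
    candidate with few eligible matches is not starved by earlier draws;
    when its pool is nevertheless exhausted, the fully relaxed window
    (``fallback``) is tried before giving up.
    """
    used: set[int] = set()
    drawn: dict[int, int] = {}
    for i in order if order is not None else range(len(eligible)):
        pool = eligible[i]
        pick = -1
        for _ in range(8):  # rejection sampling; pools are rarely exhausted
            j = int(pool[rng.integers(len(pool))])
            if j not in used:
                pick = j
                break
        if pick < 0:
            free = np.setdiff1d(pool, np.fromiter(used, dtype=int), assume_unique=False)
            if len(free) == 0 and fallback is not None:
                free = np.setdiff1d(
                    fallback[i], np.fromiter(used, dtype=int), assume_unique=False
                )
            if len(free) == 0:
                raise MatchingError(
                    f"matched pool exhausted for candidate {candidates[i]}"
                )
            pick = int(free[rng.integers(len(free))])
        used.add(pick)
        drawn[i] = pick
    return [drawn[i] for i in range(len(eligible))]


def permutation_test(
    candidates: list[str],
    gene_set: GeneSet,
    universe: pd.DataFrame,
    config: MatchingConfig = MatchingConfig(),
    rng: np.random.Generator | int | None = None,
) -> EnrichmentResult:
    """Matched-permutation enrichment of ``candidates`` in one gene set."""
    results = enrich_all(candidates, [gene_set], universe, config, rng, adjust=False)
    return results[0]


def enrich_all(
    candidates: list[str],
    gene_sets: list[GeneSet],
    universe: pd.DataFrame,
    config: MatchingConfig = MatchingConfig(),
    rng: np.random.Generator | int | None = None,
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Run the permutation test against every gene set with shared null draws.

    One matched null list per permutation is scored against all sets, which
    both saves time and mirrors a single null ensemble correction; BH is
    applied across the resulting p-values when ``adjust`` is set.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    candidates = list(dict.fromkeys(candidates))
    eligible, _stages = _eligibility(candidates, universe, config)
    order = sorted(range(len(candidates)), key=lambda i: (len(eligible[i]), i))
    fallback = _max_stage_pools(candidates, universe, config)
    pool_genes = universe.index[~universe.index.isin(candidates)].to_numpy()

    membership = np.zeros((len(gene_sets), len(pool_genes)), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(pool_genes)}
    for si, gs in enumerate(gene_sets):
        for g in gs.members:
            pos = gene_pos.get(g)
            if pos is not None:
                membership[si, pos] = True

    observed = np.array(
        [sum(g in gs.members for g in candidates) for gs in gene_sets], dtype=int
    )
    n_perm = config.n_permutations
    null_counts = np.zeros((n_perm, len(gene_sets)), dtype=np.int32)
    for p in range(n_perm):
        idx = _draw_one(eligible, rng, candidates, order, fallback)
        null_counts[p] = membership[:, idx].sum(axis=1)

    exceed = (null_counts >= observed[None, :]).sum(axis=0)
    p_emp = (1 + exceed) / (n_perm + 1)
    expected = null_counts.mean(axis=0)

    adjusted = bh_adjust(list(p_emp)) if adjust else [None] * len(gene_sets)
    return [
        EnrichmentResult(
            name=gs.name,
            size=len(gs.members),
            n_observed=int(observed[i]),
            n_expected=float(expected[i]),
            p_empirical=float(p_emp[i]),
            p_adjusted=None if adjusted[i] is None else float(adjusted[i]),
        )
        for i, gs in enumerate(gene_sets)
    ]


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(q) for q in stats.false_discovery_control(arr, method="bh")]
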
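"""Per-binding-site mutation burden score and its resampling null.

The observed site score is s_b = sum over mutated site residues of
b_i x (number of distinct samples with a missense mutation at residue
i). The null redistributes the sequence's m missense events uniformly
(with replacement) over its structural positions; the empirical
p-value is the fraction of replicates whose score is at least the
observed one. P-values are converted to FDRs with the
Benjamini-Hochberg step-up procedure across all sites of a run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from mutbind.types import MappedBindingSite, ProteinMutation, SiteTestResult

_SCORE_TIE_TOL = 1e-9


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the resampling null.

    tie_convention: whether a replicate score equal to the observed one
    counts toward the p-value ("geq", the conservative default) or not
    ("gt"). m_mode: whether m counts every mutation event at structural
    positions ("events", default) or distinct (sample, position) pairs
    ("distinct_pairs").
    """

    replicates: int = 100_000
    rng_seed: int = 0
    tie_convention: str = "geq"
    m_mode: str = "events"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.tie_convention not in ("geq", "gt"):
            raise ValueError(f"unknown tie_convention {self.tie_convention!r}")
        if self.m_mode not in ("events", "distinct_pairs"):
            raise ValueError(f"unknown m_mode {self.m_mode!r}")


def site_seed(master_seed: int, refseq_id: str, site_id: str) -> np.random.SeedSequence:
    """Deterministic per-site seed so results do not depend on the
    order in which sites are tested."""
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF,
         zlib.crc32(refseq_id.encode()),
         zlib.crc32(site_id.encode())]
    )


def site_score(site: MappedBindingSite, mutations: Iterable[ProteinMutation]) -> float:
    """Observed s_b; repeated mutations of one residue in the same
    sample count once (distinct-sample convention)."""
    samples_at: dict[int, set[str]] = {}
    for mut in mutations:
        if mut.var_class != "missense" or mut.gene_id != site.refseq_id:
            continue
        if mut.protein_pos in site.positions:
            samples_at.setdefault(mut.protein_pos, set()).add(mut.sample_id)
    return float(
        sum(site.binding_scores[pos] * len(s) for pos, s in samples_at.items())
    )


def count_structural_events(
    mutations: Iterable[ProteinMutation],
    refseq_id: str,
    structural_positions: set[int],
    m_mode: str = "events",
) -> int:
    """m: missense mutation events of a sequence that hit structural
    positions, counted with sample multiplicity (or as distinct
    (sample, position) pairs)."""
    hits = [
        (mut.sample_id, mut.protein_pos)
        for mut in mutations
        if mut.var_class == "missense"
        and mut.gene_id == refseq_id
        and mut.protein_pos in structural_positions
    ]
    return len(set(hits)) if m_mode == "distinct_pairs" else len(hits)


def permutation_test(
    s_obs: float,
    structural_positions: Sequence[int] | set[int],
    binding_scores: Mapping[int, float],
    m: int,
    cfg: PermutationConfig,
    seed_sequence: np.random.SeedSequence | None = None,
) -> float:
    """Empirical p-value of an observed site score.

    Each replicate draws m positions uniformly with replacement from
    the structural positions and sums their binding scores (zero off
    site). With m = 0 the p-value is 1; a zero replicate count is
    floored at 1/R so p stays in (0, 1].
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return 1.0
    positions = sorted(structural_positions)
    if not positions:
        raise ValueError("no structural positions but m > 0")
    b_arr = np.array([binding_scores.get(p, 0.0) for p in positions], dtype=float)
    rng = np.random.default_rng(seed_sequence if seed_sequence is not None
                                else cfg.rng_seed)
    R = cfg.replicates
    count = 0
    chunk = max(1, min(R, 20_000_000 // max(m, 1)))
    done = 0
    while done < R:
        size = min(chunk, R - done)
        idx = rng.integers(0, len(positions), size=(size, m))
        sums = b_arr[idx].sum(axis=1)
        if cfg.tie_convention == "geq":
            count += int(np.sum(sums >= s_obs - _SCORE_TIE_TOL))
        else:
            count += int(np.sum(sums > s_obs + _SCORE_TIE_TOL))
        done += size
    return max(count, 1) / R


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def evaluate_sites(
    sites: Iterable[MappedBindingSite],
    mutations: Iterable[ProteinMutation],
    structural_positions: dict[str, set[int]],
    cfg: PermutationConfig,
    cohort: str = "ALL",
) -> list[SiteTestResult]:
    """Score and test every site against its sequence's null; FDR is
    computed across all sites of this call (one cohort run)."""
    mutations = list(mutations)
    by_refseq: dict[str, list[ProteinMutation]] = {}
    for mut in mutations:
        by_refseq.setdefault(mut.gene_id, []).append(mut)

    results: list[SiteTestResult] = []
    for site in sorted(sites, key=lambda s: (s.refseq_id, s.site_id)):
        muts = by_refseq.get(site.refseq_id, [])
        universe = structural_positions.get(site.refseq_id, set())
        m = count_structural_events(muts, site.refseq_id, universe, cfg.m_mode)
        s_obs = site_score(site, muts)
        p = permutation_test(
            s_obs,
            universe,
            site.binding_scores,
            m,
            cfg,
            seed_sequence=site_seed(cfg.rng_seed, site.refseq_id, site.site_id),
        )
        mutated = {
            mut.protein_pos
            for mut in muts
            if mut.var_class == "missense" and mut.protein_pos in site.positions
        }
        results.append(
            SiteTestResult(
                refseq_id=site.refseq_id,
                site_id=site.site_id,
                category=site.category,
                cohort=cohort,
                n_binding_residues=len(site.positions),
                mutated_binding_positions=len(mutated),
                m=m,
                s_b=s_obs,
                p_empirical=p,
            )
        )
    fdrs = bh_fdr([r.p_empirical for r in results])
    return [
        SiteTestResult(**{**r.__dict__, "fdr": fdr})
        for r, fdr in zip(results, fdrs)
    ]
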
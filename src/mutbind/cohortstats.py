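"""Cohort-level burden statistics.

Position-wise hypergeometric tests compare how often binding residues
are hit by a variant class relative to all residues with structural
information (upper tail for cancer missense, lower tail for population
SNPs), a frequency-aware binomial companion test counts events rather
than positions, and the known-cancer-gene enrichment curve sweeps
significance thresholds over the per-site test results.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from mutbind.types import (
    EnrichmentPoint,
    GlobalCounts,
    MappedBindingSite,
    ProteinMutation,
    SiteTestResult,
)


def assemble_counts(
    sites: Iterable[MappedBindingSite],
    structural_positions: dict[str, set[int]],
    variants: Iterable[ProteinMutation],
    var_class: str,
    category: Optional[str] = None,
) -> GlobalCounts:
    """Pool the (N, K, n, k) quadruple over all reference sequences.

    Positions are counted once regardless of how often they are hit.
    With ``category`` set, K and k are restricted to binding residues
    of that ligand category while N and n keep the full structural
    background (the per-category variant of the same test).
    """
    binding: dict[str, set[int]] = {}
    for site in sites:
        if category is not None and site.category != category:
            continue
        binding.setdefault(site.refseq_id, set()).update(site.positions)

    hit: dict[str, set[int]] = {}
    for v in variants:
        if v.var_class != var_class:
            continue
        universe = structural_positions.get(v.gene_id)
        if universe and v.protein_pos in universe:
            hit.setdefault(v.gene_id, set()).add(v.protein_pos)

    N = sum(len(p) for p in structural_positions.values())
    K = sum(len(binding.get(r, set()) & p) for r, p in structural_positions.items())
    n = sum(len(h) for h in hit.values())
    k = sum(len(hit.get(r, set()) & binding.get(r, set())) for r in structural_positions)
    return GlobalCounts(N=N, K=K, n=n, k=k)


def hypergeom_tail(counts: GlobalCounts, tail: str) -> float:
    """Exact hypergeometric tail probability at the observed k.

    upper: P(X >= k), used for cancer missense mutations;
    lower: P(X <= k), used for SNPs.
    """
    dist = stats.hypergeom(M=counts.N, n=counts.K, N=counts.n)
    if tail == "upper":
        return float(dist.sf(counts.k - 1))
    if tail == "lower":
        return float(dist.cdf(counts.k))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def binomial_frequency_test(
    binding_events: int, total_events: int, q: float
) -> float:
    """Upper-tail binomial P(X >= binding_events | total_events, q).

    The frequency-aware companion to the position-wise test: events are
    counted with multiplicity, and q is the fraction of structural
    residues that are binding residues.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if binding_events > total_events:
        raise ValueError("binding_events cannot exceed total_events")
    if total_events == 0:
        return 1.0
    return float(stats.binomtest(binding_events, total_events, q, alternative="greater").pvalue)


def binding_fraction(
    sites: Iterable[MappedBindingSite],
    structural_positions: dict[str, set[int]],
) -> float:
    """Fraction of residues with structural information that are
    binding residues (the q of the binomial test)."""
    counts = assemble_counts(sites, structural_positions, [], var_class="missense")
    return counts.K / counts.N if counts.N else 0.0


def enrichment_ratio(
    selected_genes: int, ccg_in_selected: int, total: int, ccg_total: int
) -> Optional[float]:
    """(fraction of known cancer genes among selected) over (fraction
    in the background); None when a denominator vanishes."""
    if selected_genes == 0 or total == 0 or ccg_total == 0:
        return None
    return (ccg_in_selected / selected_genes) / (ccg_total / total)


def ccg_enrichment_curve(
    site_results: Sequence[SiteTestResult],
    ccg_genes: set[str],
    thresholds: Optional[Sequence[float]] = None,
    background_unit: str = "sites",
    quantile_levels: Sequence[float] = (0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0),
) -> list[EnrichmentPoint]:
    """Known-cancer-gene enrichment at progressively smaller p-value
    thresholds.

    At each threshold, genes with at least one binding site at
    p <= threshold are selected. The background is every mutated
    binding site (``background_unit="sites"``) or every gene with a
    mutated binding site (``"genes"``); thresholds default to quantiles
    of the observed site p-value distribution.
    """
    if background_unit not in ("sites", "genes"):
        raise ValueError(f"unknown background_unit {background_unit!r}")
    mutated = [r for r in site_results if r.mutated_binding_positions >= 1]
    if thresholds is None:
        pvals = np.array([r.p_empirical for r in mutated])
        thresholds = sorted(set(float(q) for q in np.quantile(pvals, quantile_levels))) if len(pvals) else []

    background_genes = {r.refseq_id for r in mutated}
    if background_unit == "sites":
        total = len(mutated)
        ccg_total = sum(1 for r in mutated if r.refseq_id in ccg_genes)
    else:
        total = len(background_genes)
        ccg_total = len(background_genes & ccg_genes)

    points = []
    for thr in thresholds:
        selected = {r.refseq_id for r in mutated if r.p_empirical <= thr}
        ccg_sel = len(selected & ccg_genes)
        points.append(
            EnrichmentPoint(
                p_threshold=float(thr),
                selected_genes=len(selected),
                ccg_in_selected=ccg_sel,
                total_genes=total,
                ccg_total=ccg_total,
                enrichment_ratio=enrichment_ratio(len(selected), ccg_sel, total, ccg_total),
            )
        )
    return points
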
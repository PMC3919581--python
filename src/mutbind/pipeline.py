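"""Stage orchestration: map -> annotate -> site-test -> cohort-test -> enrich.

Each stage reads the previous stage's files and writes its own, so the
stages can be run standalone or in one shot with identical results.
Every output TSV carries a provenance header (package version, seed,
config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import mutbind
from mutbind import annotate, cohortstats, io as mio, mapping, sitestats
from mutbind.types import LIGAND_CATEGORIES, MutbindError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run. Threshold defaults are
    the method's canonical values."""

    # inputs
    mutations: str = "mutations.tsv"
    transcripts: str = "transcripts.tsv"
    genome: str = "genome.fa"
    biolip: str = "biolip.tsv"
    pdb_dir: str = "structures"
    homology: str = "homology/homology_hits.tsv"
    snps: Optional[str] = None  # protein-coordinate variants
    ccg: Optional[str] = None  # gene list for enrichment
    out_dir: str = "results"
    # homology / contact thresholds
    e_value_max: float = 1e-6
    identity_min: float = 0.60
    coverage_min: float = 0.80
    binding_identity_min: float = 0.90
    contact_distance: float = 4.0
    # permutation test
    replicates: int = 100_000
    seed: int = 0
    tie_convention: str = "geq"
    m_mode: str = "events"
    # cohort handling: aggregate pools all cohorts into one run
    aggregate: bool = True
    per_cohort: bool = False
    cohorts: tuple[str, ...] = ()
    background_unit: str = "sites"

    def validate(self) -> None:
        for name, lo, hi in (
            ("identity_min", 0.0, 1.0),
            ("coverage_min", 0.0, 1.0),
            ("binding_identity_min", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise MutbindError(f"config: {name}={v} outside [{lo}, {hi}]")
        if self.e_value_max <= 0:
            raise MutbindError("config: e_value_max must be positive")
        if not 0 < self.contact_distance <= 20:
            raise MutbindError("config: contact_distance must be in (0, 20] A")
        if self.replicates < 1:
            raise MutbindError("config: replicates must be >= 1")
        if not (self.aggregate or self.per_cohort):
            raise MutbindError("config: enable aggregate and/or per_cohort")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        data = mio.read_config(path)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    #: fields that affect the science (not file locations); only these
    #: enter the provenance hash so results are path-independent
    _PARAM_FIELDS = (
        "e_value_max", "identity_min", "coverage_min", "binding_identity_min",
        "contact_distance", "replicates", "seed", "tie_convention", "m_mode",
        "aggregate", "per_cohort", "cohorts", "background_unit",
    )

    def provenance(self) -> list[str]:
        params = {name: getattr(self, name) for name in self._PARAM_FIELDS}
        payload = json.dumps(params, sort_keys=True, default=list)
        digest = hashlib.sha1(payload.encode()).hexdigest()[:12]
        return [
            f"mutbind {mutbind.__version__}",
            f"seed={self.seed} replicates={self.replicates}",
            f"tie={self.tie_convention} m_mode={self.m_mode}",
            f"config_sha1={digest}",
        ]


def _out(config: RunConfig, name: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


def _require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise MutbindError(f"{what}: expected file {p} is missing")
    return p


def stage_map(config: RunConfig) -> None:
    """Genomic -> protein mapping and reference-isoform selection."""
    muts = mio.read_mutations(_require(config.mutations, "map"), dialect="maf_like")
    transcripts = mio.read_transcripts(_require(config.transcripts, "map"))
    genome = mio.GenomeStore(_require(config.genome, "map"))
    refset = mapping.build_reference_set(muts, transcripts, genome)
    header = config.provenance()
    mio.write_protein_mutations(refset.mapped, _out(config, "mapped_mutations.tsv"), header)
    mio.write_unmapped(refset.unmapped, _out(config, "unmapped.tsv"), header)
    mio.write_isoform_mappings(refset.isoform_mappings, _out(config, "isoform_selection.tsv"))
    refseqs = mapping.reference_sequences(transcripts, genome, refset.isoform_mappings)
    mio.write_refseqs(refseqs, _out(config, "refseqs.fasta"))
    logger.info(
        "map: %d mutations mapped, %d unmapped, %d reference sequences",
        len(refset.mapped), len(refset.unmapped), len(refseqs),
    )


def stage_annotate(config: RunConfig) -> None:
    """Homology filtering, binding-site transfer, merging, scoring."""
    refseqs = mio.read_refseqs(_require(Path(config.out_dir) / "refseqs.fasta", "annotate"))
    hits = mio.read_homology_hits(_require(config.homology, "annotate"))
    pdb_paths = sorted(Path(config.pdb_dir).glob("*.pdb"))
    chains, records = mio.read_structures(pdb_paths, _require(config.biolip, "annotate"))
    matches = annotate.filter_hits(
        hits, config.e_value_max, config.identity_min, config.coverage_min
    )
    sites, structural = annotate.annotate_reference(
        refseqs, matches, records, chains,
        binding_identity_min=config.binding_identity_min,
        contact_distance=config.contact_distance,
    )
    header = config.provenance()
    mio.write_sites(sites, _out(config, "sites.tsv"), header)
    mio.write_structural_positions(structural, _out(config, "structural_positions.tsv"), header)
    logger.info("annotate: %d sites on %d sequences", len(sites), len(structural))


def _cohort_runs(config: RunConfig, mutations) -> list[tuple[str, list]]:
    runs = []
    if config.aggregate:
        runs.append(("ALL", mutations))
    if config.per_cohort:
        cohorts = config.cohorts or tuple(sorted({m.cohort for m in mutations}))
        for cohort in cohorts:
            runs.append((cohort, [m for m in mutations if m.cohort == cohort]))
    return runs


def stage_site_test(config: RunConfig) -> None:
    """Permutation test of every binding site, FDR within each run."""
    sites = mio.read_sites(_require(Path(config.out_dir) / "sites.tsv", "site-test"))
    structural = mio.read_structural_positions(
        _require(Path(config.out_dir) / "structural_positions.tsv", "site-test")
    )
    mutations = mio.read_mutations(
        _require(Path(config.out_dir) / "mapped_mutations.tsv", "site-test"),
        dialect="protein_coords",
    )
    cfg = sitestats.PermutationConfig(
        replicates=config.replicates, rng_seed=config.seed,
        tie_convention=config.tie_convention, m_mode=config.m_mode,
    )
    header = config.provenance()
    for cohort, muts in _cohort_runs(config, mutations):
        results = sitestats.evaluate_sites(sites, muts, structural, cfg, cohort=cohort)
        mio.write_site_results(results, _out(config, f"site_results_{cohort}.tsv"), header)
        logger.info("site-test[%s]: %d sites tested", cohort, len(results))


def stage_cohort_test(config: RunConfig) -> None:
    """Position-wise hypergeometric and frequency binomial burden tests."""
    sites = mio.read_sites(_require(Path(config.out_dir) / "sites.tsv", "cohort-test"))
    structural = mio.read_structural_positions(
        _require(Path(config.out_dir) / "structural_positions.tsv", "cohort-test")
    )
    mutations = mio.read_mutations(
        _require(Path(config.out_dir) / "mapped_mutations.tsv", "cohort-test"),
        dialect="protein_coords",
    )
    variant_sets = {"missense": mutations, "synonymous": mutations}
    if config.snps:
        variant_sets["snp"] = mio.read_mutations(config.snps, dialect="protein_coords")
    rows = []
    q = cohortstats.binding_fraction(sites, structural)
    for label, variants in variant_sets.items():
        var_class = "missense" if label == "snp" else label
        for category in (None, *LIGAND_CATEGORIES):
            counts = cohortstats.assemble_counts(
                sites, structural, variants, var_class, category
            )
            row = {
                "var_class": label,
                "category": category or "ALL",
                "N": counts.N, "K": counts.K, "n": counts.n, "k": counts.k,
                "p_upper": cohortstats.hypergeom_tail(counts, "upper"),
                "p_lower": cohortstats.hypergeom_tail(counts, "lower"),
                "p_binomial": None,
            }
            if label != "snp" and category is None:
                # frequency-aware companion test (events with multiplicity)
                events = [
                    v for v in variants
                    if v.var_class == var_class
                    and v.protein_pos in structural.get(v.gene_id, set())
                ]
                binding = {
                    r: {p for s in sites if s.refseq_id == r for p in s.positions}
                    for r in structural
                }
                n_binding = sum(
                    1 for v in events if v.protein_pos in binding.get(v.gene_id, set())
                )
                row["events_total"] = len(events)
                row["events_binding"] = n_binding
                row["p_binomial"] = cohortstats.binomial_frequency_test(
                    n_binding, len(events), q
                )
            rows.append(row)
    mio.write_global_counts(rows, _out(config, "global_counts.tsv"), config.provenance())
    logger.info("cohort-test: %d rows", len(rows))


def stage_enrich(config: RunConfig) -> None:
    """Known-cancer-gene enrichment sweep over the aggregate results."""
    if not config.ccg:
        logger.info("enrich: no gene list configured, skipping")
        return
    results_path = Path(config.out_dir) / "site_results_ALL.tsv"
    if not results_path.exists():
        candidates = sorted(Path(config.out_dir).glob("site_results_*.tsv"))
        if not candidates:
            raise MutbindError(f"enrich: expected file {results_path} is missing")
        results_path = candidates[0]
    results = mio.read_site_results(results_path)
    ccg = mio.read_gene_list(config.ccg)
    points = cohortstats.ccg_enrichment_curve(
        results, ccg, background_unit=config.background_unit
    )
    mio.write_enrichment_curve(points, _out(config, "enrichment_curve.tsv"), config.provenance())
    logger.info("enrich: %d thresholds", len(points))


_STAGES = (
    ("map", stage_map),
    ("annotate", stage_annotate),
    ("site-test", stage_site_test),
    ("cohort-test", stage_cohort_test),
    ("enrich", stage_enrich),
)


def run_pipeline(config: RunConfig) -> None:
    """Run every stage in order; any stage error aborts with its name."""
    config.validate()
    for name, stage in _STAGES:
        try:
            stage(config)
        except MutbindError:
            raise
        except Exception as exc:
            raise MutbindError(f"stage {name} failed: {exc}") from exc
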
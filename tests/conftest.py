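from pathlib import Path

import pytest

from mutbind.io import GenomeStore
from mutbind.pipeline import RunConfig
from mutbind.simulate import FixtureSpec, generate_fixture


def make_genome(tmp_path: Path, seqs: dict[str, str]) -> GenomeStore:
    """Write a FASTA and open it as a genome store."""
    path = tmp_path / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return GenomeStore(path)


def bundle_config(bundle: Path, out_dir: Path, **overrides) -> RunConfig:
    """RunConfig pointing at a generated fixture bundle."""
    defaults = dict(
        mutations=str(bundle / "mutations.tsv"),
        transcripts=str(bundle / "transcripts.tsv"),
        genome=str(bundle / "genome.fa"),
        biolip=str(bundle / "biolip.tsv"),
        pdb_dir=str(bundle / "structures"),
        homology=str(bundle / "homology" / "homology_hits.tsv"),
        snps=str(bundle / "snps.tsv"),
        ccg=str(bundle / "ccg_genes.txt"),
        out_dir=str(out_dir),
        replicates=5000,
        seed=7,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> tuple[Path, dict]:
    """A 6-gene synthetic bundle shared across tests (read-only)."""
    path = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(n_genes=6, rng_seed=1)
    manifest = generate_fixture(spec, path)
    return path, manifest
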
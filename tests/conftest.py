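import json

import numpy as np
import pytest
from hypothesis import settings

from editas import io as eio
from editas.cli import config_for_cohort
from editas.io import GeneModel, GenomicInterval
from editas.pipeline import run_pipeline
from editas.simulate import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Default synthetic cohort (seed 1), generated once per session."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(out, SimulationConfig(seed=1))
    return out


@pytest.fixture(scope="session")
def truth(cohort_dir):
    with open(cohort_dir / "truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def cohort(cohort_dir):
    """Parsed cohort inputs as in-memory objects."""
    return {
        "genome": eio.read_fasta(cohort_dir / "genome.fa"),
        "models": eio.read_gtf(cohort_dir / "genes.gtf"),
        "counts": eio.read_count_table(cohort_dir / "counts.tsv"),
        "design": eio.read_design(cohort_dir / "design.tsv"),
        "junctions": eio.read_junction_table(cohort_dir / "junctions.tsv"),
        "wes": eio.read_site_mask(cohort_dir / "wes.vcf"),
        "dbsnp": eio.read_site_mask(cohort_dir / "dbsnp.tsv"),
        "repeats": eio.read_bed_named(cohort_dir / "repeats.bed"),
        "peaks": eio.read_bed_named(cohort_dir / "eclip.bed"),
    }


@pytest.fixture(scope="session")
def run_dir(cohort_dir, tmp_path_factory):
    """One full pipeline run on the default cohort, shared across tests."""
    out = tmp_path_factory.mktemp("run")
    run_pipeline(config_for_cohort(cohort_dir), out)
    return out


@pytest.fixture()
def toy_gene():
    """Two-exon plus-strand gene with CDS leaving 10 nt UTRs, and a genome
    with canonical GT..AG intron ends."""
    exons = [GenomicInterval("chrT", 101, 160, "+"),
             GenomicInterval("chrT", 221, 280, "+")]
    cds = [GenomicInterval("chrT", 111, 160, "+"),
           GenomicInterval("chrT", 221, 270, "+")]
    model = GeneModel("G1", "G1.t1", "chrT", "+", exons, cds)
    rng = np.random.default_rng(0)
    seq = list(rng.choice(list("ACGT"), 400))
    seq[160:162] = "GT"
    seq[218:220] = "AG"
    return model, {"chrT": "".join(seq)}
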
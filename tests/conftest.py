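import gzip
from pathlib import Path

import numpy as np
import pytest

from kmerdiff.pipeline import PipelineConfig, run_pipeline
from kmerdiff.simulate import SimulationConfig, make_reference, spike_and_simulate

PIN_SEED = 1


def write_fastq(path: Path, seqs, gz=False):
    opener = (lambda p: gzip.open(p, "wt")) if gz else (lambda p: open(p, "w"))
    with opener(path) as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
    return path


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(PIN_SEED)


@pytest.fixture(scope="session")
def sim_refs(tmp_path_factory):
    """Default synthetic references (genome, annotation, transcriptome)."""
    outdir = tmp_path_factory.mktemp("simref")
    config = SimulationConfig(seed=PIN_SEED)
    refs = make_reference(config, outdir)
    return config, refs


@pytest.fixture(scope="session")
def sim_reads(sim_refs, tmp_path_factory):
    """Default spiked two-condition libraries plus truth records."""
    config, refs = sim_refs
    outdir = tmp_path_factory.mktemp("simreads")
    sheet, truth = spike_and_simulate(config, refs, outdir)
    return sheet, truth


def _pipeline_config(sim_refs, sheet, outdir, **overrides):
    _, refs = sim_refs
    kwargs = dict(
        samples=[(l, [str(p) for p in ps], c) for l, ps, c in sheet],
        output_dir=str(outdir),
        genome_fasta=str(refs.genome_fasta),
        gff3=str(refs.gff3),
        masking=str(refs.transcriptome_fasta),
        seed=PIN_SEED,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def full_run(sim_refs, sim_reads, tmp_path_factory):
    """One complete masked pipeline run on the default spiked data set."""
    sheet, truth = sim_reads
    outdir = tmp_path_factory.mktemp("run_masked")
    config = _pipeline_config(sim_refs, sheet, outdir)
    result = run_pipeline(config)
    return result, truth


@pytest.fixture(scope="session")
def nomask_run(sim_refs, sim_reads, tmp_path_factory):
    """The same data analyzed without transcriptome masking."""
    sheet, _ = sim_reads
    outdir = tmp_path_factory.mktemp("run_nomask")
    config = _pipeline_config(sim_refs, sheet, outdir, masking=None)
    # gene/DU annotation needs a masking transcriptome; without one the
    # pipeline still aligns and classifies, which is all this run is for
    return run_pipeline(config)
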
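import pytest

from isoscope.model import PipelineConfig
from isoscope.pipeline import run_pipeline
from isoscope.simulate import recovery_mixture

RECOVERY_SEED = 7


@pytest.fixture(scope="session")
def recovery_truth():
    """The standard 20-exon / 12-isoform / 2000-read recovery mixture."""
    return recovery_mixture(seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_result(recovery_truth):
    """Full pipeline run on the recovery mixture, truth alignments imported
    so correction and calling are scored independently of aligner quality."""
    truth = recovery_truth
    return run_pipeline(
        truth.reads,
        truth.locus.reference,
        PipelineConfig(seed=RECOVERY_SEED),
        alignments=truth.truth_alignments(),
    )
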
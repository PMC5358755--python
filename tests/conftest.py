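import numpy as np
import pytest

from ripflash.io_formats import TranscriptModel
from ripflash import synthetic_data as sd


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def coding_model(rng):
    """300-nt protein-coding transcript: 5'UTR 100, CDS 150, 3'UTR 50."""
    return TranscriptModel(
        "tx1", "g1", "G1", "protein_coding", _random_seq(rng, 300),
        (("utr5", 0, 100), ("cds", 100, 250), ("utr3", 250, 300)),
    )


@pytest.fixture
def tiny_models(rng):
    """A coding transcript, a miRNA and a lincRNA keyed by transcript_id."""
    coding = TranscriptModel(
        "txA", "gA", "GA", "protein_coding", _random_seq(rng, 600),
        (("utr5", 0, 100), ("cds", 100, 400), ("utr3", 400, 600)),
    )
    mirna = TranscriptModel("mirX", "mirX", "mir-x", "miRNA",
                            _random_seq(rng, 22), (("body", 0, 22),))
    linc = TranscriptModel("lincB", "gB", "LincB", "lincRNA",
                           _random_seq(rng, 400), (("body", 0, 400),))
    return {m.transcript_id: m for m in (coding, mirna, linc)}


@pytest.fixture(scope="session")
def small_study():
    """A small end-to-end synthetic study shared by read-level tests."""
    cfg = sd.SimulationConfig(seed=11, n_genes=120, n_reads_rip=20_000,
                              n_reads_input=20_000, n_reads_flash=40_000)
    models = sd.simulate_transcriptome(cfg)
    models, flash_reads, flash_truth = sd.simulate_flash_reads(cfg, models)
    rip, inp, rip_truth = sd.simulate_rip_reads(cfg, models)
    return dict(cfg=cfg, models=models, flash_reads=flash_reads,
                flash_truth=flash_truth, rip=rip, inp=inp, rip_truth=rip_truth)
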
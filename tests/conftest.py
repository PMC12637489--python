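import pytest

from turboprox import ProteinQuantRecord, SimulationConfig

CHANNELS = ("126C", "133N", "133C", "134N")


def make_record(accession, intensities, peptides=5, gene=None):
    return ProteinQuantRecord(
        accession=accession,
        gene_symbol=gene if gene is not None else accession.lower(),
        unique_peptides=peptides,
        intensities=dict(zip(CHANNELS, intensities)),
    )


@pytest.fixture
def small_records():
    """Five proteins over the default 4-plex channels."""
    return [
        make_record("P1", (8.0, 4.0, 2.0, 1.0)),
        make_record("P2", (16.0, 16.0, 16.0, 16.0), peptides=3),
        make_record("P3", (1.0, 2.0, 4.0, 8.0), peptides=2),
        make_record("P4", (100.0, 50.0, 25.0, 12.5), peptides=8),
        make_record("P5", (3.0, 3.0, 3.0, 0.0), peptides=4),
    ]


@pytest.fixture
def tiny_sim_config():
    """A small synthetic experiment that runs in well under a second."""
    return SimulationConfig(
        n_background=200,
        n_true_proximal=10,
        n_er_fp=40,
        n_cm_fp=40,
        n_contaminant=10,
        seed=7,
    )
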
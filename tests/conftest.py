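import pytest

from hypoxamir.pipeline import run_end_to_end
from hypoxamir.synthetic_data import GenomeParams, LibraryParams

TINY_PARAMS = dict(
    contig_lengths=(50_000, 50_000),
    n_known_mirnas=8,
    n_hairpins=2,
    n_repeats=3,
    n_ncrnas=2,
    n_pwms=6,
    n_planted_pwms=3,
    n_de_known=4,
    n_de_novel=1,
)


@pytest.fixture(scope="session")
def tiny_params() -> GenomeParams:
    return GenomeParams(**TINY_PARAMS)


@pytest.fixture(scope="session")
def tiny_library() -> LibraryParams:
    return LibraryParams(depth_treatment=20_000, depth_control=20_000)


@pytest.fixture(scope="session")
def tiny_e2e(tiny_params, tiny_library):
    """One small end-to-end run shared by tests that only read its outputs."""
    return run_end_to_end(
        seed=0,
        genome_params=tiny_params,
        library_params=tiny_library,
        n_transcripts=40,
        n_background_promoters=50,
    )
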
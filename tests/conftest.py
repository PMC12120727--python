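import pytest
from hypothesis import HealthCheck, settings

from aptakit.library import DEFAULT_LIBRARY

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def design():
    return DEFAULT_LIBRARY


@pytest.fixture
def wrap(design):
    """Wrap an insert in the library's constant regions."""

    def _wrap(insert: str) -> str:
        return design.forward_constant + insert + design.reverse_constant

    return _wrap


@pytest.fixture
def fastq_writer(tmp_path):
    """Write (id, seq[, qual]) records to a FASTQ file and return its path."""

    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        lines = []
        for rec in records:
            rid, seq = rec[0], rec[1]
            qual = rec[2] if len(rec) > 2 else "I" * len(seq)
            lines += [f"@{rid}", seq, "+", qual]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path

    return _write
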
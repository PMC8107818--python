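import textwrap
from pathlib import Path

import pytest

from qenp.compound_table import AlkaneLadder, builtin_composition_path


@pytest.fixture(scope="session")
def composition_path() -> Path:
    """Packaged 19-compound GC-MS composition table."""
    return builtin_composition_path()


@pytest.fixture
def simple_ladder() -> AlkaneLadder:
    """C10..C13 ladder with 1-minute rungs starting at 5.0 min."""
    return AlkaneLadder(entries=((10, 5.0), (11, 6.0), (12, 7.0), (13, 8.0)))


@pytest.fixture
def write_tsv(tmp_path):
    """Write dedented text to a temp file and return its path."""

    def _write(name: str, text: str) -> Path:
        p = tmp_path / name
        p.write_text(textwrap.dedent(text).lstrip("\n"))
        return p

    return _write
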
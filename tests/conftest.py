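from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SAM_HEADER_2REF = "@HD\tVN:1.6\n@SQ\tSN:T1\tLN:1000\n@SQ\tSN:T2\tLN:600\n"


def sam_line(
    qname: str,
    rname: str,
    pos1: int,
    cigar: str,
    score: int | None = None,
    flag: int = 0,
) -> str:
    tags = f"\tAS:i:{score}" if score is not None else ""
    return f"{qname}\t{flag}\t{rname}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*{tags}\n"


def unmapped_line(qname: str) -> str:
    return f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"


@pytest.fixture
def write_sam(tmp_path: Path):
    """Write a small SAM from raw record lines; returns the path."""

    def _write(lines: list[str], header: str = SAM_HEADER_2REF, name: str = "test.sam") -> Path:
        path = tmp_path / name
        path.write_text(header + "".join(lines))
        return path

    return _write


@pytest.fixture
def fig1_fixture(tmp_path: Path):
    """Prefix-pair dataset (T2 = exact 60% prefix of T1, all reads from T2)."""
    from lrquant import make_fig1_fixture

    return make_fig1_fixture(n_reads=200, seed=11, out_dir=tmp_path)
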
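import numpy as np
import pytest

from locosim.genome_model import build_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_chrom_layout():
    return build_layout([("chr1", 1000), ("chr2", 500)], 1)


@pytest.fixture
def write_chrom_sizes(tmp_path):
    def _write(sizes, name="genome.chrom.sizes"):
        path = tmp_path / name
        path.write_text("".join(f"{c}\t{l}\n" for c, l in sizes))
        return path

    return _write


@pytest.fixture
def write_bed(tmp_path):
    def _write(rows, name="intervals.bed"):
        path = tmp_path / name
        path.write_text("".join("\t".join(str(x) for x in r) + "\n" for r in rows))
        return path

    return _write
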
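import numpy as np
import pytest

from betanull.tables import CommunityTable


@pytest.fixture
def tiny_table() -> CommunityTable:
    """3 taxa x 4 samples over two regions."""
    counts = np.array(
        [
            [2, 0, 5, 1],
            [0, 0, 2, 2],
            [1, 3, 0, 4],
        ]
    )
    sample_ids = ["s1", "s2", "s3", "s4"]
    regions = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    return CommunityTable(["a", "b", "c"], sample_ids, counts, regions)


@pytest.fixture
def region_table() -> CommunityTable:
    """One region, 4 samples, 6 taxa, equal depth 20."""
    rng = np.random.default_rng(42)
    counts = rng.multinomial(20, np.full(6, 1 / 6), size=4).T
    sample_ids = [f"s{i}" for i in range(4)]
    return CommunityTable(
        [f"t{i}" for i in range(6)],
        sample_ids,
        counts,
        {s: "R" for s in sample_ids},
    )


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def tsv_pair(tmp_path):
    """Write a small community + metadata TSV pair; return their paths."""

    def _make(counts_rows, sample_ids, regions=None):
        comm = tmp_path / "community.tsv"
        meta = tmp_path / "metadata.tsv"
        write_tsv(comm, ["taxon_id", *sample_ids], counts_rows)
        regions = regions or {s: "R1" for s in sample_ids}
        write_tsv(
            meta,
            ["sample", "region", "latitude"],
            [[s, regions[s], 30.0] for s in regions],
        )
        return comm, meta

    return _make
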
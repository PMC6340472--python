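"""Shared fixtures: tiny hand-written alignments and partitions."""

import pytest

from mkregions.alignment_io import PopulationAlignment, Region, RegionPartition


def make_alignment(seqs_a, seqs_b, outgroup=None):
    """Build a PopulationAlignment from bare sequence strings."""
    a = tuple((f"a{i}", s) for i, s in enumerate(seqs_a))
    b = tuple((f"b{i}", s) for i, s in enumerate(seqs_b))
    out = ("out", outgroup) if outgroup is not None else None
    return PopulationAlignment(a, b, out)


@pytest.fixture
def minimal_alignment():
    """2 + 2 identical lines, 3 codons, no variation."""
    return make_alignment(["AAACCCGGG"] * 2, ["AAACCCGGG"] * 2)


@pytest.fixture
def two_region_partition():
    return RegionPartition((Region("head", 1, 2), Region("tail", 3, 3)))


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
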
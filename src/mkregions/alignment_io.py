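"""Codon-alignment and region-partition I/O.

Population samples arrive as one aligned nucleotide FASTA per species (all
records the same length, length divisible by three), optionally with a
single-record outgroup FASTA.  Region partitions name codon intervals in
1-based inclusive residue coordinates — the convention used when people say
a domain "spans residues 36 to 54" — while all internal arithmetic uses
0-based half-open nucleotide ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO

from .errors import (
    AlignmentFileError,
    AlphabetError,
    DuplicateIdError,
    DuplicateRegionError,
    FrameError,
    RaggedAlignmentError,
    RegionBoundsError,
    RegionOverlapError,
    SampleSizeError,
)

_ALPHABET = frozenset("ACGTN-")

FULL_CDS = "Full CDS"


@dataclass(frozen=True)
class PopulationAlignment:
    """Aligned in-frame CDS samples for two species plus optional outgroup.

    ``species_a_lines`` and ``species_b_lines`` are ordered lists of
    ``(line_id, sequence)`` pairs; sequences are stored uppercase over the
    alphabet {A, C, G, T, N, -}.
    """

    species_a_lines: tuple[tuple[str, str], ...]
    species_b_lines: tuple[tuple[str, str], ...]
    outgroup: Optional[tuple[str, str]] = None

    def __post_init__(self):
        records = list(self.species_a_lines) + list(self.species_b_lines)
        if self.outgroup is not None:
            records.append(self.outgroup)
        if not records:
            raise SampleSizeError("alignment has no sequences")
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"sequences differ in length: {sorted(lengths)}"
            )
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not a multiple of 3")
        for species, lines in (("a", self.species_a_lines), ("b", self.species_b_lines)):
            if len(lines) < 2:
                raise SampleSizeError(
                    f"species {species} has {len(lines)} line(s); need at least 2"
                )
        seen: set[str] = set()
        for line_id, seq in records:
            if line_id in seen:
                raise DuplicateIdError(f"duplicate line id {line_id!r}")
            seen.add(line_id)
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlphabetError(
                    f"line {line_id!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Alignment length in nucleotides."""
        return len(self.species_a_lines[0][1])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, sequence: str, codon_index: int) -> str:
        """Extract the 1-based ``codon_index``-th codon from ``sequence``."""
        start = 3 * (codon_index - 1)
        return sequence[start : start + 3]


@dataclass(frozen=True)
class Region:
    """A named codon interval, 1-based inclusive on both ends."""

    name: str
    start_codon: int
    end_codon: int

    def __post_init__(self):
        if self.start_codon < 1 or self.end_codon < self.start_codon:
            raise RegionBoundsError(
                f"region {self.name!r}: invalid interval "
                f"({self.start_codon}, {self.end_codon}); coordinates are "
                f"1-based and inclusive"
            )

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1

    def contains_codon(self, codon_index: int) -> bool:
        return self.start_codon <= codon_index <= self.end_codon

    @property
    def nucleotide_range(self) -> tuple[int, int]:
        """0-based half-open nucleotide range [3(s-1), 3e)."""
        return 3 * (self.start_codon - 1), 3 * self.end_codon


@dataclass(frozen=True)
class RegionPartition:
    """Ordered, non-overlapping named codon intervals within a CDS.

    The intervals need not tile the CDS (spacers between annotated regions
    are allowed), but none may be empty or extend past ``cds_codons`` when
    that bound is supplied.  A "Full CDS" pseudo-region covering everything
    is always implied and is never listed explicitly.
    """

    regions: tuple[Region, ...]
    cds_codons: Optional[int] = None

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateRegionError(f"duplicate region name(s): {dupes}")
        if FULL_CDS in names:
            raise DuplicateRegionError(f"{FULL_CDS!r} is a reserved region name")
        ordered = sorted(self.regions, key=lambda r: r.start_codon)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start_codon <= prev.end_codon:
                raise RegionOverlapError(
                    f"regions {prev.name!r} and {cur.name!r} overlap at "
                    f"codon {cur.start_codon}"
                )
        object.__setattr__(self, "regions", tuple(ordered))
        if self.cds_codons is not None:
            for r in self.regions:
                if r.end_codon > self.cds_codons:
                    raise RegionBoundsError(
                        f"region {r.name!r} ends at codon {r.end_codon}, past "
                        f"the CDS ({self.cds_codons} codons)"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def region_of(self, codon_index: int) -> Optional[str]:
        """Name of the region containing ``codon_index``, or None (spacer)."""
        for r in self.regions:
            if r.contains_codon(codon_index):
                return r.name
        return None

    def with_cds_length(self, cds_codons: int) -> "RegionPartition":
        return RegionPartition(self.regions, cds_codons=cds_codons)


def _read_fasta(path) -> list[tuple[str, str]]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise AlignmentFileError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise AlignmentFileError(f"no FASTA records in {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


def read_population_fasta(
    path_a, path_b, path_outgroup=None
) -> PopulationAlignment:
    """Read and validate a two-species (plus optional outgroup) alignment.

    The first whitespace-delimited token of each FASTA header is the line
    id.  The outgroup file must contain exactly one record.  All validation
    (equal lengths, frame, alphabet, >=2 lines per species, unique ids)
    happens in the :class:`PopulationAlignment` constructor.
    """
    lines_a = _read_fasta(path_a)
    lines_b = _read_fasta(path_b)
    outgroup = None
    if path_outgroup is not None:
        out_records = _read_fasta(path_outgroup)
        if len(out_records) != 1:
            raise AlignmentFileError(
                f"outgroup file {path_outgroup} must contain exactly one "
                f"record, found {len(out_records)}"
            )
        outgroup = out_records[0]
    return PopulationAlignment(tuple(lines_a), tuple(lines_b), outgroup)


def write_population_fasta(
    alignment: PopulationAlignment, path_a, path_b, path_outgroup=None
) -> None:
    """Inverse of :func:`read_population_fasta` (order-preserving)."""

    def _dump(pairs: Iterable[tuple[str, str]], path) -> None:
        with open(path, "w") as fh:
            for line_id, seq in pairs:
                fh.write(f">{line_id}\n{seq}\n")

    _dump(alignment.species_a_lines, path_a)
    _dump(alignment.species_b_lines, path_b)
    if alignment.outgroup is not None:
        if path_outgroup is None:
            raise ValueError("alignment has an outgroup but no path was given")
        _dump([alignment.outgroup], path_outgroup)


def load_region_partition(path, cds_codons: Optional[int] = None) -> RegionPartition:
    """Load a region partition from YAML or 3-column TSV.

    YAML: a list of ``{name, start_codon, end_codon}`` mappings (or a
    mapping ``regions:`` holding that list).  TSV: three tab-separated
    columns ``name  start_codon  end_codon``, ``#`` comments and an
    optional header row allowed.  Coordinates are 1-based inclusive codons.
    """
    path = Path(path)
    text = path.read_text()
    entries: list[tuple[str, int, int]]
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
        if isinstance(doc, dict):
            doc = doc.get("regions", doc)
        if not isinstance(doc, list):
            raise RegionBoundsError(f"{path}: expected a list of regions")
        entries = [
            (str(e["name"]), int(e["start_codon"]), int(e["end_codon"]))
            for e in doc
        ]
    else:
        entries = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise RegionBoundsError(
                    f"{path}: expected 3 tab-separated columns, got {raw!r}"
                )
            name, start, end = parts
            if entries == [] and not (start.strip().lstrip("-").isdigit()):
                continue  # header row
            entries.append((name.strip(), int(start), int(end)))
    regions = tuple(Region(name, start, end) for name, start, end in entries)
    return RegionPartition(regions, cds_codons=cds_codons)


def write_region_partition(partition: RegionPartition, path) -> None:
    """Write a partition as the YAML dialect ``load_region_partition`` reads."""
    doc = [
        {"name": r.name, "start_codon": r.start_codon, "end_codon": r.end_codon}
        for r in partition.regions
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _fmt_count(x: float) -> str:
    # counts may carry fractional pathway weights; report rounded integers
    return str(int(round(x)))


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "NA"
    if p == 0:
        return "0.00"
    # 3 significant figures, scientific below 1e-3 to match table rendering
    if p < 1e-3:
        return f"{p:.2E}"
    return f"{float(f'{p:.3g}'):.3f}"


def _fmt_stat(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.3f}"


REPORT_COLUMNS = (
    "region",
    "mode",
    "dN",
    "dS",
    "pN",
    "pS",
    "p_value",
    "alpha",
    "DoS",
)


def write_mk_report(results: Sequence, path) -> None:
    """Write MK results as a TSV table, one row per region x mode.

    Not-computable statistics are rendered as the literal token ``NA``.
    p-values use 3 significant figures, alpha and DoS 3 decimals.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for res in results:
            c = res.counts
            row = (
                c.region_name,
                c.mode,
                _fmt_count(c.dN),
                _fmt_count(c.dS),
                _fmt_count(c.pN),
                _fmt_count(c.pS),
                _fmt_p(res.p_value),
                _fmt_stat(res.alpha),
                _fmt_stat(res.dos),
            )
            fh.write("\t".join(row) + "\n")
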
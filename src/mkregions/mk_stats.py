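"""Per-region McDonald-Kreitman tables, Fisher's exact test, alpha and DoS.

The MK test asks whether the ratio of nonsynonymous to synonymous changes
among fixed interspecific differences exceeds the same ratio among
within-species polymorphisms; an excess of fixed nonsynonymous changes is
the classic signature of adaptive protein evolution.  Two summary
statistics accompany the 2x2 test:

* alpha, the estimated proportion of adaptive amino-acid substitutions,
  ``alpha = 1 - (dS * pN) / (dN * pS)``;
* DoS, the direction of selection,
  ``DoS = dN / (dN + dS) - pN / (pN + pS)``,
  positive under adaptive evolution, negative when weakly deleterious
  variants segregate.

Both are undefined on some boundaries (alpha when dN = 0 or pS = 0, DoS
when either ratio's denominator is 0); those cases are reported as ``None``
and rendered ``NA``, never coerced to a number.

With an outgroup, fixed differences can be polarized: a substitution is
assigned to the lineage of species A when species B's allele matches the
outgroup (and symmetrically), on the parsimony argument that the shared
state is ancestral.  Sites where the outgroup matches neither allele, or is
missing, are unpolarizable and excluded from polarized divergence counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from scipy.stats import fisher_exact

from .alignment_io import FULL_CDS, PopulationAlignment, RegionPartition
from .errors import MissingOutgroupError
from .site_classification import (
    SiteChange,
    apply_frequency_filter,
    call_changes,
)

logger = logging.getLogger(__name__)

Mode = Literal["unpolarized", "polarized_a", "polarized_b"]

MODES: tuple[Mode, ...] = ("unpolarized", "polarized_a", "polarized_b")


@dataclass(frozen=True)
class MKCounts:
    """The (dN, dS, pN, pS) tally for one region and polarization mode.

    Counts are nonnegative reals: fractional pathway weights are kept exact
    through tabulation and only rounded (half to even) for the contingency
    test and integer reporting.
    """

    region_name: str
    mode: Mode
    dN: float
    dS: float
    pN: float
    pS: float

    def __post_init__(self):
        for name in ("dN", "dS", "pN", "pS"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    def rounded(self) -> tuple[int, int, int, int]:
        """Counts rounded half-to-even, as used for the Fisher test."""
        return (
            int(round(self.dN)),
            int(round(self.dS)),
            int(round(self.pN)),
            int(round(self.pS)),
        )


@dataclass(frozen=True)
class MKResult:
    """MK table plus derived statistics; ``None`` marks a not-computable cell."""

    counts: MKCounts
    p_value: Optional[float]
    alpha: Optional[float]
    dos: Optional[float]


def fisher_exact_2x2(dN: float, dS: float, pN: float, pS: float) -> float:
    """Two-tailed Fisher's exact p for the divergence x polymorphism table.

    Uses the point-probability definition of two-tailed: sum the
    hypergeometric probabilities of all tables (at fixed margins) no more
    probable than the observed one.  Fractional counts are rounded half to
    even first.  An all-zero table returns 1 by convention.
    """
    a, b, c, d = (int(round(x)) for x in (dN, dS, pN, pS))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        logger.info("all-zero MK table; returning p = 1 by convention")
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compute_alpha(dN: float, dS: float, pN: float, pS: float) -> Optional[float]:
    """Proportion of adaptive substitutions; None when dN = 0 or pS = 0."""
    if dN == 0 or pS == 0:
        return None
    return 1.0 - (dS * pN) / (dN * pS)


def compute_dos(dN: float, dS: float, pN: float, pS: float) -> Optional[float]:
    """Direction of selection; None when either denominator is 0."""
    if dN + dS == 0 or pN + pS == 0:
        return None
    return dN / (dN + dS) - pN / (pN + pS)


def polarize(
    changes: Iterable[SiteChange],
    alignment: PopulationAlignment,
    focal_species: Literal["a", "b"],
    pooled_polymorphism: bool = False,
) -> list[SiteChange]:
    """Restrict fixed differences to those on the focal species' lineage.

    A fixed difference is assigned to lineage A iff species B's allele
    equals the outgroup allele at that site (the outgroup certifies B's
    state as ancestral), and symmetrically for B.  Fixed sites where the
    outgroup carries N or a gap, or matches neither species, are
    unpolarizable and dropped.  Polymorphisms are restricted to the focal
    species unless ``pooled_polymorphism`` is set, in which case both
    species' polymorphisms are retained.
    """
    if alignment.outgroup is None:
        raise MissingOutgroupError("polarization requires an outgroup sequence")
    if focal_species not in ("a", "b"):
        raise ValueError(f"focal_species must be 'a' or 'b', got {focal_species!r}")
    out_seq = alignment.outgroup[1]
    polarized: list[SiteChange] = []
    for ch in changes:
        if ch.category != "fixed":
            if pooled_polymorphism or ch.category == f"polymorphic_{focal_species}":
                polarized.append(ch)
            continue
        pos = 3 * (ch.codon_index - 1) + ch.offset
        out_allele = out_seq[pos]
        if out_allele not in "ACGT":
            continue  # outgroup missing data: unpolarizable
        if out_allele == ch.allele_b and out_allele != ch.allele_a:
            on_lineage = "a"
        elif out_allele == ch.allele_a and out_allele != ch.allele_b:
            on_lineage = "b"
        else:
            continue  # outgroup matches neither: unpolarizable
        if on_lineage == focal_species:
            polarized.append(ch)
    return polarized


def tabulate(
    changes: Iterable[SiteChange],
    partition: RegionPartition,
    mode: Mode = "unpolarized",
) -> list[MKCounts]:
    """Accumulate changes into one MKCounts per region, plus Full CDS.

    Each change contributes its syn/nonsyn weights to the region containing
    its codon (changes in inter-region spacers appear only in the Full CDS
    row).  Polymorphisms from both species pool into pN/pS; in polarized
    modes the caller is expected to have already restricted the change list
    via :func:`polarize`.
    """
    region_names = [FULL_CDS, *partition.names]
    acc = {name: [0.0, 0.0, 0.0, 0.0] for name in region_names}  # dN dS pN pS
    for ch in changes:
        targets = [FULL_CDS]
        region = partition.region_of(ch.codon_index)
        if region is not None:
            targets.append(region)
        for name in targets:
            slot = acc[name]
            if ch.category == "fixed":
                slot[0] += ch.nonsyn_weight
                slot[1] += ch.syn_weight
            else:
                slot[2] += ch.nonsyn_weight
                slot[3] += ch.syn_weight
    return [
        MKCounts(name, mode, *acc[name])
        for name in region_names
    ]


def result_from_counts(counts: MKCounts) -> MKResult:
    """Derive Fisher p, alpha and DoS from a single MK table.

    The test uses half-to-even rounded counts; alpha and DoS use the exact
    (possibly fractional) counts.
    """
    a, b, c, d = counts.rounded()
    return MKResult(
        counts=counts,
        p_value=fisher_exact_2x2(a, b, c, d),
        alpha=compute_alpha(counts.dN, counts.dS, counts.pN, counts.pS),
        dos=compute_dos(counts.dN, counts.dS, counts.pN, counts.pS),
    )


@dataclass(frozen=True)
class MKOptions:
    """Knobs for the end-to-end analysis.

    ``min_freq`` is the strict lower bound on minor-allele frequency for a
    polymorphism to be retained (0 disables the filter); ``modes`` selects
    which polarizations to compute; ``pooled_polymorphism`` keeps both
    species' polymorphisms in polarized modes instead of the focal
    species' only.
    """

    min_freq: float = 0.05
    modes: tuple[Mode, ...] = ("unpolarized",)
    pooled_polymorphism: bool = False


def run_mk_analysis(
    alignment: PopulationAlignment,
    partition: RegionPartition,
    options: MKOptions = MKOptions(),
) -> list[MKResult]:
    """Full pipeline: call changes, filter, tabulate, test — per region x mode.

    Results are ordered mode-major (in the order requested), region-minor
    (Full CDS first, then partition order), and are deterministic for a
    given alignment regardless of line order.  No multiple-testing
    correction is applied; a log note records how many tests were run.
    """
    partition = partition.with_cds_length(alignment.n_codons)
    changes = call_changes(alignment)
    if options.min_freq > 0:
        changes = apply_frequency_filter(changes, options.min_freq)
    results: list[MKResult] = []
    for mode in options.modes:
        if mode == "unpolarized":
            mode_changes = changes
        else:
            focal = "a" if mode == "polarized_a" else "b"
            mode_changes = polarize(
                changes,
                alignment,
                focal,  # type: ignore[arg-type]
                pooled_polymorphism=options.pooled_polymorphism,
            )
        for counts in tabulate(mode_changes, partition, mode):
            results.append(result_from_counts(counts))
    logger.info(
        "ran %d MK tests (no multiple-testing correction applied)", len(results)
    )
    return results
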
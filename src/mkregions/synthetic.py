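"""Ground-truthed codon-evolution simulator for two species plus outgroup.

The generator emulates the data layout of a region-partitioned MK study:
an ancestral in-frame CDS evolves independently into an outgroup sequence
and into consensus sequences for two focal species; each consensus is then
copied into a population sample into which segregating single-nucleotide
polymorphisms are injected with a chosen site-frequency spectrum.

Selection is modeled as acceptance-thinning: every proposed nonsynonymous
change is accepted with probability omega of the region it falls in
(synonymous changes are always accepted), with separate omega maps for
fixations (``omega_div``) and polymorphisms (``omega_poly``).  Mutation
proposals pick a site uniformly within the codon and an alternative
nucleotide with transition weight kappa versus transversion weight 1;
proposals creating stop codons are rejected.  This is deliberately simpler
than a full codon-substitution matrix — it is sufficient to generate MK
count structure with closed-form expectations.

Every accepted event is recorded in a :class:`GroundTruth`, so pipeline
output can be reconciled against what was actually simulated.  Homoplasy
(two events hitting the same nucleotide site) is allowed but flagged, not
prevented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np

from .alignment_io import (
    PopulationAlignment,
    RegionPartition,
    write_population_fasta,
    write_region_partition,
)
from .errors import SimulationError
from .site_classification import STOP_CODONS, translate_codon

Lineage = Literal["a", "b", "outgroup_stem"]
EventKind = Literal["fixation", "polymorphism"]

SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    )
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

OmegaMap = Union[float, Mapping[Optional[str], float]]


def _omega_for(omega: OmegaMap, region: Optional[str]) -> float:
    """Resolve the omega applying to ``region`` (None = spacer / no region)."""
    if isinstance(omega, (int, float)):
        return float(omega)
    if region in omega:
        return float(omega[region])
    if None in omega:
        return float(omega[None])
    raise SimulationError(f"no omega configured for region {region!r}")


@dataclass(frozen=True)
class Event:
    """One accepted mutation event with full provenance."""

    codon_index: int  # 1-based
    offset: int  # 0..2
    lineage: Lineage
    kind: EventKind
    nonsyn: bool
    nt_from: str
    nt_to: str
    derived_count: int = 0  # carriers of the derived allele; 0 for fixations


@dataclass
class GroundTruth:
    """Every simulated event, plus the set of multiply-hit (flagged) sites."""

    events: list[Event] = field(default_factory=list)

    @property
    def flagged_sites(self) -> set[tuple[int, int]]:
        """Sites hit by more than one event (possible homoplasy/masking)."""
        seen: dict[tuple[int, int], int] = {}
        for ev in self.events:
            key = (ev.codon_index, ev.offset)
            seen[key] = seen.get(key, 0) + 1
        return {k for k, v in seen.items() if v > 1}

    @property
    def multihit_codons(self) -> set[int]:
        """Codons hit by more than one event (pathway-weight conventions
        at such codons may differ between simulator labels and pipeline)."""
        seen: dict[int, int] = {}
        for ev in self.events:
            seen[ev.codon_index] = seen.get(ev.codon_index, 0) + 1
        return {k for k, v in seen.items() if v > 1}

    def counts_by_region(
        self,
        partition: RegionPartition,
        min_freq: float = 0.0,
        sample_sizes: Optional[Mapping[str, int]] = None,
        exclude_flagged: bool = True,
        exclude_codons: Optional[set[int]] = None,
        lineages: Sequence[Lineage] = ("a", "b"),
    ) -> dict[Optional[str], tuple[int, int, int, int]]:
        """True (dN, dS, pN, pS) per region (None key = spacer sites).

        Fixations on ``lineages`` enter dN/dS; polymorphisms enter pN/pS
        unless their derived-allele frequency (folded to the minor allele)
        falls strictly below ``min_freq``; ``sample_sizes`` maps lineage
        name to its number of lines (required when filtering).
        ``exclude_codons`` drops every event in those codons (used to set
        aside multiply-hit codons when reconciling against the pipeline).
        """
        flagged = self.flagged_sites if exclude_flagged else set()
        excluded = exclude_codons or set()
        acc: dict[Optional[str], list[int]] = {}
        for ev in self.events:
            if (ev.codon_index, ev.offset) in flagged:
                continue
            if ev.codon_index in excluded:
                continue
            region = partition.region_of(ev.codon_index)
            slot = acc.setdefault(region, [0, 0, 0, 0])
            if ev.kind == "fixation":
                if ev.lineage not in lineages:
                    continue
                slot[0 if ev.nonsyn else 1] += 1
            else:
                if min_freq > 0:
                    if sample_sizes is None:
                        raise ValueError("sample_sizes required when min_freq > 0")
                    n = sample_sizes[ev.lineage]
                    minor = min(ev.derived_count, n - ev.derived_count)
                    if minor / n < min_freq:
                        continue
                slot[2 if ev.nonsyn else 3] += 1
        return {k: tuple(v) for k, v in acc.items()}  # type: ignore[return-value]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters with per-region selection strength.

    ``t_a``/``t_b``/``t_out`` are expected mutation proposals per codon on
    each branch; realized substitution counts are lower under purifying
    selection (omega < 1).  ``omega_div`` and ``omega_poly`` may be a
    single float or a mapping from region name (None for spacers) to the
    nonsynonymous acceptance probability.  ``sfs`` picks the distribution
    of derived-allele counts for injected polymorphisms: the standard
    neutral spectrum P(k) proportional to 1/k, or uniform.
    """

    n_codons: int
    partition: RegionPartition
    n_a: int = 30
    n_b: int = 30
    t_a: float = 0.05
    t_b: float = 0.05
    t_out: float = 0.10
    kappa: float = 2.0
    omega_div: OmegaMap = 0.2
    omega_poly: OmegaMap = 0.2
    n_poly_a: int = 30
    n_poly_b: int = 30
    sfs: Literal["neutral_1_over_i", "uniform"] = "neutral_1_over_i"
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise SimulationError("n_codons must be >= 1")
        if self.n_a < 2 or self.n_b < 2:
            raise SimulationError("sample sizes must be >= 2")
        for name in ("t_a", "t_b", "t_out", "kappa"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.sfs not in ("neutral_1_over_i", "uniform"):
            raise SimulationError(f"unknown SFS {self.sfs!r}")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_ancestral_cds(n_codons: int, seed) -> str:
    """Uniform-random sense codons (no stops); deterministic given seed."""
    if n_codons < 1:
        raise SimulationError(f"n_codons must be >= 1, got {n_codons}")
    rng = _as_rng(seed)
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _propose_alt(nt: str, kappa: float, rng: np.random.Generator) -> str:
    """Alternative nucleotide: transition weight kappa, transversions 1 each."""
    transition = _TRANSITION[nt]
    transversions = [x for x in "ACGT" if x != nt and x != transition]
    weights = np.array([kappa, 1.0, 1.0])
    p = weights / weights.sum()
    choice = rng.choice(3, p=p)
    return ([transition] + transversions)[choice]


def evolve_lineage(
    sequence: str,
    t: float,
    kappa: float,
    omega_by_region: OmegaMap,
    partition: RegionPartition,
    seed,
    lineage: Lineage = "a",
) -> tuple[str, list[Event]]:
    """Evolve a CDS along one branch; return the new sequence and events.

    Per codon, Poisson(t) proposals; each picks a site uniformly and an
    alternative nucleotide by transition/transversion weighting.  Proposals
    creating stop codons are rejected outright; synonymous proposals are
    accepted; nonsynonymous proposals are accepted with probability omega
    of the codon's region.  Accepted proposals mutate the sequence
    immediately, so later proposals in the same codon see the updated
    state (multiple hits arise only from independent proposals).
    """
    rng = _as_rng(seed)
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    events: list[Event] = []
    n_proposals = rng.poisson(t, size=len(codons))
    for ci, n_prop in enumerate(n_proposals, start=1):
        if n_prop == 0:
            continue
        region = partition.region_of(ci)
        omega = _omega_for(omega_by_region, region)
        for _ in range(n_prop):
            codon = codons[ci - 1]
            off = int(rng.integers(0, 3))
            old_nt = codon[off]
            new_nt = _propose_alt(old_nt, kappa, rng)
            new_codon = codon[:off] + new_nt + codon[off + 1 :]
            if new_codon in STOP_CODONS:
                continue
            nonsyn = translate_codon(codon) != translate_codon(new_codon)
            if nonsyn and rng.random() >= omega:
                continue
            codons[ci - 1] = new_codon
            events.append(
                Event(
                    codon_index=ci,
                    offset=off,
                    lineage=lineage,
                    kind="fixation",
                    nonsyn=nonsyn,
                    nt_from=old_nt,
                    nt_to=new_nt,
                )
            )
    return "".join(codons), events


def _draw_sfs_count(
    n: int, sfs: str, rng: np.random.Generator
) -> int:
    ks = np.arange(1, n)
    if sfs == "neutral_1_over_i":
        w = 1.0 / ks
    else:
        w = np.ones_like(ks, dtype=float)
    return int(rng.choice(ks, p=w / w.sum()))


def inject_polymorphisms(
    lines: Sequence[tuple[str, str]],
    n_poly: int,
    omega_poly_by_region: OmegaMap,
    partition: RegionPartition,
    sfs: str,
    seed,
    kappa: float = 2.0,
    lineage: Lineage = "a",
) -> tuple[list[tuple[str, str]], list[Event]]:
    """Place segregating single-nucleotide sites into a population sample.

    Each polymorphism picks a previously unused nucleotide position, an
    alternative allele by transition/transversion weighting (stop-creating
    proposals rejected, nonsynonymous ones thinned by the region's
    omega_poly), a derived-allele count k from the chosen SFS over
    1..n-1, and a uniform-random subset of k lines to carry the derived
    allele.  The derived allele is applied relative to each carrier line's
    current codon, so every emitted site is genuinely segregating.
    """
    if len(lines) < 2:
        raise SimulationError("need at least 2 lines to inject polymorphisms")
    n_lines = len(lines)
    seq_len = len(lines[0][1])
    if n_poly > seq_len:
        raise SimulationError(
            f"cannot place {n_poly} polymorphisms in {seq_len} sites"
        )
    rng = _as_rng(seed)
    seqs = [list(seq) for _, seq in lines]
    used: set[int] = set()
    events: list[Event] = []
    attempts = 0
    max_attempts = 500 * max(n_poly, 1) + 1000
    while len(events) < n_poly:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"could not place {n_poly} polymorphisms after "
                f"{max_attempts} attempts (omega too small or CDS too short?)"
            )
        pos = int(rng.integers(0, seq_len))
        if pos in used:
            continue
        ci, off = pos // 3 + 1, pos % 3
        # mutate relative to the majority (consensus) codon at this position
        ref_codon = "".join(seqs[0][3 * (ci - 1) : 3 * (ci - 1) + 3])
        old_nt = ref_codon[off]
        new_nt = _propose_alt(old_nt, kappa, rng)
        new_codon = ref_codon[:off] + new_nt + ref_codon[off + 1 :]
        if new_codon in STOP_CODONS or ref_codon in STOP_CODONS:
            continue
        nonsyn = translate_codon(ref_codon) != translate_codon(new_codon)
        region = partition.region_of(ci)
        omega = _omega_for(omega_poly_by_region, region)
        if nonsyn and rng.random() >= omega:
            continue
        k = _draw_sfs_count(n_lines, sfs, rng)
        carriers = rng.choice(n_lines, size=k, replace=False)
        for li in carriers:
            seqs[li][pos] = new_nt
        used.add(pos)
        events.append(
            Event(
                codon_index=ci,
                offset=off,
                lineage=lineage,
                kind="polymorphism",
                nonsyn=nonsyn,
                nt_from=old_nt,
                nt_to=new_nt,
                derived_count=k,
            )
        )
    return (
        [(line_id, "".join(s)) for (line_id, _), s in zip(lines, seqs)],
        events,
    )


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`emit_dataset`."""

    alignment: PopulationAlignment
    partition: RegionPartition
    truth: GroundTruth
    config: SimulationConfig


def emit_dataset(
    config: SimulationConfig, out_dir: Optional[Union[str, Path]] = None
) -> SimulatedDataset:
    """Simulate a full two-species + outgroup dataset with ground truth.

    The ancestral CDS evolves into the outgroup (branch ``t_out``) and into
    each species' consensus (branches ``t_a``, ``t_b``) under
    ``omega_div``; consensus sequences are copied into ``n_a``/``n_b``
    population lines and polymorphisms are injected under ``omega_poly``.
    A single seeded RNG stream drives every draw, so identical configs
    produce byte-identical output.  With ``out_dir`` set, writes
    ``species_a.fa``, ``species_b.fa``, ``outgroup.fa``, ``regions.yaml``
    and ``truth.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    partition = config.partition.with_cds_length(config.n_codons)
    truth = GroundTruth()

    ancestral = simulate_ancestral_cds(config.n_codons, rng)
    outgroup_seq, ev = evolve_lineage(
        ancestral, config.t_out, config.kappa, config.omega_div,
        partition, rng, lineage="outgroup_stem",
    )
    truth.events.extend(ev)
    consensus = {}
    for key, t in (("a", config.t_a), ("b", config.t_b)):
        consensus[key], ev = evolve_lineage(
            ancestral, t, config.kappa, config.omega_div,
            partition, rng, lineage=key,
        )
        truth.events.extend(ev)

    samples = {}
    for key, n, n_poly in (
        ("a", config.n_a, config.n_poly_a),
        ("b", config.n_b, config.n_poly_b),
    ):
        lines = [(f"{key}_{i}", consensus[key]) for i in range(n)]
        lines, ev = inject_polymorphisms(
            lines, n_poly, config.omega_poly, partition, config.sfs, rng,
            kappa=config.kappa, lineage=key,
        )
        truth.events.extend(ev)
        samples[key] = tuple(lines)

    alignment = PopulationAlignment(
        samples["a"], samples["b"], ("outgroup", outgroup_seq)
    )
    dataset = SimulatedDataset(alignment, partition, truth, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_population_fasta(
            alignment,
            out / "species_a.fa",
            out / "species_b.fa",
            out / "outgroup.fa",
        )
        write_region_partition(partition, out / "regions.yaml")
        _write_truth(truth, out / "truth.tsv")
    return dataset


def _write_truth(truth: GroundTruth, path) -> None:
    flagged = truth.flagged_sites
    with open(path, "w") as fh:
        fh.write(
            "codon_index\toffset\tlineage\tkind\teffect\t"
            "nt_from\tnt_to\tderived_count\tflagged\n"
        )
        for ev in truth.events:
            fh.write(
                f"{ev.codon_index}\t{ev.offset}\t{ev.lineage}\t{ev.kind}\t"
                f"{'nonsyn' if ev.nonsyn else 'syn'}\t{ev.nt_from}\t{ev.nt_to}\t"
                f"{ev.derived_count}\t"
                f"{int((ev.codon_index, ev.offset) in flagged)}\n"
            )
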
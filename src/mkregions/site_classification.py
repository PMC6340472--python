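"""Classify variable sites as polymorphic or fixed and score them syn/nonsyn.

The McDonald-Kreitman framework partitions nucleotide changes along two
axes: polymorphic within a species vs. fixed between species, and
synonymous vs. nonsynonymous.  This module walks every codon column of a
:class:`~mkregions.alignment_io.PopulationAlignment`, emits one
:class:`SiteChange` per variable nucleotide site, and applies the
low-frequency polymorphism filter (variants segregating in fewer than a
given fraction of lines are presumed deleterious and excluded).

Conventions the source data do not dictate, chosen here and held fixed:

* Polymorphisms are scored against the species-majority codon at that
  column (ties broken lexicographically), which makes the output invariant
  under reordering of lines.
* Codons differing at several positions are scored by pathway counting:
  average the per-site synonymous/nonsynonymous assignments over every
  ordering of single-nucleotide steps that avoids stop codons.
* Lines with N or a gap in a codon are dropped from that column only; a
  species needs at least two remaining lines for the column to be scored.
* Changes to or from stop codons contribute nothing (they fall outside the
  amino-acid replacement framework) and are flagged on the result.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .alignment_io import PopulationAlignment
from .errors import StopCodonError

Category = Literal["polymorphic_a", "polymorphic_b", "fixed"]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)


def translate_codon(codon: str, genetic_code: Optional[dict] = None) -> Optional[str]:
    """Amino acid for a sense codon, or None for a stop."""
    table = genetic_code if genetic_code is not None else _CODON_TO_AA
    return table.get(codon)


@dataclass(frozen=True)
class SiteChange:
    """One scored nucleotide change at a single alignment site.

    ``syn_weight + nonsyn_weight == 1`` for every retained change; the
    weights are fractional when the codon pair differs at several positions
    and the pathway orderings disagree on this site's step.
    """

    codon_index: int  # 1-based
    offset: int  # 0..2 within the codon
    category: Category
    nonsyn_weight: float
    syn_weight: float
    minor_count: int  # lines carrying the minor allele; 0 for fixed
    sample_size: int  # lines scored at this column (focal species; min of both for fixed)
    allele_a: Optional[str] = None  # fixed allele in species A (fixed changes)
    allele_b: Optional[str] = None  # fixed allele in species B (fixed changes)

    @property
    def site(self) -> tuple[int, int]:
        return (self.codon_index, self.offset)


def codon_column_states(
    alignment: PopulationAlignment, codon_index: int
) -> dict[str, tuple[Counter, int]]:
    """Observed codon multiset and effective sample size per species.

    Lines whose codon contains N or a gap at this column are dropped and do
    not count toward the effective sample size.
    """
    out: dict[str, tuple[Counter, int]] = {}
    for key, lines in (("a", alignment.species_a_lines), ("b", alignment.species_b_lines)):
        tally: Counter = Counter()
        for _, seq in lines:
            codon = alignment.codon(seq, codon_index)
            if set(codon) <= {"A", "C", "G", "T"}:
                tally[codon] += 1
        out[key] = (tally, sum(tally.values()))
    return out


def classify_codon_change(
    codon_from: str,
    codon_to: str,
    genetic_code: Optional[dict] = None,
) -> dict[int, tuple[float, float]]:
    """Per-site (nonsyn_weight, syn_weight) for a codon substitution.

    Codons differing at one site score that site (1, 0) if the amino acid
    changes, (0, 1) otherwise.  For k > 1 differing sites, all k! orderings
    of single-nucleotide steps are enumerated, orderings passing through a
    stop codon are discarded, and each site's weights are averaged over the
    surviving orderings.  If every ordering passes through a stop the
    result is empty (the site pair contributes nothing).

    Raises :class:`StopCodonError` if either endpoint is a stop codon.
    """
    for c in (codon_from, codon_to):
        if translate_codon(c, genetic_code) is None:
            raise StopCodonError(f"stop codon {c} supplied to classify_codon_change")
    diff_sites = [i for i in range(3) if codon_from[i] != codon_to[i]]
    if not diff_sites:
        return {}
    per_site_nonsyn: dict[int, float] = {i: 0.0 for i in diff_sites}
    n_valid = 0
    for order in itertools.permutations(diff_sites):
        current = codon_from
        steps: list[tuple[int, bool]] = []
        ok = True
        for site in order:
            nxt = current[:site] + codon_to[site] + current[site + 1 :]
            aa_next = translate_codon(nxt, genetic_code)
            if aa_next is None:  # path passes through a stop
                ok = False
                break
            aa_cur = translate_codon(current, genetic_code)
            steps.append((site, aa_cur != aa_next))
            current = nxt
        if ok:
            n_valid += 1
            for site, is_nonsyn in steps:
                if is_nonsyn:
                    per_site_nonsyn[site] += 1.0
    if n_valid == 0:
        return {}
    return {
        site: (per_site_nonsyn[site] / n_valid, 1.0 - per_site_nonsyn[site] / n_valid)
        for site in diff_sites
    }


def _majority_codon(tally: Counter) -> str:
    """Most frequent codon; ties broken lexicographically."""
    best = max(tally.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
    # the key above prefers higher count, then lexicographically smaller codon
    return best[0]


def _variable_codon_indices(alignment: PopulationAlignment) -> Iterable[int]:
    """Codon columns that could possibly yield a change (fast numpy screen).

    A column is interesting iff any line (in either species) differs from
    the first line of species A, or any line carries N/-.  Monomorphic
    columns identical across both species — the vast majority in realistic
    data — are skipped without per-line Python work.
    """
    seqs = [s for _, s in alignment.species_a_lines] + [
        s for _, s in alignment.species_b_lines
    ]
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), alignment.length
    )
    varying = (arr != arr[0]).any(axis=0)
    codon_mask = varying.reshape(-1, 3).any(axis=1)
    return (int(i) + 1 for i in np.nonzero(codon_mask)[0])


def call_changes(
    alignment: PopulationAlignment,
    genetic_code: Optional[dict] = None,
) -> list[SiteChange]:
    """Emit every polymorphic and fixed nucleotide change in the alignment.

    Per codon column:

    * each nucleotide site segregating within species X yields one
      ``polymorphic_X`` change per non-majority allele, scored against the
      species-majority codon;
    * a site yields a ``fixed`` change only when both species are
      monomorphic there and their alleles differ — a shared allele is never
      a fixed difference;
    * a species with fewer than two gap/N-free lines at the column is
      skipped for polymorphism, and fixed calls require both species
      scorable.

    Changes involving stop codons are silently excluded from the returned
    list.  Output order is deterministic (by codon, offset, category) and
    independent of the order of lines in the input.
    """
    changes: list[SiteChange] = []
    for codon_index in _variable_codon_indices(alignment):
        states = codon_column_states(alignment, codon_index)
        tally_a, n_a = states["a"]
        tally_b, n_b = states["b"]
        per_species = []
        for cat, tally, n in (
            ("polymorphic_a", tally_a, n_a),
            ("polymorphic_b", tally_b, n_b),
        ):
            if n < 2:
                per_species.append(None)
                continue
            major = _majority_codon(tally)
            per_species.append(major)
            # polymorphisms: one change per segregating site per minor allele
            if translate_codon(major, genetic_code) is None:
                continue  # majority codon is a stop; skip this species' calls
            site_alleles: dict[int, Counter] = {0: Counter(), 1: Counter(), 2: Counter()}
            for codon, count in tally.items():
                for off in range(3):
                    site_alleles[off][codon[off]] += count
            for off in range(3):
                alleles = site_alleles[off]
                if len(alleles) < 2:
                    continue
                major_allele = major[off]
                for allele, count in sorted(alleles.items()):
                    if allele == major_allele:
                        continue
                    mutant = major[:off] + allele + major[off + 1 :]
                    if translate_codon(mutant, genetic_code) is None:
                        continue  # change to a stop: excluded
                    weights = classify_codon_change(major, mutant, genetic_code)
                    nonsyn_w, syn_w = weights[off]
                    changes.append(
                        SiteChange(
                            codon_index=codon_index,
                            offset=off,
                            category=cat,  # type: ignore[arg-type]
                            nonsyn_weight=nonsyn_w,
                            syn_weight=syn_w,
                            minor_count=count,
                            sample_size=n,
                        )
                    )
        # fixed differences: both species scorable and monomorphic at the site
        major_a, major_b = per_species
        if major_a is None or major_b is None:
            continue
        if (
            translate_codon(major_a, genetic_code) is None
            or translate_codon(major_b, genetic_code) is None
        ):
            continue
        fixed_sites = []
        for off in range(3):
            alleles_a = {codon[off] for codon in tally_a}
            alleles_b = {codon[off] for codon in tally_b}
            if len(alleles_a) == 1 and len(alleles_b) == 1 and alleles_a != alleles_b:
                fixed_sites.append(off)
        if not fixed_sites:
            continue
        # pathway-average over the consensus codon pair; weights read off at
        # the genuinely fixed sites (other differing sites, if any, are
        # segregating and already reported as polymorphisms)
        weights = classify_codon_change(major_a, major_b, genetic_code)
        for off in fixed_sites:
            if off not in weights:
                continue  # all pathways through stops
            nonsyn_w, syn_w = weights[off]
            changes.append(
                SiteChange(
                    codon_index=codon_index,
                    offset=off,
                    category="fixed",
                    nonsyn_weight=nonsyn_w,
                    syn_weight=syn_w,
                    minor_count=0,
                    sample_size=min(n_a, n_b),
                    allele_a=major_a[off],
                    allele_b=major_b[off],
                )
            )
    changes.sort(key=lambda ch: (ch.codon_index, ch.offset, ch.category, ch.minor_count))
    return changes


def apply_frequency_filter(
    changes: Iterable[SiteChange], threshold: float = 0.05
) -> list[SiteChange]:
    """Drop low-frequency polymorphisms; keep everything else.

    A polymorphic change is removed iff its minor-allele frequency
    ``minor_count / sample_size`` is strictly below ``threshold`` ("fewer
    than" the cutoff fraction of lines).  Fixed changes always pass.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    kept = []
    for ch in changes:
        if ch.category == "fixed":
            kept.append(ch)
        elif ch.minor_count / ch.sample_size >= threshold:
            kept.append(ch)
    return kept
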
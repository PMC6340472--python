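"""Simulator: determinism, acceptance-thinning semantics, SFS shape,
and reconciliation of pipeline output against recorded ground truth."""

import math
import pytest

from mkregions import (
    SimulationConfig,
    apply_frequency_filter,
    call_changes,
    emit_dataset,
    evolve_lineage,
    inject_polymorphisms,
    simulate_ancestral_cds,
)
from mkregions.alignment_io import Region, RegionPartition
from mkregions.errors import SimulationError
from mkregions.mk_stats import polarize, tabulate
from mkregions.site_classification import STOP_CODONS, translate_codon
from mkregions.synthetic import _TRANSITION

PART = RegionPartition((Region("left", 1, 10), Region("right", 11, 20)))


def default_config(**kw):
    base = dict(n_codons=20, partition=PART, seed=0, n_poly_a=4, n_poly_b=4)
    base.update(kw)
    return SimulationConfig(**base)


class TestAncestralCds:
    def test_zero_codons_rejected(self):
        with pytest.raises(SimulationError):
            simulate_ancestral_cds(0, 1)

    def test_deterministic_given_seed(self):
        assert simulate_ancestral_cds(50, 42) == simulate_ancestral_cds(50, 42)
        assert simulate_ancestral_cds(50, 42) != simulate_ancestral_cds(50, 43)

    def test_no_stop_codons_in_10k(self):
        seq = simulate_ancestral_cds(10_000, 3)
        codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
        assert codons.isdisjoint(STOP_CODONS)


class TestEvolveLineage:
    part = RegionPartition((Region("all", 1, 4000),))

    def test_zero_branch_length_is_identity(self):
        seq = simulate_ancestral_cds(30, 1)
        part = RegionPartition((Region("all", 1, 30),))
        out, events = evolve_lineage(seq, 0.0, 2.0, 1.0, part, seed=2)
        assert out == seq
        assert events == []

    def test_omega_zero_means_all_synonymous(self):
        seq = simulate_ancestral_cds(500, 1)
        part = RegionPartition((Region("all", 1, 500),))
        out, events = evolve_lineage(seq, 0.3, 2.0, 0.0, part, seed=2)
        assert events  # something happened
        assert all(not ev.nonsyn for ev in events)
        # and every event is synonymous at the protein level overall
        prot = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)]
        prot_out = [translate_codon(out[i : i + 3]) for i in range(0, len(out), 3)]
        assert prot == prot_out

    def test_nonsyn_fraction_matches_enumeration(self):
        """At omega = 1 the accepted nonsyn:syn ratio equals the proposal
        process's expectation, computed by exhaustive enumeration of every
        codon x site x alternative-nucleotide proposal."""
        kappa = 2.0
        seq = simulate_ancestral_cds(4000, 9)
        # expectation over the ancestral composition
        weight_nonsyn = weight_total = 0.0
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            for off in range(3):
                nt = codon[off]
                for alt in "ACGT":
                    if alt == nt:
                        continue
                    w = kappa if _TRANSITION[nt] == alt else 1.0
                    mutant = codon[:off] + alt + codon[off + 1 :]
                    if mutant in STOP_CODONS:
                        continue  # proposal rejected, never an event
                    weight_total += w
                    if translate_codon(mutant) != translate_codon(codon):
                        weight_nonsyn += w
        # NB stop-creating proposals are removed from numerator and
        # denominator alike: acceptance at omega=1 conditions on non-stop
        expected = weight_nonsyn / weight_total
        _, events = evolve_lineage(seq, 0.15, kappa, 1.0, self.part, seed=10)
        observed = sum(ev.nonsyn for ev in events) / len(events)
        se = math.sqrt(expected * (1 - expected) / len(events))
        assert abs(observed - expected) < 3 * se

    def test_region_specific_omega(self):
        part = RegionPartition((Region("frozen", 1, 250), Region("free", 251, 500)))
        seq = simulate_ancestral_cds(500, 5)
        _, events = evolve_lineage(
            seq, 0.4, 2.0, {"frozen": 0.0, "free": 1.0}, part, seed=6
        )
        by_region = {"frozen": [], "free": []}
        for ev in events:
            by_region[part.region_of(ev.codon_index)].append(ev)
        assert all(not ev.nonsyn for ev in by_region["frozen"])
        assert any(ev.nonsyn for ev in by_region["free"])


class TestInjectPolymorphisms:
    def test_zero_polymorphisms_is_identity(self):
        lines = [("l1", "AAACCC"), ("l2", "AAACCC")]
        part = RegionPartition((Region("all", 1, 2),))
        out, events = inject_polymorphisms(lines, 0, 1.0, part, "uniform", 3)
        assert out == lines
        assert events == []

    def test_all_sites_segregating(self):
        part = RegionPartition((Region("all", 1, 100),))
        consensus = simulate_ancestral_cds(100, 8)
        lines = [(f"l{i}", consensus) for i in range(12)]
        out, events = inject_polymorphisms(
            lines, 30, 0.5, part, "neutral_1_over_i", 9
        )
        for ev in events:
            pos = 3 * (ev.codon_index - 1) + ev.offset
            alleles = {seq[pos] for _, seq in out}
            assert len(alleles) == 2
            assert 1 <= ev.derived_count <= len(lines) - 1
            carriers = sum(1 for _, seq in out if seq[pos] == ev.nt_to)
            assert carriers == ev.derived_count

    def test_distinct_positions(self):
        part = RegionPartition((Region("all", 1, 50),))
        consensus = simulate_ancestral_cds(50, 2)
        lines = [(f"l{i}", consensus) for i in range(6)]
        _, events = inject_polymorphisms(lines, 40, 1.0, part, "uniform", 4)
        sites = [(ev.codon_index, ev.offset) for ev in events]
        assert len(sites) == len(set(sites)) == 40

    def test_too_many_polymorphisms_rejected(self):
        part = RegionPartition((Region("all", 1, 2),))
        lines = [("l1", "AAACCC"), ("l2", "AAACCC")]
        with pytest.raises(SimulationError):
            inject_polymorphisms(lines, 7, 1.0, part, "uniform", 1)

    def test_neutral_sfs_singleton_fraction(self):
        """For n = 28 lines under the 1/k spectrum, the fraction of sites
        with derived count 1 converges to 1/H(27)."""
        part = RegionPartition((Region("all", 1, 2000),))
        consensus = simulate_ancestral_cds(2000, 1)
        lines = [(f"l{i}", consensus) for i in range(28)]
        _, events = inject_polymorphisms(
            lines, 1500, 1.0, part, "neutral_1_over_i", 13
        )
        h27 = sum(1.0 / k for k in range(1, 28))
        expected = 1.0 / h27
        observed = sum(ev.derived_count == 1 for ev in events) / len(events)
        se = math.sqrt(expected * (1 - expected) / len(events))
        assert abs(observed - expected) < 3 * se


class TestEmitDataset:
    def test_byte_identical_given_seed(self, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        ds1 = emit_dataset(default_config(seed=11), out_dir=d1)
        ds2 = emit_dataset(default_config(seed=11), out_dir=d2)
        assert ds1.alignment == ds2.alignment
        assert ds1.truth.events == ds2.truth.events
        for name in ("species_a.fa", "species_b.fa", "outgroup.fa",
                     "regions.yaml", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_file_layout(self, tmp_path):
        emit_dataset(default_config(seed=1), out_dir=tmp_path)
        header, *rows = (tmp_path / "truth.tsv").read_text().splitlines()
        assert header.split("\t")[:4] == ["codon_index", "offset", "lineage", "kind"]
        assert rows

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pipeline_counts_reconcile_with_ground_truth(self, seed):
        """On codons hit by a single simulated event, pipeline counts equal
        ground-truth counts exactly, region by region (multiply-hit codons,
        where pathway-weight conventions may differ, are set aside)."""
        part = RegionPartition(
            (Region("left", 1, 120), Region("central", 121, 240),
             Region("right", 241, 360))
        )
        cfg = SimulationConfig(
            n_codons=360, partition=part, seed=seed, t_a=0.08, t_b=0.08,
            t_out=0.16, omega_div=0.3, omega_poly=0.3,
            n_poly_a=25, n_poly_b=25,
        )
        ds = emit_dataset(cfg)
        skip = ds.truth.multihit_codons
        changes = [c for c in call_changes(ds.alignment) if c.codon_index not in skip]
        pipeline = {
            c.region_name: (c.dN, c.dS, c.pN, c.pS)
            for c in tabulate(changes, ds.partition)
        }
        truth = ds.truth.counts_by_region(ds.partition, exclude_codons=skip)
        for region in ("left", "central", "right"):
            assert pipeline[region] == pytest.approx(
                truth.get(region, (0, 0, 0, 0))
            )

    def test_frequency_filter_agrees_with_ground_truth(self):
        """The 5% filter removes exactly the polymorphisms whose folded
        minor-allele frequency is below 0.05, per the recorded counts."""
        cfg = default_config(
            n_codons=300,
            partition=RegionPartition((Region("all", 1, 300),)),
            n_a=28, n_b=28, n_poly_a=40, n_poly_b=40, seed=21,
        )
        ds = emit_dataset(cfg)
        skip = ds.truth.multihit_codons
        truth_by_site = {
            (ev.codon_index, ev.offset): ev
            for ev in ds.truth.events
            if ev.kind == "polymorphism" and ev.codon_index not in skip
        }
        changes = call_changes(ds.alignment)
        kept = {
            c.site
            for c in apply_frequency_filter(changes, 0.05)
            if c.category.startswith("polymorphic")
        }
        n = 28
        checked = 0
        for site, ev in truth_by_site.items():
            minor = min(ev.derived_count, n - ev.derived_count)
            assert (site in kept) == (minor / n >= 0.05)
            checked += 1
        assert checked > 20

    def test_polarization_recovers_true_lineage(self):
        """Fixations at singly-hit sites polarize onto the lineage that
        actually carried them."""
        part = RegionPartition((Region("all", 1, 400),))
        cfg = SimulationConfig(
            n_codons=400, partition=part, seed=17, t_a=0.06, t_b=0.06,
            t_out=0.12, omega_div=0.5, omega_poly=0.5,
            n_poly_a=10, n_poly_b=10,
        )
        ds = emit_dataset(cfg)
        skip = ds.truth.multihit_codons
        truth_lineage = {
            (ev.codon_index, ev.offset): ev.lineage
            for ev in ds.truth.events
            if ev.kind == "fixation" and ev.lineage in ("a", "b")
            and ev.codon_index not in skip
        }
        changes = [c for c in call_changes(ds.alignment)
                   if c.codon_index not in skip]
        for focal in ("a", "b"):
            assigned = {
                c.site for c in polarize(changes, ds.alignment, focal)
                if c.category == "fixed"
            }
            for site in assigned:
                assert truth_lineage[site] == focal

    def test_sample_sizes_respected(self):
        ds = emit_dataset(default_config(n_a=5, n_b=9))
        assert len(ds.alignment.species_a_lines) == 5
        assert len(ds.alignment.species_b_lines) == 9
        assert ds.alignment.outgroup is not None

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            default_config(n_a=1)
        with pytest.raises(SimulationError):
            default_config(t_a=-0.1)
        with pytest.raises(SimulationError):
            default_config(sfs="bogus")
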
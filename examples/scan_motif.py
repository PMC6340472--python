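"""Scan proteins with a degenerate PROSITE-style motif.

Uses the S/TP-region pattern [ST]-P-X(5,8)-S-P-X-[LIM]-S-P-I — the
critical phospho-motif residues of a Polo-kinase-binding region at their
native spacing — to find the motif in synthetic protein sequences, the
way a pattern-hit-initiated homology search seeds on a conserved block
inside otherwise unalignable sequence.
"""

from mkregions import parse_pattern, region_percent_identity, scan_sequence
from mkregions.alignment_io import Region, RegionPartition

PATTERN = "[ST]-P-X(5,8)-S-P-X-[LIM]-S-P-I"
pattern = parse_pattern(PATTERN)
print(f"pattern {PATTERN}")
print(f"  {len(pattern.elements)} elements, span {pattern.min_span}"
      f"-{pattern.max_span} residues\n")

# synthetic proteins: a conserved motif embedded in divergent sequence
proteins = {
    "species_1": "MNEQRLVTPADKWGESPALSPIKHHDDELVMRAAT",
    "species_2": "MSDFKTPQQQQQSPQMSPIWNNAAGHRE",
    "species_3": "MNEQRLVAPADKWGESPALSPIKHHDDELVMRAAT",  # T->A: motif broken
}
for name, seq in proteins.items():
    hits = scan_sequence(pattern, seq, name)
    if not hits:
        print(f"{name}: no match")
    for h in hits:
        print(f"{name}: residues {h.start}-{h.end}  {h.matched}")

# per-region identity between two aligned homologs (alignment columns)
regions = RegionPartition((Region("N-term", 1, 7), Region("motif", 8, 22),
                           Region("C-term", 23, 35)))
identity = region_percent_identity(
    proteins["species_1"], proteins["species_3"], regions
)
print()
for region, pct in identity.items():
    print(f"identity {region}: {pct:.1f}%")
print()
print("The motif region stays identical while a single substitution at the")
print("pattern's anchoring threonine abolishes the hit — degenerate motifs")
print("separate conserved functional blocks from background divergence.")
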
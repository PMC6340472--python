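"""Independent brute-force re-implementations used only as test oracles.

Everything here is written directly from the definitions (no imports from
the package's counting code) so the pipeline can be checked against it on
small random instances.
"""

from collections import Counter

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def is_stop(codon):
    return GENETIC_CODE[codon] == "*"


def pathway_weights(codon_from, codon_to):
    """Per-site (nonsyn, syn) weights by explicit path enumeration.

    Recursively walks every order of single-site steps from codon_from to
    codon_to, pruning paths that enter a stop codon, and averages each
    site's nonsynonymous indicator over complete paths.
    """
    paths = []

    def walk(current, remaining, steps):
        if not remaining:
            paths.append(list(steps))
            return
        for site in remaining:
            nxt = current[:site] + codon_to[site] + current[site + 1:]
            if is_stop(nxt):
                continue
            steps.append((site, GENETIC_CODE[current] != GENETIC_CODE[nxt]))
            walk(nxt, [s for s in remaining if s != site], steps)
            steps.pop()

    diff = [i for i in range(3) if codon_from[i] != codon_to[i]]
    walk(codon_from, diff, [])
    if not paths:
        return {}
    out = {}
    for site in diff:
        nonsyn_share = sum(
            1 for p in paths for s, ns in p if s == site and ns
        ) / len(paths)
        out[site] = (nonsyn_share, 1.0 - nonsyn_share)
    return out


def majority(tally):
    """Most common codon, lexicographically smallest on ties."""
    top = max(tally.values())
    return min(c for c, n in tally.items() if n == top)


def enumerate_changes(seqs_a, seqs_b):
    """Brute-force change list for an alignment given as sequence lists.

    Returns tuples (codon_index, offset, category, nonsyn_w, syn_w,
    minor_count, sample_size) sorted like the pipeline output.
    """
    changes = []
    n_codons = len(seqs_a[0]) // 3
    for ci in range(1, n_codons + 1):
        tallies = {}
        for species, seqs in (("a", seqs_a), ("b", seqs_b)):
            t = Counter()
            for s in seqs:
                codon = s[3 * (ci - 1): 3 * ci]
                if all(ch in "ACGT" for ch in codon):
                    t[codon] += 1
            tallies[species] = t
        majors = {}
        for species, t in tallies.items():
            n = sum(t.values())
            if n < 2:
                majors[species] = None
                continue
            maj = majority(t)
            majors[species] = maj
            if is_stop(maj):
                continue
            for off in range(3):
                alleles = Counter()
                for codon, count in t.items():
                    alleles[codon[off]] += count
                if len(alleles) < 2:
                    continue
                for allele in sorted(alleles):
                    if allele == maj[off]:
                        continue
                    mutant = maj[:off] + allele + maj[off + 1:]
                    if is_stop(mutant):
                        continue
                    w = pathway_weights(maj, mutant)[off]
                    changes.append(
                        (ci, off, f"polymorphic_{species}", w[0], w[1],
                         alleles[allele], n)
                    )
        ma, mb = majors["a"], majors["b"]
        if ma is None or mb is None or is_stop(ma) or is_stop(mb):
            continue
        weights = pathway_weights(ma, mb)
        for off in range(3):
            aa = {c[off] for c in tallies["a"]}
            bb = {c[off] for c in tallies["b"]}
            if len(aa) == 1 and len(bb) == 1 and aa != bb and off in weights:
                changes.append(
                    (ci, off, "fixed", weights[off][0], weights[off][1], 0,
                     min(sum(tallies["a"].values()), sum(tallies["b"].values())))
                )
    changes.sort(key=lambda c: (c[0], c[1], c[2], c[5]))
    return changes
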
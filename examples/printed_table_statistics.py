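"""Derive MK statistics from per-region count tables.

Takes the published per-region (dN, dS, pN, pS) quadruples for a
region-partitioned MK study of a rapidly evolving meiotic gene and
recomputes the three derived statistics: the two-tailed Fisher exact
p-value, alpha (the estimated proportion of adaptive substitutions), and
DoS (direction of selection).
"""

from mkregions import compute_alpha, compute_dos, fisher_exact_2x2

TABLES = [
    ("Full CDS", (7, 4, 2, 25)),
    ("N-terminal", (2, 1, 0, 1)),
    ("S/TP", (0, 0, 0, 2)),
    ("Central", (5, 2, 1, 8)),
    ("SAM-proximal", (0, 0, 0, 3)),
    ("SAM domain", (0, 1, 1, 11)),
]


def fmt(x):
    return "NA" if x is None else f"{x:.3f}"


print(f"{'region':<14}{'dN':>4}{'dS':>4}{'pN':>4}{'pS':>4}"
      f"{'p':>10}{'alpha':>8}{'DoS':>8}")
for region, (dN, dS, pN, pS) in TABLES:
    p = fisher_exact_2x2(dN, dS, pN, pS)
    alpha = compute_alpha(dN, dS, pN, pS)
    dos = compute_dos(dN, dS, pN, pS)
    print(f"{region:<14}{dN:>4}{dS:>4}{pN:>4}{pS:>4}"
          f"{p:>10.3g}{fmt(alpha):>8}{fmt(dos):>8}")

print()
print("A small p with positive DoS (Full CDS, Central) is the signature of")
print("adaptive fixation excess; NA cells are boundary tables where the")
print("statistic is undefined (no divergent substitutions of one class).")
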
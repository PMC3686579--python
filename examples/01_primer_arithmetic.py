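"""Degenerate-primer arithmetic on the bundled COI primer table.

Prints the fold degeneracy (how many concrete oligos the IUPAC string
encodes), the number of degenerate synthesis positions, and the literal
reverse complement — which for the mini-barcode pair is deliberately NOT the
printed reverse primer (five W positions were synthesised as S).
"""

from minicoi import (count_degenerate_positions, degeneracy, expand,
                     reverse_complement)
from minicoi.io import load_primer_table

primers = load_primer_table()
for name in ("mlCOIintF", "mlCOIintR", "jgHCO2198", "LCO1490"):
    p = primers[name]
    print(f"{name:12s} {p.sequence:30s} degeneracy={degeneracy(p):4d} "
          f"degenerate_sites={count_degenerate_positions(p)}")

fwd = primers["mlCOIintF"]
print("\nliteral reverse complement of mlCOIintF:", reverse_complement(fwd.sequence))
print("printed mlCOIintR                       :", primers["mlCOIintR"].sequence)
diff = [i + 1 for i, (a, b) in enumerate(zip(reverse_complement(fwd.sequence),
                                             primers["mlCOIintR"].sequence)) if a != b]
print(f"they differ at positions {diff} (W vs S)")

members = expand(fwd)
print(f"\nmlCOIintF expands to {len(members)} concrete 26-mers; one of them:",
      sorted(members)[0])
print("A 128-fold degenerate primer is one synthesis tube containing 128 "
      "distinct oligos, which is what lets it anneal across divergent taxa.")
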
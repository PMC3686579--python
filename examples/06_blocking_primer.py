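"""Design a predator-blocking primer.

A blocking primer overlaps the 3' end of a universal priming site on the
predator's own template and extends into predator-specific sequence; its 3'
end carries a C3 spacer so it anneals but cannot be extended, suppressing
predator amplification while leaving prey templates free. A candidate is
rejected when any prey reference is too similar in the extension region.
"""

from minicoi import design_blocking_primer, find_binding_sites
from minicoi.io import load_blocking_primers, load_primer_table
from minicoi.sim import SimSpec, make_reference_panel

primers = load_primer_table()
panel = make_reference_panel(SimSpec(seed=15, n_species=6))

predator_id = panel.barcodes[0][0]
template = panel.template(predator_id)
site = [s for s in find_binding_sites(primers["jgHCO2198"], template, 0)
        if s.strand == "-"][0]
print(f"universal reverse site on the predator template: "
      f"{site.start}-{site.end} ({site.strand} strand)")

prey = {rid: panel.template(rid) for rid, _ in panel.barcodes
        if panel.species_of[rid] != panel.species_of[predator_id]}
blocker = design_blocking_primer(template, site, overlap_len=10, total_len=29,
                                 prey_refs=prey, min_prey_mismatches=2)
print(f"blocker ({len(blocker.sequence)} nt, 3'-blocked): {blocker.sequence}")
print(f"overlap with universal site: template {blocker.overlap_span}, "
      f"extension: {blocker.extension_span}")
print("prey mismatches in the extension:", blocker.prey_mismatches)

print("\nthe three published 29-nt blockers ship as fixtures:")
for name, b in load_blocking_primers().items():
    print(f"  {name:14s} {b.sequence}")
print("More extension mismatches against prey means less collateral "
      "suppression of the prey signal.")
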
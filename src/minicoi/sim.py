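"""Seeded generators for every input class the toolkit consumes: codon-
structured reference panels with a conserved priming window, lineage tables,
frequency-encoded alignments for consensus round-trips, and tagged gut-content
read sets with planted reading-frame violations and chimeras.

The generated data emulate a predator gut-content metabarcoding experiment:
a mini-barcode insert amplified between a conserved internal forward site and
a conserved reverse site, multiplexed hierarchically (per-pool MIDs plus 6-bp
sample tags on both primer ends), with abundant intact predator DNA over
degraded prey DNA. The sequencing error model is deliberately simple —
substitutions plus whole events planted at stated rates (stop mutations,
single-nucleotide frameshifts, whole-codon indels, two-parent chimeras) —
rather than a flowgram simulation.

Determinism: the same spec (including seed) reproduces byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iupac import (DegeneratePrimer, INVERTEBRATE_MITO, IUPAC_SETS,
                    reverse_complement, translate)
from .io import RANKS, load_primer_table, load_tags
from .qc import SampleTagScheme

BASES = "ACGT"
PHYLA = ["Arthropoda", "Mollusca", "Annelida", "Chordata"]


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the generator.

    Divergences are per-site substitution fractions on the insert region;
    ``intra`` must be strictly below ``inter``. Violation fractions partition
    the read stream (their sum must be <= 1; the rest are clean reads).
    """

    seed: int = 0
    n_species: int = 12
    n_refs_per_species: int = 2
    barcode_length: int = 658
    window_start: int = 320          # 1-based, inclusive
    intra_divergence: float = 0.02
    inter_divergence: float = 0.12
    n_samples: int = 16
    reads_per_sample: int = 300
    n_predator_species: int = 3
    predator_fraction: float = 0.15
    substitution_rate: float = 0.0
    stop_fraction: float = 0.0
    frameshift_fraction: float = 0.0
    codon_insertion_fraction: float = 0.0
    codon_deletion_pass_fraction: float = 0.0    # 1-3 codons: tolerated
    codon_deletion_discard_fraction: float = 0.0  # 4 codons: discarded
    chimera_fraction: float = 0.0
    chimera_min_segment: int = 104   # middle-third breakpoints on a 313-nt insert
    tag_length: int = 6
    mid_length: int = 8

    def validate(self) -> None:
        fractions = [self.predator_fraction, self.substitution_rate,
                     self.stop_fraction, self.frameshift_fraction,
                     self.codon_insertion_fraction,
                     self.codon_deletion_pass_fraction,
                     self.codon_deletion_discard_fraction,
                     self.chimera_fraction]
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise ValueError("all rates must lie in [0, 1]")
        if self.violation_total > 1.0:
            raise ValueError("violation fractions sum past 1")
        if not (0 <= self.intra_divergence < self.inter_divergence <= 0.5):
            raise ValueError("need intra < inter divergence, both feasible")
        if self.n_predator_species > self.n_species:
            raise ValueError("more predator species than species")

    @property
    def violation_total(self) -> float:
        return (self.stop_fraction + self.frameshift_fraction
                + self.codon_insertion_fraction
                + self.codon_deletion_pass_fraction
                + self.codon_deletion_discard_fraction + self.chimera_fraction)


@dataclass
class ReferencePanel:
    """A generated reference set with known structure.

    ``barcodes`` hold the full-length region per reference individual;
    ``inserts`` the mini-barcode region between the primer footprints (in
    frame 0); ``qc_references`` the inserts trimmed to complete codons, the
    form consumed by the frame classifier. ``species_of`` maps reference id ->
    species name. The true alignment is the barcodes themselves (the
    generator introduces no indels between references).
    """

    spec: SimSpec
    forward_member: str
    reverse_member: str
    lco_site: str
    barcodes: list[tuple[str, str]]
    inserts: list[tuple[str, str]]
    lineage: pd.DataFrame
    species_of: dict[str, str]
    centroid_of_species: dict[str, str]  # species -> reference id of centroid
    insert_start: int  # 0-based offset of the insert within the barcode

    @property
    def qc_references(self) -> list[tuple[str, str]]:
        return [(rid, seq[:len(seq) - len(seq) % 3]) for rid, seq in self.inserts]

    def template(self, ref_id: str) -> str:
        """Amplifiable template: upstream forward-barcoding site, the full
        region, then the reverse-complemented reverse priming site."""
        barcode = dict(self.barcodes)[ref_id]
        return self.lco_site + barcode + reverse_complement(self.reverse_member)

    def reference_db(self):
        lin = self.lineage.set_index("seq_id")
        return [(rid, seq, {r: lin.loc[rid, r] for r in RANKS})
                for rid, seq in self.inserts]


def _sample_member(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[ch])) for ch in primer.sequence)


def _has_stop(seq: str) -> bool:
    return bool(translate(seq, INVERTEBRATE_MITO, 0)[1])


def _fix_stops(seq: list[str], protected: set[int], rng: np.random.Generator,
               max_rounds: int = 200) -> bool:
    """Resample free bases inside stop codons until the frame-0 translation is
    stop-free. Returns False when a stop codon is fully protected."""
    for _ in range(max_rounds):
        _, stops = translate("".join(seq), INVERTEBRATE_MITO, 0)
        if not stops:
            return True
        fixed_any = False
        for c in stops:
            free = [p for p in range(3 * c, 3 * c + 3) if p < len(seq) and p not in protected]
            if not free:
                return False
            p = int(rng.choice(free))
            seq[p] = rng.choice([b for b in BASES if b != seq[p]])
            fixed_any = True
        if not fixed_any:
            return False
    return not _has_stop("".join(seq))


def make_reference_panel(spec: SimSpec,
                         forward_primer: DegeneratePrimer | None = None,
                         reverse_primer: DegeneratePrimer | None = None) -> ReferencePanel:
    """Generate an in-frame, stop-free reference panel.

    The conserved window (default: region 320-345 of a 658-nt barcode)
    carries one concrete expansion member of the forward primer, identical in
    every reference; species centroids diverge from a common ancestor at the
    inter-species rate outside the window, conspecific references at the
    intra-species rate, with pairwise insert-region divergence constraints
    enforced by construction. Raises when the spec is infeasible.
    """
    spec.validate()
    primers = load_primer_table()
    fwd = forward_primer or primers["mlCOIintF"]
    rev = reverse_primer or primers["jgHCO2198"]
    lco = primers["LCO1490"].sequence
    rng = np.random.default_rng(spec.seed)
    L = spec.barcode_length
    w0 = spec.window_start - 1
    w1 = w0 + len(fwd.sequence)  # half-open
    if w1 > L:
        raise ValueError("window does not fit in the barcode")
    window_pos = set(range(w0, w1))
    insert_start = w1
    ins_len = L - insert_start

    non_stop = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in INVERTEBRATE_MITO.stops]

    ancestor = None
    fwd_member = None
    for _ in range(100):
        member = _sample_member(fwd, rng)
        codons = rng.choice(non_stop, size=L // 3 + 1)
        seq = list("".join(codons)[:L])
        seq[w0:w1] = list(member)
        if _fix_stops(seq, window_pos, rng):
            ancestor = "".join(seq)
            fwd_member = member
            break
    if ancestor is None:
        raise ValueError("could not realize a stop-free ancestor with this window")
    rev_member = _sample_member(rev, rng)

    k_insert = max(1, round(spec.inter_divergence * ins_len))
    k_upstream = max(0, round(spec.inter_divergence * w0))
    insert_positions = np.arange(insert_start, L)
    upstream_positions = np.arange(0, w0)

    def mutate(base_seq: str, k_ins: int, k_up: int) -> str:
        seq = list(base_seq)
        chosen = list(rng.choice(insert_positions, size=min(k_ins, ins_len), replace=False))
        if k_up and w0:
            chosen += list(rng.choice(upstream_positions, size=min(k_up, w0), replace=False))
        for p in chosen:
            seq[int(p)] = rng.choice([b for b in BASES if b != seq[int(p)]])
        if not _fix_stops(seq, window_pos, rng):
            raise ValueError("could not keep mutant stop-free")
        return "".join(seq)

    def insert_div(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a[insert_start:], b[insert_start:]))

    centroids: list[str] = []
    for s in range(spec.n_species):
        for _ in range(200):
            cand = mutate(ancestor, k_insert, k_upstream)
            if all(insert_div(cand, c) >= k_insert for c in centroids):
                centroids.append(cand)
                break
        else:
            raise ValueError("could not satisfy the inter-species divergence target")

    max_intra = int(spec.intra_divergence * ins_len)
    barcodes: list[tuple[str, str]] = []
    species_of: dict[str, str] = {}
    centroid_of: dict[str, str] = {}
    lineage_rows = []
    for s, centroid in enumerate(centroids, start=1):
        sp_name = f"Species_{s:02d}"
        for r in range(1, spec.n_refs_per_species + 1):
            rid = f"sp{s:02d}_r{r}"
            if r == 1:
                seq = centroid
                centroid_of[sp_name] = rid
            else:
                j = int(rng.integers(0, max_intra + 1))
                seq = mutate(centroid, j, min(j, w0)) if j else centroid
            barcodes.append((rid, seq))
            species_of[rid] = sp_name
            phylum = PHYLA[(s - 1) % len(PHYLA)]
            lineage_rows.append({
                "seq_id": rid, "kingdom": "Animalia", "phylum": phylum,
                "class": f"{phylum}_class", "order": f"Order_{(s - 1) // 4 + 1:02d}",
                "family": f"Family_{(s - 1) // 2 + 1:02d}",
                "genus": f"Genus_{(s - 1) // 2 + 1:02d}", "species": sp_name,
            })
    inserts = [(rid, seq[insert_start:]) for rid, seq in barcodes]
    return ReferencePanel(spec=spec, forward_member=fwd_member,
                          reverse_member=rev_member, lco_site=lco,
                          barcodes=barcodes, inserts=inserts,
                          lineage=pd.DataFrame(lineage_rows),
                          species_of=species_of, centroid_of_species=centroid_of,
                          insert_start=insert_start)


def make_window_alignment(primer: DegeneratePrimer, n_rows: int, n_cols: int,
                          window_start: int, seed: int = 0) -> list[tuple[str, str]]:
    """An alignment whose window columns encode the primer's base sets as
    frequencies: in a window column with base set S, row i carries
    sorted(S)[i mod |S|], so every base of S appears at frequency ~1/|S| and
    single-base columns are exactly conserved (h = 0). Non-window columns mix
    two bases at uneven frequencies, so their entropy is strictly positive.
    Consensus calling on the window at a small minimum frequency returns the
    primer exactly (the round-trip fixture).
    """
    rng = np.random.default_rng(seed)
    w0 = window_start - 1
    w1 = w0 + len(primer.sequence)
    if w1 > n_cols:
        raise ValueError("window does not fit")
    cols = []
    for j in range(n_cols):
        if w0 <= j < w1:
            pool = sorted(IUPAC_SETS[primer.sequence[j - w0]])
            cols.append([pool[i % len(pool)] for i in range(n_rows)])
        else:
            two = rng.choice(list(BASES), size=2, replace=False)
            split = int(rng.integers(max(1, n_rows // 3), max(2, 2 * n_rows // 3)))
            col = [two[0]] * split + [two[1]] * (n_rows - split)
            cols.append(col)
    return [(f"row{i + 1:03d}", "".join(cols[j][i] for j in range(n_cols)))
            for i in range(n_rows)]


def default_sample_layout(spec: SimSpec, rng: np.random.Generator):
    """Hierarchical scheme: published 6-bp tags cycled within pools of five,
    one generated MID per pool; predators assigned round-robin."""
    tags = list(load_tags().values())
    n_pools = (spec.n_samples + len(tags) - 1) // len(tags)
    mids = []
    while len(mids) < n_pools:
        mid = "".join(rng.choice(list(BASES), size=spec.mid_length))
        if mid not in mids:
            mids.append(mid)
    scheme = []
    predator_map = {}
    for i in range(spec.n_samples):
        sid = f"S{i + 1:02d}"
        scheme.append(SampleTagScheme(sid, mids[i // len(tags)],
                                      tags[i % len(tags)][:spec.tag_length]))
        predator_map[sid] = f"Species_{(i % spec.n_predator_species) + 1:02d}"
    return scheme, predator_map


def make_gut_reads(spec: SimSpec, panel: ReferencePanel):
    """Generate tagged gut-content reads plus an exhaustive truth table.

    Read layout: MID + tag + forward priming site + insert + rc(reverse
    priming site) + rc(tag) + rc(MID). Violations are planted in the read
    interior (>= 10 nt from the insert ends; an end-free aligner cannot, even
    in principle, classify terminal indels). Truth verdicts use the QC
    vocabulary so comparisons are mechanical.

    Returns (reads, truth, scheme, predator_map).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    scheme, predator_map = default_sample_layout(spec, rng)
    inserts = dict(panel.inserts)
    ref_ids = [rid for rid, _ in panel.inserts]
    predators = {f"Species_{i + 1:02d}" for i in range(spec.n_predator_species)}
    prey_refs = [r for r in ref_ids if panel.species_of[r] not in predators]
    refs_by_species: dict[str, list[str]] = {}
    for rid in ref_ids:
        refs_by_species.setdefault(panel.species_of[rid], []).append(rid)

    categories = ["discard_stop", "repaired", "discard_insertion",
                  "pass_deletion", "discard_deletion", "discard_chimera"]
    weights = [spec.stop_fraction, spec.frameshift_fraction,
               spec.codon_insertion_fraction, spec.codon_deletion_pass_fraction,
               spec.codon_deletion_discard_fraction, spec.chimera_fraction]
    weights = [1.0 - sum(weights)] + weights
    categories = ["pass"] + categories

    non_stop = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in INVERTEBRATE_MITO.stops]

    reads: list[tuple[str, str]] = []
    truth_rows = []
    counter = 0
    for s in scheme:
        predator = predator_map[s.sample_id]
        for _ in range(spec.reads_per_sample):
            counter += 1
            read_id = f"read{counter:06d}"
            if rng.random() < spec.predator_fraction:
                rid = rng.choice(refs_by_species[predator])
            else:
                rid = rng.choice(prey_refs)
            insert = inserts[rid]
            L = len(insert)
            n_codons = L // 3
            cat = rng.choice(categories, p=np.array(weights) / sum(weights))
            parent_b = None
            verdict = "pass"
            if cat == "discard_stop":
                c = int(rng.integers(4, n_codons - 4))
                stop = rng.choice(["TAA", "TAG"])
                insert = insert[:3 * c] + stop + insert[3 * c + 3:]
                verdict = "discard_stop"
            elif cat == "repaired":
                p = int(rng.integers(10, L - 10))
                insert = insert[:p] + insert[p + 1:]
                verdict = "repaired"
            elif cat == "discard_insertion":
                c = int(rng.integers(4, n_codons - 4))
                insert = insert[:3 * c] + rng.choice(non_stop) + insert[3 * c:]
                verdict = "discard_insertion"
            elif cat == "pass_deletion":
                k = int(rng.integers(1, 4))
                c = int(rng.integers(4, n_codons - 4 - k))
                insert = insert[:3 * c] + insert[3 * (c + k):]
                verdict = "pass"
            elif cat == "discard_deletion":
                c = int(rng.integers(4, n_codons - 8))
                insert = insert[:3 * c] + insert[3 * (c + 4):]
                verdict = "discard_deletion"
            elif cat == "discard_chimera":
                other_species = rng.choice(
                    [sp for sp in refs_by_species if sp != panel.species_of[rid]])
                parent_b = panel.centroid_of_species[other_species]
                rid_a = panel.centroid_of_species[panel.species_of[rid]]
                b = int(rng.integers(spec.chimera_min_segment,
                                     L - spec.chimera_min_segment + 1))
                insert = inserts[rid_a][:b] + inserts[parent_b][b:]
                rid = rid_a
                verdict = "discard_chimera"
            if spec.substitution_rate > 0:
                seq = list(insert)
                hits = np.nonzero(rng.random(len(seq)) < spec.substitution_rate)[0]
                for p in hits:
                    seq[p] = rng.choice([b for b in BASES if b != seq[p]])
                insert = "".join(seq)
            read = (s.mid + s.tag + panel.forward_member + insert
                    + reverse_complement(panel.reverse_member)
                    + reverse_complement(s.tag) + reverse_complement(s.mid))
            reads.append((read_id, read))
            truth_rows.append({
                "read_id": read_id, "sample_id": s.sample_id,
                "source": rid, "source_species": panel.species_of[rid],
                "planted_verdict": verdict,
                "is_chimera": verdict == "discard_chimera",
                "chimera_parent_b": parent_b or "",
            })
    truth = pd.DataFrame(truth_rows)
    return reads, truth, scheme, predator_map
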
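"""OTU clustering, identity-threshold taxonomy with rank fallback, OTU
tables, diet summaries and analytic rarefaction.

Clustering is deterministic greedy centroid clustering over dereplicated,
abundance-sorted sequences: a sequence joins the first centroid within the
dissimilarity radius (default 0.07, the midpoint of the 6–8% band typical of
COI species delineation in marine invertebrates), else founds a new OTU. It is
a behavioural surrogate for Bayesian OTU pickers, not a re-implementation of
one.

Identity is matches / alignment columns under global alignment with end-gap
columns excluded; this convention is stated here because published "percent
identity" figures vary in their denominator.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .align import pairwise_identity
from .io import RANKS

#: Abundance classes used for reporting OTU size spectra.
ABUNDANCE_CLASSES = [(1, 1, "1"), (2, 9, "2-9"), (10, 99, "10-99"),
                     (100, 999, "100-999"), (1000, None, ">=1000")]

DEFAULT_FALLBACK_BANDS = [(0.95, "genus"), (0.90, "family"), (0.85, "order"),
                          (0.80, "class"), (0.70, "phylum")]


@dataclass
class TaxonAssignment:
    """Taxonomic call for one OTU representative.

    ``method`` is 'species_match' (best identity at or above the species
    threshold), 'rank_consensus' (identity-banded consensus across reference
    hits) or 'unidentified' (nothing above the lowest band floor).
    """

    method: str
    best_identity: float
    taxon_path: dict[str, str] = field(default_factory=dict)
    assigned_rank: str | None = None
    best_reference: str | None = None


@dataclass
class OTU:
    otu_id: str
    representative: str
    members: list[str] = field(default_factory=list)  # read ids
    sample_counts: Counter = field(default_factory=Counter)
    assignment: TaxonAssignment | None = None

    @property
    def abundance(self) -> int:
        return len(self.members)


def dereplicate(reads: list[tuple[str, str, str]]):
    """Collapse identical sequences. Input rows are (read_id, sample_id, seq);
    returns a list of (seq, abundance, [(read_id, sample_id), ...]) sorted by
    abundance descending, ties lexicographic by sequence (deterministic)."""
    groups: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for read_id, sample_id, seq in reads:
        groups[seq.upper()].append((read_id, sample_id))
    derep = [(seq, len(items), items) for seq, items in groups.items()]
    derep.sort(key=lambda t: (-t[1], t[0]))
    return derep


def cluster_otus(reads: list[tuple[str, str, str]], radius: float = 0.07) -> list[OTU]:
    """Greedy centroid clustering of reads (read_id, sample_id, sequence) at a
    dissimilarity ``radius``.

    Sequences are dereplicated and visited in abundance-descending order
    (ties lexicographic); each joins the first existing centroid within the
    radius, else founds a new OTU whose representative it becomes. With
    radius 0 every unique sequence founds its own OTU. The representative is
    always the most abundant member sequence.
    """
    if not reads:
        raise ValueError("no sequences to cluster")
    if not (0 <= radius < 0.5):
        raise ValueError("radius must lie in [0, 0.5)")
    derep = dereplicate(reads)
    otus: list[OTU] = []
    for seq, _, items in derep:
        home = None
        for otu in otus:
            if seq == otu.representative or \
                    (radius > 0 and 1.0 - pairwise_identity(seq, otu.representative) <= radius):
                home = otu
                break
        if home is None:
            home = OTU(otu_id=f"OTU_{len(otus) + 1:04d}", representative=seq)
            otus.append(home)
        for read_id, sample_id in items:
            home.members.append(read_id)
            home.sample_counts[sample_id] += 1
    return otus


def assign_taxonomy(representative: str,
                    reference_db: list[tuple[str, str, dict[str, str]]],
                    species_threshold: float = 0.98,
                    fallback_bands=None) -> TaxonAssignment:
    """Assign one OTU representative against a reference database of
    (seq_id, sequence, lineage) rows.

    Best identity >= ``species_threshold`` (inclusive) gives a species-level
    match to the best hit. Otherwise the applicable fallback band (the highest
    band floor not exceeding the best identity) caps the assignable rank, and
    the assignment is the deepest rank, up to that cap, on which all reference
    hits within the band floor agree. Below the lowest floor the OTU is
    unidentified.
    """
    if not reference_db:
        raise ValueError("empty reference database")
    bands = sorted(fallback_bands or DEFAULT_FALLBACK_BANDS, reverse=True)
    idents = [(pairwise_identity(representative, seq), seq_id, lineage)
              for seq_id, seq, lineage in reference_db]
    best_ident, best_id, best_lineage = max(idents, key=lambda t: t[0])
    if best_ident >= species_threshold:
        return TaxonAssignment("species_match", best_ident,
                               dict(best_lineage), "species", best_id)
    band = next(((floor, rank) for floor, rank in bands if best_ident >= floor), None)
    if band is None:
        return TaxonAssignment("unidentified", best_ident)
    floor, rank_cap = band
    hits = [lineage for ident, _, lineage in idents if ident >= floor]
    cap_depth = RANKS.index(rank_cap)
    path: dict[str, str] = {}
    assigned = None
    for depth, rank in enumerate(RANKS):
        if depth > cap_depth:
            break
        values = {h.get(rank) for h in hits}
        if len(values) == 1 and None not in values:
            path[rank] = values.pop()
            assigned = rank
        else:
            break
    if assigned is None:
        return TaxonAssignment("unidentified", best_ident)
    return TaxonAssignment("rank_consensus", best_ident, path, assigned, best_id)


def abundance_class(n: int) -> str:
    for lo, hi, label in ABUNDANCE_CLASSES:
        if n >= lo and (hi is None or n <= hi):
            return label
    raise ValueError(f"abundance {n} outside all classes")


def build_otu_table(otus: list[OTU], samples: list[str] | None = None) -> pd.DataFrame:
    """OTU x sample abundance matrix. Row/column sums equal member counts;
    empty samples keep their zero column."""
    if samples is None:
        samples = sorted({s for o in otus for s in o.sample_counts})
    data = {o.otu_id: [o.sample_counts.get(s, 0) for s in samples] for o in otus}
    df = pd.DataFrame(data, index=samples).T
    for o in otus:
        missing = set(o.sample_counts) - set(samples)
        if missing:
            raise ValueError(f"{o.otu_id} has reads from unknown samples {sorted(missing)}")
    return df


def abundance_class_tally(otus: list[OTU]) -> pd.Series:
    labels = [label for _, _, label in ABUNDANCE_CLASSES]
    counts = Counter(abundance_class(o.abundance) for o in otus)
    return pd.Series([counts.get(l, 0) for l in labels], index=labels, name="otus")


def phylum_tally(otus: list[OTU]) -> pd.Series:
    counts = Counter((o.assignment.taxon_path.get("phylum") if o.assignment
                      and o.assignment.taxon_path else "unknown") or "unknown"
                     for o in otus)
    return pd.Series(dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))),
                     name="otus")


def remove_self_otus(otus: list[OTU], predator_species: dict[str, str]):
    """Drop OTUs assigned to the host predator of a sample they occur in.

    ``predator_species`` maps sample_id -> predator species name. Only
    species-level assignments are eligible; congeners and unassigned OTUs are
    retained. Returns (kept, report) where report lists removed ids with
    their abundances and the matching predator."""
    kept, report = [], []
    for o in otus:
        removed = False
        if o.assignment and o.assignment.method == "species_match":
            sp = o.assignment.taxon_path.get("species")
            hosts = {predator_species.get(s) for s in o.sample_counts}
            if sp is not None and sp in hosts:
                report.append({"otu_id": o.otu_id, "species": sp,
                               "abundance": o.abundance})
                removed = True
        if not removed:
            kept.append(o)
    return kept, report


@dataclass
class DietSummary:
    """Within- and between-predator OTU sharing plus phylum breakdowns."""

    intraspecific: dict[str, dict] = field(default_factory=dict)
    interspecific: dict[str, dict] = field(default_factory=dict)
    abundance_classes: dict[str, int] = field(default_factory=dict)
    phyla: dict[str, int] = field(default_factory=dict)


def diet_summaries(otus: list[OTU], predator_species: dict[str, str]) -> DietSummary:
    """Summarise prey OTU sharing within and between predator species.

    Samples are individual predators; ``predator_species`` maps sample ->
    species. For each predator species: how many of its OTUs occur in exactly
    one, exactly two, or more than two individuals (with the phylum breakdown
    of the shared ones). Across species: the proportion of each species' OTUs
    also found in at least one other predator species.
    """
    species = sorted(set(predator_species.values()))
    otus_by_species: dict[str, set[str]] = {sp: set() for sp in species}
    summary = DietSummary()
    for sp in species:
        individuals = [s for s, p in predator_species.items() if p == sp]
        counts = {}
        for o in otus:
            n_ind = sum(1 for s in individuals if o.sample_counts.get(s, 0) > 0)
            if n_ind > 0:
                counts[o.otu_id] = n_ind
                otus_by_species[sp].add(o.otu_id)
        total = len(counts)
        in1 = sum(1 for v in counts.values() if v == 1)
        in2 = sum(1 for v in counts.values() if v == 2)
        more = sum(1 for v in counts.values() if v > 2)
        shared_ids = {oid for oid, v in counts.items() if v > 2}
        shared_phyla = Counter(
            (o.assignment.taxon_path.get("phylum") if o.assignment
             and o.assignment.taxon_path else "unknown") or "unknown"
            for o in otus if o.otu_id in shared_ids)
        summary.intraspecific[sp] = {
            "n_otus": total, "in_1": in1, "in_2": in2, "in_more": more,
            "prop_1": in1 / total if total else float("nan"),
            "prop_2": in2 / total if total else float("nan"),
            "prop_more": more / total if total else float("nan"),
            "shared_phyla": dict(shared_phyla),
        }
    for sp in species:
        mine = otus_by_species[sp]
        others = set().union(*(otus_by_species[o] for o in species if o != sp)) \
            if len(species) > 1 else set()
        shared = mine & others
        summary.interspecific[sp] = {
            "n_otus": len(mine), "shared_with_others": len(shared),
            "prop_shared": len(shared) / len(mine) if mine else float("nan"),
        }
    summary.abundance_classes = abundance_class_tally(otus).to_dict()
    summary.phyla = phylum_tally(otus).to_dict()
    return summary


def rarefaction_curve(abundances, depths) -> pd.DataFrame:
    """Analytic rarefaction: expected OTU richness at each subsampling depth.

    E[S(d)] = sum_i 1 - C(N - n_i, d) / C(N, d), the hypergeometric
    expectation over all C(N, d) equally likely subsamples without
    replacement. Monotone non-decreasing in d; equals the observed richness
    at d = N and 1 at d = 1 (for a non-empty sample).
    """
    n = np.asarray([a for a in abundances if a > 0], dtype=float)
    if n.size == 0:
        raise ValueError("empty abundance vector")
    N = n.sum()
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths < 1).any() or (depths > N).any():
        raise ValueError(f"depths must lie in 1..{int(N)}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rows = []
    for d in depths:
        ok = (N - n) >= d
        term = np.zeros_like(n)
        term[ok] = np.exp(log_comb(N - n[ok], d) - log_comb(N, d))
        rows.append({"depth": int(d), "expected_otus": float((1.0 - term).sum())})
    return pd.DataFrame(rows)
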
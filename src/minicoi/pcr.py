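"""IUPAC-aware in-silico PCR: primer-template annealing, amplicon extraction
and mismatch-distribution reports.

Matching is gapless set-intersection on IUPAC codes: a primer position
mismatches iff its base set and the template position's base set are disjoint.
Inosine never mismatches. Template N matches everything by default; a strict
mode counts template N as a mismatch. No 3'-end weighting is applied — the
report counts raw mismatches along the oligo.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import DegeneratePrimer, IUPAC_SETS, normalize, reverse_complement

#: 4-bit base masks (A=1, C=2, G=4, T=8); a primer/template symbol pair
#: mismatches iff the bitwise AND of their masks is zero. Inosine carries the
#: full mask, so it never mismatches.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK = {sym: sum(_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _m in IUPAC_MASK.items():
    _MASK_LUT[ord(_sym)] = _m


def _encode(seq: str) -> np.ndarray:
    return _MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class BindingSiteMatch:
    """A primer annealed to a template. Coordinates are 1-based inclusive on
    the plus strand of the template; for strand '−' the primer's reverse
    complement occupies [start, end] and the primer extends towards lower
    coordinates. ``mismatch_mask`` runs 5'->3' of the primer."""

    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatch_count: int
    mismatch_mask: tuple[bool, ...]


@dataclass(frozen=True)
class Amplicon:
    """The product of one forward/reverse site pair. ``insert`` coordinates
    are the region strictly between the two primer footprints."""

    template_id: str
    insert_start: int
    insert_end: int
    forward_site: BindingSiteMatch
    reverse_site: BindingSiteMatch

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start + 1

    @property
    def with_primers_length(self) -> int:
        return self.insert_length + (self.forward_site.end - self.forward_site.start + 1) \
            + (self.reverse_site.end - self.reverse_site.start + 1)


def _mismatch_at(primer_sym: str, template_sym: str, strict_n: bool) -> bool:
    if primer_sym == "I":
        return False
    if strict_n and template_sym == "N":
        return True
    return IUPAC_SETS[primer_sym].isdisjoint(IUPAC_SETS[template_sym])


def count_mismatches(primer: DegeneratePrimer | str, site: str,
                     strict_template_n: bool = False) -> tuple[int, tuple[bool, ...]]:
    """Mismatch count and per-position mask (5'->3' of the primer) between a
    degenerate primer and an equal-length template site."""
    pseq = primer.sequence if isinstance(primer, DegeneratePrimer) else normalize(primer)
    site = normalize(site)
    if len(pseq) != len(site):
        raise ValueError(f"primer length {len(pseq)} != site length {len(site)}")
    mask = tuple(_mismatch_at(p, t, strict_template_n) for p, t in zip(pseq, site))
    return sum(mask), mask


def find_binding_sites(primer: DegeneratePrimer | str, template: str,
                       max_mismatches: int = 0, template_id: str = "template",
                       strict_template_n: bool = False) -> list[BindingSiteMatch]:
    """All annealing sites of the primer on either strand of the template with
    at most ``max_mismatches`` mismatches, sorted by (mismatch_count, start).

    A '+' site means the primer sequence itself aligns left-to-right at
    [start, end]; a '−' site means the primer anneals to the bottom strand
    (its reverse complement appears at [start, end] on the top strand).
    """
    pseq = primer.sequence if isinstance(primer, DegeneratePrimer) else normalize(primer)
    template = normalize(template)
    L, n = len(pseq), len(template)
    if n < L:
        return []
    rc = reverse_complement(pseq)
    windows = np.lib.stride_tricks.sliding_window_view(_encode(template), L)
    out: list[BindingSiteMatch] = []
    for strand, patt in (("+", pseq), ("-", rc)):
        pmask = _encode(patt)
        mm = (windows & pmask) == 0
        if strict_template_n:
            mm |= np.lib.stride_tricks.sliding_window_view(
                np.frombuffer(template.encode(), dtype=np.uint8), L) == ord("N")
        counts = mm.sum(axis=1)
        for i in np.nonzero(counts <= max_mismatches)[0]:
            mask = tuple(bool(x) for x in mm[i])
            if strand == "-":  # report mask 5'->3' of the primer itself
                mask = mask[::-1]
            out.append(BindingSiteMatch(template_id, strand, int(i) + 1,
                                        int(i) + L, int(counts[i]), mask))
    out.sort(key=lambda s: (s.mismatch_count, s.start, s.strand))
    return out


def amplify(forward: DegeneratePrimer, reverse: DegeneratePrimer, template: str,
            max_mismatches: int = 0, template_id: str = "template") -> list[Amplicon]:
    """Every properly oriented forward('+') / reverse('−') site pair with the
    forward footprint upstream of the reverse footprint yields one amplicon;
    the insert excludes both primer footprints."""
    fsites = [s for s in find_binding_sites(forward, template, max_mismatches, template_id)
              if s.strand == "+"]
    rsites = [s for s in find_binding_sites(reverse, template, max_mismatches, template_id)
              if s.strand == "-"]
    out = []
    for f in fsites:
        for r in rsites:
            if f.end < r.start:
                out.append(Amplicon(template_id, f.end + 1, r.start - 1, f, r))
    out.sort(key=lambda a: (a.insert_start, a.insert_end))
    return out


@dataclass
class MismatchDistribution:
    """Per-group histogram of best-site mismatch counts for one primer."""

    primer_name: str
    histograms: dict[str, Counter] = field(default_factory=dict)
    unalignable: dict[str, int] = field(default_factory=dict)

    def fraction_below(self, group: str, k: int) -> float:
        h = self.histograms.get(group, Counter())
        total = sum(h.values()) + self.unalignable.get(group, 0)
        if total == 0:
            return float("nan")
        return sum(c for m, c in h.items() if m < k) / total

    def max_mismatches(self, group: str | None = None) -> int:
        hists = self.histograms.values() if group is None else [self.histograms.get(group, Counter())]
        values = [m for h in hists for m in h]
        return max(values) if values else 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, h in sorted(self.histograms.items()):
            for m, c in sorted(h.items()):
                rows.append({"group": group, "mismatches": m, "count": c})
            if self.unalignable.get(group):
                rows.append({"group": group, "mismatches": -1,
                             "count": self.unalignable[group]})
        return pd.DataFrame(rows, columns=["group", "mismatches", "count"])


def mismatch_distribution(primer: DegeneratePrimer,
                          references: list[tuple[str, str, str]],
                          site: tuple[int, int] | None = None,
                          ceiling: int = 10) -> MismatchDistribution:
    """Distribution of primer-template mismatches across a grouped reference
    library (one row per template: (id, group, sequence)).

    With ``site`` = (start, end) 1-based, mismatches are counted at those
    fixed template coordinates; otherwise the minimum-mismatch site found by
    search on both strands is used (ties: leftmost). Templates with no site at
    <= ``ceiling`` mismatches land in an 'unalignable' bin, never dropped.
    """
    dist = MismatchDistribution(primer_name=primer.name)
    for _, group, seq in references:
        dist.histograms.setdefault(group, Counter())
        dist.unalignable.setdefault(group, 0)
        seq = normalize(seq)
        if site is not None:
            s, e = site
            window = seq[s - 1:e]
            if len(window) != len(primer.sequence):
                dist.unalignable[group] += 1
                continue
            m, _ = count_mismatches(primer, window)
            best = m
        else:
            hits = find_binding_sites(primer, seq, max_mismatches=ceiling)
            if not hits:
                dist.unalignable[group] += 1
                continue
            best = hits[0].mismatch_count
        if best > ceiling:
            dist.unalignable[group] += 1
        else:
            dist.histograms[group][best] += 1
    return dist
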
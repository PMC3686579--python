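"""Alignment entropy profiling, conserved-window discovery, degenerate
consensus primers and predator-blocking primer design.

The workflow mirrors how a conserved internal priming site is located inside a
hypervariable barcode: compute per-column Shannon entropy h(x) over a large
multiple alignment, find low-entropy windows of primer length, and read a
degenerate consensus off the window's base frequencies. Entropy is reported in
bits (log2), so 0 <= h(x) <= 2 for a 4-letter alphabet: h = 0 at a perfectly
conserved column, 2 when all four bases are equally frequent.

Gap handling: gaps are excluded from the frequencies entering h(x) but tracked
as per-column coverage; windows containing columns below a coverage floor are
disqualified. Ambiguity codes contribute fractionally (1/|base set|) to each
base they denote; a strict mode drops ambiguous residues instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import (DegeneratePrimer, IUPAC_SETS, SET_TO_IUPAC,
                    InvalidSequenceError, normalize)
from .pcr import BindingSiteMatch, count_mismatches, find_binding_sites

BASES = "ACGT"
GAP_CHARS = "-."


@dataclass
class AlignmentProfile:
    """Per-column base counts, coverage and entropy of a fixed-width MSA.

    ``counts`` is (n_columns, 4) over A,C,G,T (fractional when ambiguity codes
    are distributed); ``gaps`` counts gap characters; ``coverage`` is the
    non-gap fraction; ``entropy`` is h(x) in bits with NaN at all-gap columns
    (undefined, never reported as 0).
    """

    counts: np.ndarray
    gaps: np.ndarray
    n_rows: int

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return 1.0 - self.gaps / self.n_rows

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)

    @property
    def entropy(self) -> np.ndarray:
        return np.array([
            column_entropy(dict(zip(BASES, row))) if row.sum() > 0 else np.nan
            for row in self.counts
        ])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "column", np.arange(1, self.n_columns + 1))
        df["gap"] = self.gaps
        df["coverage"] = self.coverage
        df["entropy"] = self.entropy
        return df


def column_entropy(base_counts: dict[str, float]) -> float:
    """Shannon entropy h(x) in bits of one column's base counts.

    Gaps must already be excluded. All-gap (empty) columns are undefined and
    raise rather than returning 0, since h=0 asserts perfect conservation.
    """
    counts = np.array([float(base_counts.get(b, 0.0)) for b in BASES])
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy undefined for a column with no counted bases")
    f = counts[counts > 0] / total
    return float(-(f * np.log2(f)).sum()) + 0.0


def profile_alignment(rows, ambiguous: str = "fractional") -> AlignmentProfile:
    """Profile an aligned FASTA (iterable of (id, seq) or plain sequences).

    All rows must have equal length; ragged input is rejected listing the
    offending rows. ``ambiguous`` is 'fractional' (default: a residue with
    base set S adds 1/|S| to each base in S) or 'drop' (ambiguous residues are
    counted as gaps).
    """
    pairs = [(r if isinstance(r, tuple) else (f"row{i+1}", r))
             for i, r in enumerate(rows)]
    if not pairs:
        raise ValueError("empty alignment")
    seqs = [s.upper().replace(".", "-") for _, s in pairs]
    width = len(seqs[0])
    ragged = [pairs[i][0] for i, s in enumerate(seqs) if len(s) != width]
    if ragged:
        raise ValueError(f"ragged alignment; offending rows: {ragged}")
    counts = np.zeros((width, 4), dtype=float)
    gaps = np.zeros(width, dtype=float)
    weight = {}
    for sym, bases in IUPAC_SETS.items():
        vec = np.zeros(4)
        if ambiguous == "fractional" or len(bases) == 1:
            for b in bases:
                vec[BASES.index(b)] = 1.0 / len(bases)
        weight[sym] = vec
    for name, s in zip((n for n, _ in pairs), seqs):
        for j, ch in enumerate(s):
            if ch in GAP_CHARS:
                gaps[j] += 1
            elif ch == "U":
                counts[j, BASES.index("T")] += 1
            elif ch in weight:
                w = weight[ch]
                if w.sum() == 0:  # 'drop' mode, ambiguous residue
                    gaps[j] += 1
                else:
                    counts[j] += w
            else:
                raise InvalidSequenceError(
                    f"invalid character {ch!r} at column {j + 1} of row {name!r}")
    return AlignmentProfile(counts=counts, gaps=gaps, n_rows=len(pairs))


@dataclass
class ConservedWindow:
    """A candidate priming window; coordinates are 1-based inclusive."""

    start: int
    end: int
    mean_entropy: float
    max_entropy: float
    frequencies: np.ndarray  # (width, 4) over ACGT

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def find_conserved_windows(profile: AlignmentProfile, width: int,
                           max_mean_entropy: float = 0.5,
                           min_coverage: float = 0.5) -> list[ConservedWindow]:
    """All width-column windows with mean h(x) <= max_mean_entropy and every
    column's coverage >= min_coverage, ranked by mean entropy ascending (ties:
    lower max entropy, then smaller start). Returns [] when nothing qualifies.
    """
    if width < 1 or width > profile.n_columns:
        raise ValueError(
            f"window width {width} outside 1..{profile.n_columns}")
    ent = profile.entropy
    cov = profile.coverage
    freqs = profile.frequencies
    out = []
    for s in range(profile.n_columns - width + 1):
        e = ent[s:s + width]
        if np.isnan(e).any():
            continue
        if (cov[s:s + width] < min_coverage).any():
            continue
        mean_e = float(e.mean())
        if mean_e <= max_mean_entropy:
            out.append(ConservedWindow(
                start=s + 1, end=s + width, mean_entropy=mean_e,
                max_entropy=float(e.max()), frequencies=freqs[s:s + width]))
    out.sort(key=lambda w: (w.mean_entropy, w.max_entropy, w.start))
    return out


def degenerate_consensus(window: ConservedWindow, min_base_freq: float = 0.05,
                         name: str = "consensus") -> DegeneratePrimer:
    """IUPAC consensus of a window: per column, the symbol covering exactly
    the bases with frequency >= min_base_freq (the modal base is always
    included), returned 5'->3' as a forward primer."""
    symbols = []
    for row in window.frequencies:
        if np.isnan(row).any():
            raise ValueError("consensus requires full base coverage in the window")
        keep = {BASES[i] for i in range(4) if row[i] > 0 and row[i] >= min_base_freq}
        keep.add(BASES[int(np.argmax(row))])
        symbols.append(SET_TO_IUPAC[frozenset(keep)])
    return DegeneratePrimer(name=name, sequence="".join(symbols),
                            orientation="forward")


@dataclass
class BlockingPrimer:
    """A 3'-blocked oligo overlapping a universal priming site and extending
    into host-specific sequence, used to suppress predator amplification.

    Spans are 1-based inclusive template coordinates.
    """

    sequence: str
    overlap_span: tuple[int, int]
    extension_span: tuple[int, int]
    three_prime_block: bool = True
    prey_mismatches: dict[str, int] = field(default_factory=dict)

    def as_primer(self, name: str = "blocker") -> DegeneratePrimer:
        return DegeneratePrimer(name, self.sequence, "forward",
                                three_prime_block=True)


class BlockingDesignError(ValueError):
    pass


def design_blocking_primer(predator_ref: str, universal_site: BindingSiteMatch,
                           overlap_len: int, total_len: int,
                           prey_refs: dict[str, str],
                           min_prey_mismatches: int = 4) -> BlockingPrimer:
    """Design a predator-blocking primer off a located universal priming site.

    The candidate overlaps the universal primer's 3' end by ``overlap_len``
    bases and extends ``total_len - overlap_len`` bases into predator-specific
    template, in the universal primer's extension direction. It is rejected
    when any prey reference shows fewer than ``min_prey_mismatches`` mismatches
    against the predator-specific extension (the blocker would block prey too).
    """
    predator_ref = normalize(predator_ref)
    if not (1 <= overlap_len < total_len):
        raise ValueError("need 1 <= overlap_len < total_len")
    ext_len = total_len - overlap_len
    s0, e0 = universal_site.start - 1, universal_site.end  # 0-based half-open
    if universal_site.strand == "+":
        if e0 + ext_len > len(predator_ref):
            raise BlockingDesignError("template too short for the extension")
        seq = predator_ref[e0 - overlap_len:e0 + ext_len]
        overlap_span = (e0 - overlap_len + 1, e0)
        extension_span = (e0 + 1, e0 + ext_len)
        extension = predator_ref[e0:e0 + ext_len]
    else:
        if s0 - ext_len < 0:
            raise BlockingDesignError("template too short for the extension")
        from .iupac import reverse_complement
        seq = reverse_complement(predator_ref[s0 - ext_len:s0 + overlap_len])
        overlap_span = (s0 + 1, s0 + overlap_len)
        extension_span = (s0 - ext_len + 1, s0)
        extension = reverse_complement(predator_ref[s0 - ext_len:s0])
    prey_mm: dict[str, int] = {}
    for prey_id, prey_seq in prey_refs.items():
        sites = find_binding_sites(
            DegeneratePrimer("ext", extension), normalize(prey_seq),
            max_mismatches=len(extension))
        prey_mm[prey_id] = min(s.mismatch_count for s in sites) if sites else len(extension)
    bad = {k: v for k, v in prey_mm.items() if v < min_prey_mismatches}
    if bad:
        closest = min(bad, key=bad.get)
        raise BlockingDesignError(
            f"no qualifying blocker: prey {closest!r} has only {bad[closest]} "
            f"mismatches in the extension (need >= {min_prey_mismatches})")
    return BlockingPrimer(sequence=seq, overlap_span=overlap_span,
                          extension_span=extension_span,
                          prey_mismatches=prey_mm)
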
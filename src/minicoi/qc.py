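"""Amplicon read processing: hierarchical demultiplexing, primer and length
filters, codon-aware functional filtering with single-frameshift repair, and a
two-parent chimera screen.

The functional filter exploits the protein-coding structure of the marker:
each read is aligned (end-free, affine gaps) to its closest in-frame
reference, the reading frame is inherited through the alignment, and gap runs
are classified — runs of length 0 mod 3 are whole-codon insertions/deletions,
anything else is a frameshift. Stop codons are counted on the frame-corrected
translation (frameshift-affected codons excised), so a genuine stop mutation
is never masked by a downstream indel and vice versa.

Keep rules: a read passes with no stops, no frameshifts, no codon insertions
and fewer than four codon deletions. A read with exactly one frameshift and no
other anomaly is kept after repair: the codon containing the frameshifted
position cannot be reconstructed, so it is removed entirely, leaving an
in-frame, stop-free sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .align import (alignment_gap_runs, edit_distance, endfree_affine_align,
                    match_profile, pairwise_identity)
from .iupac import (DegeneratePrimer, GeneticCode, INVERTEBRATE_MITO,
                    reverse_complement, translate)
from .pcr import count_mismatches, find_binding_sites

VERDICTS = ("pass", "repaired", "discard_stop", "discard_frameshift",
            "discard_insertion", "discard_deletion", "discard_primer",
            "discard_length", "discard_chimera", "unassigned")


@dataclass(frozen=True)
class SampleTagScheme:
    """One sample's address in the hierarchical tagging scheme: a pool-level
    MID plus a short (default 6 bp) tag carried on both primer 5' ends."""

    sample_id: str
    mid: str
    tag: str


@dataclass
class ReadQCRecord:
    """Per-read QC ledger accumulated across the pipeline stages."""

    read_id: str
    sample_id: str | None = None
    fwd_primer_mismatches: int | None = None
    rev_primer_mismatches: int | None = None
    length_ok: bool = True
    n_stop_codons: int = 0
    n_frameshifts: int = 0
    n_inserted_codons: int = 0
    n_deleted_codons: int = 0
    best_reference: str | None = None
    best_identity: float | None = None
    verdict: str = "pass"
    output_sequence: str = ""
    repaired_sequence: str | None = None


class SchemeError(ValueError):
    pass


def _check_scheme(scheme: list[SampleTagScheme]) -> None:
    ids = [s.sample_id for s in scheme]
    if len(set(ids)) != len(ids):
        raise SchemeError("duplicate sample_ids in tagging scheme")
    keys = [(s.mid, s.tag) for s in scheme]
    if len(set(keys)) != len(keys):
        raise SchemeError("duplicate (MID, tag) pairs in tagging scheme")


def demultiplex(reads, scheme: list[SampleTagScheme],
                forward_primer: DegeneratePrimer,
                reverse_primer: DegeneratePrimer,
                max_primer_mismatches: int = 2,
                min_length: int = 150):
    """Assign reads to samples by exact (MID, tag) prefix, locate and trim the
    flanking primers, and apply the primer-mismatch and length filters.

    Returns ``(bins, records)`` where bins maps sample_id -> list of
    (read_id, trimmed insert) for reads surviving this stage, and records
    holds one :class:`ReadQCRecord` per input read (a partition: every read
    lands in exactly one sample or discard/unassigned bin).

    Reads with more than ``max_primer_mismatches`` mismatches in the forward
    primer are discarded (default ceiling 2); reads whose trimmed insert is
    shorter than ``min_length`` are discarded as too short (the base-space
    recast of a minimum-flow filter).
    """
    _check_scheme(scheme)
    bins: dict[str, list[tuple[str, str]]] = {s.sample_id: [] for s in scheme}
    records: list[ReadQCRecord] = []
    by_prefix = {(s.mid + s.tag): s for s in scheme}
    prefix_lens = sorted({len(s.mid) + len(s.tag) for s in scheme})
    fwd_len = len(forward_primer.sequence)
    for read_id, seq in reads:
        seq = seq.upper()
        rec = ReadQCRecord(read_id=read_id)
        hit = None
        for plen in prefix_lens:
            hit = by_prefix.get(seq[:plen])
            if hit is not None:
                break
        if hit is None:
            rec.verdict = "unassigned"
            records.append(rec)
            continue
        rec.sample_id = hit.sample_id
        plen = len(hit.mid) + len(hit.tag)
        primer_region = seq[plen:plen + fwd_len]
        if len(primer_region) < fwd_len:
            rec.length_ok = False
            rec.verdict = "discard_length"
            records.append(rec)
            continue
        mm, _ = count_mismatches(forward_primer, primer_region)
        rec.fwd_primer_mismatches = mm
        if mm > max_primer_mismatches:
            rec.verdict = "discard_primer"
            records.append(rec)
            continue
        remainder = seq[plen + fwd_len:]
        rsites = [s for s in find_binding_sites(reverse_primer, remainder,
                                                max_mismatches=max_primer_mismatches)
                  if s.strand == "-"]
        if rsites:
            best = min(rsites, key=lambda s: (s.mismatch_count, -s.start))
            rec.rev_primer_mismatches = best.mismatch_count
            insert = remainder[:best.start - 1]
        else:
            insert = remainder
        if len(insert) < min_length:
            rec.length_ok = False
            rec.verdict = "discard_length"
            records.append(rec)
            continue
        rec.output_sequence = insert
        bins[hit.sample_id].append((read_id, insert))
        records.append(rec)
    return bins, records


# ---------------------------------------------------------------------------
# Frame classification


def _affected_codon(ref_pos: int) -> int:
    # codon-boundary tie rule: the codon on the 3' side of the gap is removed
    return ref_pos // 3


def frame_classify(read: str, references: list[tuple[str, str]],
                   code: GeneticCode = INVERTEBRATE_MITO,
                   min_identity: float = 0.5,
                   record: ReadQCRecord | None = None) -> ReadQCRecord:
    """Classify reading-frame anomalies of one trimmed read against an
    in-frame, stop-free reference panel.

    The closest reference (edit distance, ties to panel order) provides the
    reading frame; references must be declared in frame 0. Gap runs of the
    end-free affine alignment are classified into whole-codon insertions /
    deletions (length 0 mod 3) and frameshifts (anything else). Stops are
    counted on the frame-corrected read with frameshift-affected codons
    removed; that corrected sequence is also the repair candidate.

    Reads closer than ``min_identity`` to nothing in the panel are returned
    with verdict 'unassigned'.
    """
    rec = record if record is not None else ReadQCRecord(read_id="read")
    read = read.upper()
    if not references:
        raise ValueError("empty reference panel")
    dists = [edit_distance(read, seq) for _, seq in references]
    best_i = int(np.argmin(dists))
    ref_id, ref_seq = references[best_i]
    identity = pairwise_identity(read, ref_seq)
    rec.best_reference = ref_id
    rec.best_identity = identity
    if identity < min_identity:
        rec.verdict = "unassigned"
        return rec
    aln = endfree_affine_align(read, ref_seq)
    insertions, deletions, _, _ = alignment_gap_runs(aln)

    n_ins = sum(r // 3 for r, _, _ in insertions if r % 3 == 0)
    n_del = sum(r // 3 for r, _, _ in deletions if r % 3 == 0)
    fs_runs = [(r, p, q, "ins") for r, p, q in insertions if r % 3 != 0] + \
              [(r, p, q, "del") for r, p, q in deletions if r % 3 != 0]
    rec.n_inserted_codons = n_ins
    rec.n_deleted_codons = n_del
    rec.n_frameshifts = len(fs_runs)

    affected = {_affected_codon(p) for _, p, _, _ in fs_runs}
    fs_insert_read_pos: set[int] = set()
    for r, _, q, kind in fs_runs:
        if kind == "ins":
            fs_insert_read_pos.update(range(q, q + r))

    # Assemble codon groups in alignment order: aligned read bases keyed by
    # their reference codon; inserted runs keyed as pseudo-codons at their
    # insertion point (codon-multiple insertions only).
    # Codon ids: integers for reference codons, half-integers for inserted
    # pseudo-codons placed just before the reference codon they precede.
    tblocks, qblocks = aln.aligned
    units: list[tuple[tuple[float, int], str]] = []  # ((codon_id, within), base)
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for j in range(te - ts):
            if qs + j in fs_insert_read_pos:
                continue
            units.append(((float((ts + j) // 3), (ts + j) % 3), read[qs + j]))
    for r, p, q in insertions:
        if r % 3 == 0:
            for k in range(r):
                units.append(((p / 3 - 0.5, k), read[q + k]))
    units.sort(key=lambda u: u[0])

    groups: dict[float, list[str]] = defaultdict(list)
    order: list[float] = []
    for (gid, _), base in units:
        if gid not in groups:
            order.append(gid)
        groups[gid].append(base)

    corrected_parts: list[str] = []
    for gid in order:
        bases = groups[gid]
        if not float(gid).is_integer():
            # inserted pseudo-codon run (length is a multiple of 3)
            corrected_parts.append("".join(bases))
            continue
        if int(gid) in affected:
            continue
        if len(bases) != 3:
            continue  # partial terminal codon (end-free overhang)
        corrected_parts.append("".join(bases))
    corrected = "".join(corrected_parts)
    _, stops = translate(corrected, code, frame=0)
    rec.n_stop_codons = len(stops)
    rec.repaired_sequence = corrected
    if not rec.output_sequence:
        rec.output_sequence = read
    return rec


def apply_keep_rules(record: ReadQCRecord) -> ReadQCRecord:
    """Apply the keep/repair rules to a populated record.

    pass: no stops, no frameshifts, no codon insertions, fewer than four codon
    deletions. repaired: exactly one frameshift and nothing else wrong — the
    affected codon has been excised and the in-frame repaired sequence becomes
    the output. Otherwise the verdict names the first violated rule in the
    fixed precedence stop > frameshift > insertion > deletion.
    """
    if record.verdict in ("unassigned", "discard_primer", "discard_length"):
        return record
    r = record
    if r.n_stop_codons > 0:
        r.verdict = "discard_stop"
    elif r.n_frameshifts == 1 and r.n_inserted_codons == 0 and r.n_deleted_codons == 0:
        r.verdict = "repaired"
        r.output_sequence = r.repaired_sequence or ""
    elif r.n_frameshifts > 0:
        r.verdict = "discard_frameshift"
    elif r.n_inserted_codons > 0:
        r.verdict = "discard_insertion"
    elif r.n_deleted_codons >= 4:
        r.verdict = "discard_deletion"
    else:
        r.verdict = "pass"
    return r


# ---------------------------------------------------------------------------
# Chimera screen


@dataclass(frozen=True)
class ChimeraCall:
    """Outcome of the two-parent chimera test for one read.

    ``score`` is the identity gain of the best one-breakpoint two-parent
    model over the best single parent; by construction it is >= 0 (the search
    includes the degenerate pair A = B).
    """

    read_id: str
    is_chimera: bool
    best_single_parent_identity: float
    best_two_parent_identity: float
    breakpoint: int | None
    parents: tuple[str, str] | None
    score: float
    evaluable: bool = True


def detect_chimera(read: str, references: list[tuple[str, str]],
                   min_score_gain: float = 0.05, min_segment: int = 30,
                   read_id: str = "read") -> ChimeraCall:
    """Screen one read against a reference panel for a two-parent chimera.

    The best single-parent identity is compared with the best identity
    achievable by joining a left segment from one parent and a right segment
    from another at a single breakpoint, each segment at least ``min_segment``
    read bases. The read is flagged when the gain reaches
    ``min_score_gain``. Reads shorter than two minimum segments are not
    evaluable and are never flagged.
    """
    if len(references) < 2:
        raise ValueError("chimera detection needs at least two references")
    L = len(read)
    if L < 2 * min_segment:
        return ChimeraCall(read_id, False, float("nan"), float("nan"),
                           None, None, 0.0, evaluable=False)
    profiles = np.stack([match_profile(read, seq) for _, seq in references])
    totals = profiles.sum(axis=1)
    best_single_i = int(np.argmax(totals))
    best_single = totals[best_single_i] / L
    prefix = np.cumsum(profiles, axis=1)  # prefix[:, b-1] = matches in read[:b]
    best_two = best_single
    best_bp = None
    best_pair = (best_single_i, best_single_i)
    for b in range(min_segment, L - min_segment + 1):
        left = prefix[:, b - 1]
        right = totals - prefix[:, b - 1]
        a = int(np.argmax(left))
        c = int(np.argmax(right))
        score = (left[a] + right[c]) / L
        if score > best_two + 1e-12:
            best_two = score
            best_bp = b
            best_pair = (a, c)
    score = best_two - best_single
    is_chimera = (score >= min_score_gain
                  and best_pair[0] != best_pair[1]
                  and best_bp is not None)
    parents = (references[best_pair[0]][0], references[best_pair[1]][0]) \
        if best_bp is not None else None
    return ChimeraCall(read_id, bool(is_chimera), float(best_single),
                       float(best_two), best_bp, parents, float(score))


# ---------------------------------------------------------------------------
# Full front-end pipeline


def run_qc_pipeline(reads, scheme: list[SampleTagScheme],
                    forward_primer: DegeneratePrimer,
                    reverse_primer: DegeneratePrimer,
                    references: list[tuple[str, str]],
                    code: GeneticCode = INVERTEBRATE_MITO,
                    max_primer_mismatches: int = 2, min_length: int = 150,
                    chimera_min_score_gain: float = 0.05,
                    chimera_min_segment: int = 30,
                    screen_chimeras: bool = True):
    """demultiplex -> frame classify -> keep rules -> chimera screen.

    Returns ``(records, bins, summary)``: one record per input read, the
    per-sample surviving (pass/repaired) inserts, and a verdict accounting
    summary (input, per-verdict counts, final).
    """
    bins, records = demultiplex(reads, scheme, forward_primer, reverse_primer,
                                max_primer_mismatches, min_length)
    rec_by_id = {r.read_id: r for r in records}
    out_bins: dict[str, list[tuple[str, str]]] = {s.sample_id: [] for s in scheme}
    for sample_id, items in bins.items():
        for read_id, insert in items:
            rec = rec_by_id[read_id]
            frame_classify(insert, references, code, record=rec)
            apply_keep_rules(rec)
            if rec.verdict not in ("pass", "repaired"):
                continue
            if screen_chimeras:
                call = detect_chimera(insert, references,
                                      min_score_gain=chimera_min_score_gain,
                                      min_segment=chimera_min_segment,
                                      read_id=read_id)
                if call.is_chimera:
                    rec.verdict = "discard_chimera"
                    continue
            out_bins[sample_id].append((read_id, rec.output_sequence))
    counts = Counter(r.verdict for r in records)
    summary = {
        "input": len(records),
        "verdicts": {v: counts.get(v, 0) for v in VERDICTS},
        "repaired": counts.get("repaired", 0),
        "final": counts.get("pass", 0) + counts.get("repaired", 0),
    }
    return records, out_bins, summary
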
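"""Barcode demultiplexing and trimming to the repetitive-domain region.

Reads are assigned to samples by their leading 10 bases (Hamming
distance <= 1 to exactly one barcode; ties stay unassigned).  Trimming
anchors on the degenerate forward primer at the start of the
signal-peptide coding region and on the reverse-primer region, and cuts
out the in-frame coding sequence of the mature repetitive domain.
Rejected reads are kept as QC records, never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import BarcodedRead, Read
from .simulate import FORWARD_PRIMER, REVERSE_ANCHOR, SIGNAL_FLANK_NT

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "W": "AT", "S": "CG",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_degenerate(
    sequence: str, pattern: str, max_mismatch: int = 0, start: int = 0
) -> Optional[int]:
    """Leftmost position where *pattern* (IUPAC codes) matches, or None.

    A position mismatches when the base is not in the IUPAC class;
    up to *max_mismatch* such positions are tolerated per window.
    """
    pattern = pattern.upper()
    classes = []
    for p in pattern:
        if p not in IUPAC:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern")
        classes.append(IUPAC[p])
    seq = sequence.upper()
    for i in range(start, len(seq) - len(pattern) + 1):
        mm = 0
        for j, cls in enumerate(classes):
            if seq[i + j] not in cls:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return None


def demultiplex(
    reads: Iterable[Read],
    barcode_map: dict[str, str],
    max_mismatch: int = 1,
) -> tuple[dict[str, list[BarcodedRead]], list[BarcodedRead]]:
    """Partition reads by sample barcode; ambiguous/unmatched stay unassigned.

    A read is assigned iff exactly one barcode is within *max_mismatch*
    of its leading bases.
    """
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    (bc_len,) = lengths
    dupes = [b for b, k in Counter(barcode_map.values()).items() if k > 1]
    if dupes:
        raise ValueError(f"barcode assigned to multiple samples: {dupes}")

    assigned: dict[str, list[BarcodedRead]] = {s: [] for s in barcode_map}
    unassigned: list[BarcodedRead] = []
    for read in reads:
        lead = read.sequence[:bc_len]
        hits = [
            sample
            for sample, bc in barcode_map.items()
            if len(lead) == bc_len and hamming(lead, bc) <= max_mismatch
        ]
        if len(hits) == 1:
            assigned[hits[0]].append(
                BarcodedRead(read.read_id, read.sequence, read.quality, hits[0])
            )
        else:
            unassigned.append(
                BarcodedRead(read.read_id, read.sequence, read.quality, "unassigned")
            )
    return assigned, unassigned


@dataclass
class TrimSpec:
    """Anchors and bounds for domain trimming.

    Both domain boundaries are located by sequence content: the domain
    starts right after the ``start_anchor`` (the end of the
    signal-peptide coding region, so indels further upstream cannot
    shift the cut) and ends at the ``reverse_anchor`` match.  Length
    bounds are QC flags, not filters.
    """

    forward_primer: str = FORWARD_PRIMER
    start_anchor: str = SIGNAL_FLANK_NT[-15:]
    reverse_anchor: str = REVERSE_ANCHOR
    max_primer_mismatch: int = 1
    length_bounds: tuple[int, int] = (240, 281)


@dataclass
class TrimmedFragment:
    read_id: str
    sample_id: str
    nt_domain: str
    length_ok: bool


@dataclass
class RejectedRead:
    read_id: str
    sample_id: str
    reason: str


def trim_to_domain(
    read: BarcodedRead, spec: Optional[TrimSpec] = None
) -> TrimmedFragment | RejectedRead:
    """Cut a demultiplexed read down to the in-frame repetitive domain."""
    if spec is None:
        spec = TrimSpec()
    sample = read.assigned_sample
    fwd = match_degenerate(
        read.sequence, spec.forward_primer, max_mismatch=spec.max_primer_mismatch
    )
    if fwd is None:
        return RejectedRead(read.read_id, sample, "fwd_primer_not_found")
    anchor = match_degenerate(
        read.sequence,
        spec.start_anchor,
        max_mismatch=spec.max_primer_mismatch,
        start=fwd + len(spec.forward_primer),
    )
    if anchor is None:
        return RejectedRead(read.read_id, sample, "start_anchor_not_found")
    start = anchor + len(spec.start_anchor)
    rev = match_degenerate(
        read.sequence, spec.reverse_anchor, max_mismatch=spec.max_primer_mismatch, start=start
    )
    if rev is None:
        return RejectedRead(read.read_id, sample, "rev_anchor_not_found")
    if rev <= start:
        return RejectedRead(read.read_id, sample, "empty_domain")
    domain = read.sequence[start:rev]
    lo, hi = spec.length_bounds
    return TrimmedFragment(read.read_id, sample, domain, lo <= len(domain) <= hi)


def trim_all(
    demuxed: dict[str, Sequence[BarcodedRead]], spec: Optional[TrimSpec] = None
) -> tuple[dict[str, list[TrimmedFragment]], pd.DataFrame]:
    """Trim every assigned read; returns fragments per sample + a QC table."""
    fragments: dict[str, list[TrimmedFragment]] = {}
    qc_rows = []
    for sample, reads in demuxed.items():
        kept: list[TrimmedFragment] = []
        reasons: Counter = Counter()
        for read in reads:
            result = trim_to_domain(read, spec)
            if isinstance(result, TrimmedFragment):
                kept.append(result)
            else:
                reasons[result.reason] += 1
        fragments[sample] = kept
        qc_rows.append(
            {
                "sample_id": sample,
                "assigned": len(reads),
                "trimmed": len(kept),
                "length_ok": sum(f.length_ok for f in kept),
                **{f"rejected_{r}": n for r, n in sorted(reasons.items())},
            }
        )
    qc = pd.DataFrame(qc_rows).set_index("sample_id").fillna(0).astype(int)
    return fragments, qc
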
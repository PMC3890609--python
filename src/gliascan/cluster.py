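"""Dereplication, homopolymer denoising and greedy identity clustering.

The stages mirror the amplicon workflow for 454 reads of the
alpha-gliadin repetitive domain:

1. exact dereplication with per-sample read counts, sorted by
   decreasing abundance (the most abundant sequence is most likely
   error-free);
2. homopolymer correction — a rare unique sequence is merged into a
   dominant one when they differ only by one or two single-base indels
   inside homopolymer runs of the dominant sequence;
3. an abundance gate per sequencing run, suppressing rare artefacts;
4. greedy abundance-sorted clustering at 99.5% identity against cluster
   representatives;
5. abundance-weighted majority consensus and a final cluster-size filter.

Pairwise identity uses the Levenshtein edit distance (every gap and
every mismatch is one difference) normalised by the longer sequence:
``identity = 1 - d / max(len(a), len(b))``.  Edit distances come from
edlib; alignments of near-identical amplicons are unambiguous at the
0.995 decision boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class Dereplicate:
    """A unique nucleotide sequence with per-sample read counts."""

    unique_nt: str
    per_sample_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass
class SequenceCluster:
    """A 99.5%-identity cluster of unique sequences."""

    cluster_id: str
    members: list[Dereplicate]
    consensus_nt: str = ""

    @property
    def representative_nt(self) -> str:
        return self.members[0].unique_nt

    @property
    def per_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            for s, n in m.per_sample_counts.items():
                counts[s] = counts.get(s, 0) + n
        return counts

    @property
    def total_reads(self) -> int:
        return sum(m.total for m in self.members)


def _sort_derep(records: list[Dereplicate]) -> list[Dereplicate]:
    return sorted(records, key=lambda r: (-r.total, r.unique_nt))


def dereplicate(fragments: Iterable) -> list[Dereplicate]:
    """Group trimmed fragments by exact sequence identity.

    Accepts objects with ``sample_id``/``nt_domain`` attributes or
    ``(sample_id, nt)`` tuples.  Output is sorted by decreasing total
    count, ties broken lexicographically by sequence.
    """
    counts: dict[str, dict[str, int]] = {}
    n_in = 0
    for frag in fragments:
        if isinstance(frag, tuple):
            sample, nt = frag
        else:
            sample, nt = frag.sample_id, frag.nt_domain
        per = counts.setdefault(nt, {})
        per[sample] = per.get(sample, 0) + 1
        n_in += 1
    if n_in == 0:
        raise ValueError("no fragments to dereplicate")
    return _sort_derep([Dereplicate(nt, per) for nt, per in counts.items()])


def pairwise_identity(a: str, b: str) -> float:
    """Global identity in [0, 1]; every gap and mismatch is a difference."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    longer = max(len(a), len(b))
    return (longer - dist) / longer


def _run_length_at(seq: str, i: int) -> int:
    """Length of the homopolymer run containing position *i*."""
    c = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == c:
        lo -= 1
    hi = i
    while hi + 1 < len(seq) and seq[hi + 1] == c:
        hi += 1
    return hi - lo + 1


def is_homopolymer_variant(dominant: str, rare: str, max_hp_indels: int = 2) -> bool:
    """True iff *rare* differs from *dominant* only by <= *max_hp_indels*
    single-base indels, each inside a homopolymer run (length >= 2) of
    the dominant sequence, with zero substitutions."""
    if dominant == rare:
        return False
    if abs(len(dominant) - len(rare)) > max_hp_indels:
        return False
    aln = edlib.align(rare, dominant, mode="NW", task="path", k=max_hp_indels)
    if aln["editDistance"] < 0:  # distance exceeds k
        return False
    n_indels = 0
    q = t = 0  # q indexes rare (query), t indexes dominant (target)
    for num, op in _CIGAR_RE.findall(aln["cigar"]):
        n = int(num)
        if op == "=":
            q += n
            t += n
        elif op == "X":
            return False
        elif op == "D":  # dominant has extra base(s)
            if n != 1 or _run_length_at(dominant, t) < 2:
                return False
            n_indels += 1
            t += n
        elif op == "I":  # rare has extra base(s)
            if n != 1:
                return False
            c = rare[q]
            beside = (t < len(dominant) and dominant[t] == c and _run_length_at(dominant, t) >= 2) or (
                t > 0 and dominant[t - 1] == c and _run_length_at(dominant, t - 1) >= 2
            )
            if not beside:
                return False
            n_indels += 1
            q += n
    return 0 < n_indels <= max_hp_indels


def _base_composition(seq: str) -> tuple[int, int, int, int]:
    return (seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T"))


def correct_homopolymers(
    derep: Sequence[Dereplicate], min_ratio: float = 5.0, max_hp_indels: int = 2
) -> list[Dereplicate]:
    """Merge homopolymer-artefact uniques into their dominant neighbours.

    Scans rare records in increasing abundance; each is merged into the
    most abundant record that (a) outnumbers it at least *min_ratio*-fold
    in raw (pre-correction) read support and (b) differs only by
    homopolymer indels.  Counts add; the result is re-sorted by abundance.

    Since indel-only variants change each base count by at most one, a
    base-composition distance > *max_hp_indels* rules a pair out before
    any alignment is computed.
    """
    records = [Dereplicate(r.unique_nt, dict(r.per_sample_counts)) for r in _sort_derep(list(derep))]
    raw_totals = [r.total for r in records]
    comps = [_base_composition(r.unique_nt) for r in records]
    merged_away: set[int] = set()
    # records are sorted by decreasing raw total: candidates for a rare
    # record form a prefix of the list, and only strictly smaller records
    # (already processed) can have been merged away
    for ri in range(len(records) - 1, -1, -1):
        rare = records[ri]
        needed = min_ratio * raw_totals[ri]
        for di in range(len(records)):
            if raw_totals[di] < needed:
                break
            if di == ri or di in merged_away:
                continue
            if abs(len(records[di].unique_nt) - len(rare.unique_nt)) > max_hp_indels:
                continue
            comp_dist = sum(abs(a - b) for a, b in zip(comps[di], comps[ri]))
            if comp_dist > max_hp_indels:
                continue
            if is_homopolymer_variant(records[di].unique_nt, rare.unique_nt, max_hp_indels):
                for s, n in rare.per_sample_counts.items():
                    records[di].per_sample_counts[s] = records[di].per_sample_counts.get(s, 0) + n
                merged_away.add(ri)
                break
    return _sort_derep([r for i, r in enumerate(records) if i not in merged_away])


def abundance_gate(
    derep: Sequence[Dereplicate],
    run_of_sample: Optional[dict[str, str]] = None,
    min_run_reads: int = 20,
) -> tuple[list[Dereplicate], list[Dereplicate]]:
    """Keep uniques backed by >= *min_run_reads* reads in some sequencing run.

    With no run annotation the gate applies to the pooled count.
    Returns (passed, dropped), both abundance-sorted.
    """
    passed, dropped = [], []
    for rec in derep:
        if run_of_sample is None:
            run_counts = [rec.total]
        else:
            by_run: dict[str, int] = {}
            for s, n in rec.per_sample_counts.items():
                run = run_of_sample.get(s, "run1")
                by_run[run] = by_run.get(run, 0) + n
            run_counts = list(by_run.values())
        (passed if max(run_counts) >= min_run_reads else dropped).append(rec)
    return _sort_derep(passed), _sort_derep(dropped)


def greedy_cluster(
    derep: Sequence[Dereplicate], identity_threshold: float = 0.995
) -> list[SequenceCluster]:
    """Greedy abundance-sorted clustering against cluster representatives.

    Scanning in decreasing abundance, each record joins the first
    existing cluster whose representative is >= *identity_threshold*
    identical, else founds a new cluster.  Deterministic given the
    input order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    clusters: list[SequenceCluster] = []
    for rec in _sort_derep(list(derep)):
        for cl in clusters:
            if pairwise_identity(rec.unique_nt, cl.representative_nt) >= identity_threshold:
                cl.members.append(rec)
                break
        else:
            clusters.append(SequenceCluster(f"C{len(clusters) + 1:04d}", [rec]))
    for cl in clusters:
        cl.consensus_nt = consensus(cl)
    return clusters


def consensus(cluster: SequenceCluster) -> str:
    """Abundance-weighted per-column majority over the cluster members.

    Members are aligned to the representative; ties (including on
    insertions) resolve toward the representative.
    """
    rep = cluster.representative_nt
    if len(cluster.members) == 1:
        return rep
    total_w = sum(m.total for m in cluster.members)
    col_votes: list[dict[str, int]] = [{} for _ in rep]
    ins_votes: list[dict[str, int]] = [{} for _ in range(len(rep) + 1)]
    for member in cluster.members:
        seq, w = member.unique_nt, member.total
        if seq == rep:
            for t, c in enumerate(rep):
                col_votes[t][c] = col_votes[t].get(c, 0) + w
            continue
        aln = edlib.align(seq, rep, mode="NW", task="path")
        q = t = 0
        for num, op in _CIGAR_RE.findall(aln["cigar"]):
            n = int(num)
            if op in "=X":
                for k in range(n):
                    c = seq[q + k]
                    col_votes[t + k][c] = col_votes[t + k].get(c, 0) + w
                q += n
                t += n
            elif op == "D":  # member lacks these representative bases
                for k in range(n):
                    col_votes[t + k]["-"] = col_votes[t + k].get("-", 0) + w
                t += n
            else:  # I: member has extra bases before rep position t
                ins = seq[q : q + n]
                ins_votes[t][ins] = ins_votes[t].get(ins, 0) + w
                q += n
    out = []
    for t in range(len(rep) + 1):
        if ins_votes[t]:
            ins, w = max(ins_votes[t].items(), key=lambda kv: (kv[1], kv[0]))
            if w > total_w / 2:  # strict majority required to out-vote the rep
                out.append(ins)
        if t < len(rep):
            votes = dict(col_votes[t])
            best = max(votes.values())
            winners = {c for c, wv in votes.items() if wv == best}
            char = rep[t] if rep[t] in winners else min(winners)
            if char != "-":
                out.append(char)
    return "".join(out)


def filter_clusters(
    clusters: Sequence[SequenceCluster], min_total_reads: int = 21
) -> tuple[list[SequenceCluster], list[SequenceCluster]]:
    """Final size filter: keep clusters with >= *min_total_reads* pooled
    reads (default 21, i.e. 'more than 20').  Returns (passed, dropped)."""
    passed = [c for c in clusters if c.total_reads >= min_total_reads]
    dropped = [c for c in clusters if c.total_reads < min_total_reads]
    return passed, dropped


def dropped_read_mass(dropped: Sequence) -> int:
    """Total reads in dropped uniques/clusters, for conservation QC."""
    return sum(getattr(d, "total_reads", None) or d.total for d in dropped)
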
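"""Translation of cluster consensus sequences, unique deduced protein
fragments (UPFs), celiac-disease epitope scanning and sub-genome calls.

Epitope matching is exact string equality between every 9-residue window
of a fragment and the 9-mer cores of the catalog (non-deamidated Q-form;
deamidation chemistry is outside the scope of transcript profiling).
Overlapping and repeated occurrences each count.

Fragments containing an internal stop are translated through and kept,
flagged: transcripts whose premature stop lies downstream of the epitope
region remain a potential source of immunogenic peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cluster import SequenceCluster
from .reference import load_epitope_catalog, load_subgenome_motifs
from .simulate import translate_nt

#: The four canonical DQ2.5 cores (alpha1a, alpha1b, alpha2, alpha3).
CANONICAL_CORES = frozenset({"PFPQPQLPY", "PYPQPQLPY", "PQPQLPYPQ", "FRPQQPYPQ"})


@dataclass
class TranslatedFragment:
    aa_sequence: str
    has_internal_stop: bool
    frameshift_suspect: bool


def translate_fragment(nt: str) -> TranslatedFragment:
    """Standard-code frame-0 translation with stop/frameshift flags.

    A length not divisible by 3 marks the fragment ``frameshift_suspect``
    and translates floor(len/3) codons.  Internal stops are rendered
    as '*' and flagged; the fragment is retained.
    """
    if len(nt) < 3:
        raise ValueError("fragment shorter than one codon")
    aa = translate_nt(nt)
    return TranslatedFragment(aa, "*" in aa, len(nt) % 3 != 0)


@dataclass
class UPF:
    """A unique deduced protein fragment aggregating >= 1 clusters."""

    upf_id: str
    aa_sequence: str
    source_cluster_ids: list[str]
    per_sample_counts: dict[str, int]
    has_internal_stop: bool = False
    subgenome: str = "unassigned"

    @property
    def total(self) -> int:
        return sum(self.per_sample_counts.values())


def collapse_upfs(clusters: Sequence[SequenceCluster]) -> list[UPF]:
    """Merge clusters with identical deduced protein fragments into UPFs.

    UPFs are numbered by decreasing pooled read count (ties broken by
    sequence), matching the convention of naming the overall most
    abundant fragment first.
    """
    by_aa: dict[str, dict] = {}
    for cl in clusters:
        tr = translate_fragment(cl.consensus_nt)
        entry = by_aa.setdefault(
            tr.aa_sequence,
            {"clusters": [], "counts": {}, "stop": tr.has_internal_stop},
        )
        entry["clusters"].append(cl.cluster_id)
        for s, n in cl.per_sample_counts.items():
            entry["counts"][s] = entry["counts"].get(s, 0) + n
    ordered = sorted(
        by_aa.items(), key=lambda kv: (-sum(kv[1]["counts"].values()), kv[0])
    )
    return [
        UPF(f"U{i + 1:03d}", aa, e["clusters"], e["counts"], e["stop"])
        for i, (aa, e) in enumerate(ordered)
    ]


@dataclass
class EpitopeProfile:
    """Occurrence counts of every catalog epitope in one fragment."""

    counts: dict[str, int]
    canonical_total: int


def scan_epitopes(
    aa_sequence: str, catalog: Optional[pd.DataFrame] = None
) -> EpitopeProfile:
    """Count every catalog core in every 9-residue window of the fragment."""
    if catalog is None:
        catalog = load_epitope_catalog()
    counts = {name: 0 for name in catalog["name"]}
    cores = list(zip(catalog["name"], catalog["core"], catalog["status"]))
    canonical_total = 0
    for i in range(len(aa_sequence) - 8):
        window = aa_sequence[i : i + 9]
        for name, core, status in cores:
            if window == core:
                counts[name] += 1
                if status == "canonical":
                    canonical_total += 1
    return EpitopeProfile(counts, canonical_total)


def epitope_count_table(
    upfs: Sequence[UPF], catalog: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """UPF x epitope occurrence matrix plus a canonical_total column."""
    if catalog is None:
        catalog = load_epitope_catalog()
    rows = {}
    for upf in upfs:
        profile = scan_epitopes(upf.aa_sequence, catalog)
        rows[upf.upf_id] = {**profile.counts, "canonical_total": profile.canonical_total}
    columns = list(catalog["name"]) + ["canonical_total"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).fillna(0).astype(int)


def assign_subgenome(
    aa_sequence: str, motif_table: Optional[pd.DataFrame] = None
) -> str:
    """Assign A/B/D/D-B origin from diagnostic motifs.

    Precedence: D motif together with any B motif -> "D/B"; D motif
    alone -> "D"; any B motif -> "B"; else the (near-ubiquitous) "YS"
    dipeptide -> "A"; otherwise "unassigned".
    """
    if motif_table is None:
        motif_table = load_subgenome_motifs()
    present = {
        sub: any(m in aa_sequence for m in grp["motif"])
        for sub, grp in motif_table.groupby("subgenome")
    }
    if present.get("D") and present.get("B"):
        return "D/B"
    if present.get("D"):
        return "D"
    if present.get("B"):
        return "B"
    if present.get("A"):
        return "A"
    return "unassigned"


def annotate_subgenomes(
    upfs: Sequence[UPF], motif_table: Optional[pd.DataFrame] = None
) -> None:
    for upf in upfs:
        upf.subgenome = assign_subgenome(upf.aa_sequence, motif_table)
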
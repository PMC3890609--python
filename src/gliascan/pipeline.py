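"""End-to-end pipeline driver: demultiplex -> trim -> denoise -> cluster
-> translate -> collapse -> scan -> quantify -> profile.

All stages are pure functions from the sibling modules; this module
wires them together, enforces read-mass conservation between stages and
assembles a run report mirroring the per-run statistics a sequencing
facility would tabulate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import cluster as clu
from . import demux as dmx
from . import epitopes as epi
from . import quantify as qnt
from .io import Read, write_fasta, write_json, write_table
from .reference import load_epitope_catalog, load_subgenome_motifs

__version__ = "0.1.0"


@dataclass
class PipelineParams:
    """All tunable thresholds of the analysis, with the published defaults."""

    max_barcode_mismatch: int = 1
    identity_threshold: float = 0.995
    min_run_reads: int = 20     # unique must reach this in some sequencing run
    min_total_reads: int = 21   # cluster must exceed 20 pooled reads
    min_abundance: float = 0.1  # UPF filter: per-100 abundance floor
    min_upf_reads: int = 6      # UPF filter: more than 5 reads
    hp_min_ratio: float = 5.0
    hp_max_indels: int = 2
    profile_threshold: float = 0.5


@dataclass
class PipelineResult:
    demux_qc: pd.DataFrame
    trim_qc: pd.DataFrame
    clusters: list
    dropped_uniques: list
    dropped_clusters: list
    upfs: list
    matrix: qnt.AbundanceMatrix
    matrix_prefilter: qnt.AbundanceMatrix
    dropped_upfs: list
    epitope_counts: pd.DataFrame
    potential: pd.Series
    profiles: Optional[qnt.ProfileAssignment]
    report: dict

    def upf_by_sequence(self) -> dict[str, str]:
        return {u.aa_sequence: u.upf_id for u in self.upfs}


def _counts_frame(clusters_or_upfs: Sequence, ids: Sequence[str]) -> pd.DataFrame:
    samples = sorted({s for item in clusters_or_upfs for s in item.per_sample_counts})
    data = {
        i: {s: item.per_sample_counts.get(s, 0) for s in samples}
        for i, item in zip(ids, clusters_or_upfs)
    }
    return pd.DataFrame(data, index=samples).fillna(0).astype(int)


def run_pipeline(
    reads: Sequence[Read],
    barcode_map: dict[str, str],
    params: Optional[PipelineParams] = None,
    run_of_sample: Optional[dict[str, str]] = None,
    trim_spec: Optional[dmx.TrimSpec] = None,
    catalog: Optional[pd.DataFrame] = None,
    motif_table: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run every stage on a read set; raises if read mass is not conserved."""
    if params is None:
        params = PipelineParams()
    if catalog is None:
        catalog = load_epitope_catalog()
    if motif_table is None:
        motif_table = load_subgenome_motifs()

    reads = list(reads)
    assigned, unassigned = dmx.demultiplex(
        reads, barcode_map, max_mismatch=params.max_barcode_mismatch
    )
    n_assigned = sum(len(v) for v in assigned.values())
    if n_assigned + len(unassigned) != len(reads):
        raise RuntimeError("demultiplexing lost reads")
    demux_qc = pd.DataFrame(
        {"assigned": {s: len(v) for s, v in assigned.items()}}
    ).rename_axis("sample_id")

    fragments, trim_qc = dmx.trim_all(assigned, trim_spec)
    n_trimmed = sum(len(v) for v in fragments.values())

    derep = clu.dereplicate(
        f for frags in fragments.values() for f in frags
    )
    derep = clu.correct_homopolymers(
        derep, min_ratio=params.hp_min_ratio, max_hp_indels=params.hp_max_indels
    )
    if sum(r.total for r in derep) != n_trimmed:
        raise RuntimeError("read mass not conserved through homopolymer correction")

    gated, dropped_uniques = clu.abundance_gate(
        derep, run_of_sample=run_of_sample, min_run_reads=params.min_run_reads
    )
    clusters = clu.greedy_cluster(gated, identity_threshold=params.identity_threshold)
    clusters, dropped_clusters = clu.filter_clusters(
        clusters, min_total_reads=params.min_total_reads
    )
    n_clustered = sum(c.total_reads for c in clusters)
    mass_out = (
        n_clustered
        + clu.dropped_read_mass(dropped_uniques)
        + clu.dropped_read_mass(dropped_clusters)
    )
    if mass_out != n_trimmed:
        raise RuntimeError("read mass not conserved through clustering")

    upfs = epi.collapse_upfs(clusters)
    epi.annotate_subgenomes(upfs, motif_table)
    epitope_counts = epi.epitope_count_table(upfs, catalog)

    raw_counts = _counts_frame(upfs, [u.upf_id for u in upfs])
    matrix_prefilter = qnt.normalise(raw_counts)
    matrix, dropped_upfs = qnt.apply_upf_filter(
        matrix_prefilter, min_abundance=params.min_abundance, min_reads=params.min_upf_reads
    )
    potential = qnt.immunogenic_potential(matrix, epitope_counts["canonical_total"])

    profiles = None
    if len(matrix.samples) >= 2 and len(matrix.upfs) >= 2:
        profiles = qnt.cluster_profiles(matrix, threshold=params.profile_threshold)

    report = {
        "tool_version": __version__,
        "params": dataclasses.asdict(params),
        "n_samples": len(barcode_map),
        "raw_reads": len(reads),
        "assigned_reads": n_assigned,
        "unassigned_reads": len(unassigned),
        "trimmed_reads": n_trimmed,
        "reads_in_passed_clusters": n_clustered,
        "reads_dropped_by_gate": clu.dropped_read_mass(dropped_uniques),
        "reads_dropped_by_cluster_filter": clu.dropped_read_mass(dropped_clusters),
        "n_unique_sequences": len(derep),
        "n_clusters": len(clusters),
        "n_upfs": len(upfs),
        "n_upfs_after_filter": len(matrix.upfs),
    }
    return PipelineResult(
        demux_qc=demux_qc,
        trim_qc=trim_qc,
        clusters=clusters,
        dropped_uniques=dropped_uniques,
        dropped_clusters=dropped_clusters,
        upfs=upfs,
        matrix=matrix,
        matrix_prefilter=matrix_prefilter,
        dropped_upfs=dropped_upfs,
        epitope_counts=epitope_counts,
        potential=potential,
        profiles=profiles,
        report=report,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write all standard artifacts of a run into *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(
        (
            Read(f"{c.cluster_id}|reads={c.total_reads}", c.consensus_nt)
            for c in result.clusters
        ),
        out / "clusters.fasta",
    )
    write_fasta(
        (
            Read(
                f"{u.upf_id}|reads={u.total}|subgenome={u.subgenome.replace('/', '-')}",
                u.aa_sequence,
            )
            for u in result.upfs
        ),
        out / "upfs.fasta",
    )
    write_table(
        _counts_frame(result.clusters, [c.cluster_id for c in result.clusters]),
        out / "cluster_counts.tsv",
    )
    write_table(result.matrix.raw_counts, out / "upf_counts.tsv")
    write_table(result.matrix.values, out / "upf_abundance.tsv")
    write_table(result.epitope_counts, out / "epitope_counts.tsv")
    write_table(result.potential.rename("immunogenic_potential").to_frame(), out / "potential.tsv")
    write_table(result.trim_qc, out / "trim_qc.tsv")
    if result.profiles is not None:
        groups = pd.Series(result.profiles.groups, name="profile_group").rename_axis("sample_id")
        write_table(groups.to_frame(), out / "profile_groups.tsv")
        write_table(qnt.pearson_matrix(result.matrix), out / "correlations.tsv")
    write_json(result.report, out / "report.json")
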
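"""Synthetic 454-style amplicon read sets with known ground truth.

The simulator emulates the multiplexed RNA-amplicon design used for the
first repetitive domain of alpha-gliadins: each read carries a 10-bp
sample barcode, the degenerate forward primer at the start of the
signal-peptide coding region, the in-frame repetitive-domain coding
sequence, and the reverse-primer region.  The dominant 454 error mode —
single-base insertions/deletions inside homopolymer runs — is modelled
per run, plus uniform substitutions.

Templates are built by deterministic reverse translation of amino-acid
fragments.  A fixed codon table keeps nucleotide-level dereplication
reproducible, and a parity-coded synonymous "tag" (CAA/CAG wobble in the
first eight glutamine codons) guarantees that any two panel templates
differ by at least two nucleotides, as distinct transcripts of this
multigene family do in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import BarcodedRead
from .reference import load_expression_profiles

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed reverse-translation table (one codon per residue, wheat-leaning).
CODON_TABLE = {
    "A": "GCC", "C": "TGC", "D": "GAT", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAT", "I": "ATC", "K": "AAG", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGG",
    "S": "AGC", "T": "ACA", "V": "GTG", "W": "TGG", "Y": "TAC",
}

#: Degenerate forward primer at the start of the signal peptide
#: (MKTF[LP]I motif; R=A/G, M=A/C, Y=C/T).
FORWARD_PRIMER = "ATGAARACMTTTCYCATC"

#: IUPAC pattern matched by the reverse-primer region on the read strand
#: (reverse complement of the reverse primer).
REVERSE_ANCHOR = "AWCYAATTTCACAGCAGCAG"

#: 19-residue signal-peptide placeholder; its first six codons are the
#: forward-primer binding site.
SIGNAL_PEPTIDE_AA = "MKTFLILALLAIVATTATT"
SIGNAL_FLANK_NT = "ATGAAAACATTTCTCATC" + "".join(
    CODON_TABLE[a] for a in SIGNAL_PEPTIDE_AA[6:]
)

#: Read-strand sequence of the reverse-primer region appended downstream
#: of the domain; matches REVERSE_ANCHOR exactly.
DOWNSTREAM_FLANK_NT = "ATCCAATTTCACAGCAGCAG"

#: Mature-domain scaffold used to extend epitope-region fragments to
#: full repetitive-domain length.  Deliberately free of catalog epitope
#: cores, sub-genome B/D motifs and the YS dipeptide.
DOMAIN_PREFIX = "VRVPVPQLQPQNPSQQQPQEQVPLVQQQQFPGQQQPFPQQQPYPQPQPFPSQQPYLQLQ"
DOMAIN_SUFFIX = "SQPQQ"

#: Full fragments are padded to a constant length (residues).
FRAGMENT_LENGTH = 86

# Positions/letters used to make repeated epitope-region fragments
# distinct at the protein level (real UPFs sharing an epitope region
# differ elsewhere in the domain).  Letters are absent from the epitope
# catalog alphabet and their codons are >=2 nt from any scaffold codon.
_VARIANT_POSITIONS = (15, 16, 17, 18)
_VARIANT_LETTERS = "AKW"

_N_TAG_BITS = 8  # 7 index bits + even parity, over the first 8 Q codons


@dataclass
class TemplateAmplicon:
    """A reference transcript: amino-acid fragment + coding sequence + flanks."""

    template_id: str
    aa_fragment: str
    nt_sequence: str
    upstream_nt: str = SIGNAL_FLANK_NT
    downstream_nt: str = DOWNSTREAM_FLANK_NT

    def __post_init__(self) -> None:
        if len(self.nt_sequence) % 3:
            raise ValueError(f"{self.template_id}: coding length not divisible by 3")
        if translate_nt(self.nt_sequence) != self.aa_fragment:
            raise ValueError(f"{self.template_id}: nt sequence does not encode fragment")

    def read_template(self, barcode: str) -> str:
        return barcode + self.upstream_nt + self.nt_sequence + self.downstream_nt


@dataclass
class MixtureDesign:
    """Per-sample mixture: template proportions, read depth and barcode."""

    sample_id: str
    proportions: dict[str, float]
    depth: int
    barcode: str

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: proportions sum to {total}, not 1")
        if self.depth < 1:
            raise ValueError(f"{self.sample_id}: depth must be >= 1")
        if len(self.barcode) != 10:
            raise ValueError(f"{self.sample_id}: barcode must be 10 nt")


@dataclass
class ErrorModel:
    """454-style error rates.

    homopolymer_indel_rate
        Probability, per homopolymer run (length >= 2), that the run
        gains or loses one base (the dominant 454 error mode).
    substitution_rate
        Per-base substitution probability.  Pyrosequencing miscalls are
        indel-dominated, so the default is an order of magnitude below
        the homopolymer rate.
    """

    homopolymer_indel_rate: float = 0.01
    substitution_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("homopolymer_indel_rate", "substitution_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def translate_nt(nt: str) -> str:
    """In-frame translation with the standard code ('*' for stops)."""
    from Bio.Seq import Seq

    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def reverse_translate(aa: str, codon_table: dict[str, str] = CODON_TABLE) -> str:
    for pos, residue in enumerate(aa):
        if residue not in codon_table:
            raise ValueError(f"non-amino-acid character {residue!r} at position {pos}")
    return "".join(codon_table[a] for a in aa)


def _synonymous_tag(nt: str, index: int) -> str:
    """Recode the first 8 Q codons per an even-parity codeword of *index*.

    Distinct indices yield codewords at Hamming distance >= 2, so any
    two tagged templates differ by >= 2 nt even if their amino-acid
    fragments differ by a single residue with near-identical codons.
    """
    if index >= 2 ** (_N_TAG_BITS - 1):
        raise ValueError(f"panel too large for synonymous tagging ({index})")
    bits = [(index >> b) & 1 for b in range(_N_TAG_BITS - 1)]
    bits.append(sum(bits) % 2)
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    q_seen = 0
    for i, codon in enumerate(codons):
        if codon in ("CAA", "CAG"):
            if q_seen < _N_TAG_BITS:
                codons[i] = "CAG" if bits[q_seen] else "CAA"
            q_seen += 1
    return "".join(codons)


def expand_regions(regions: Sequence[str]) -> list[str]:
    """Extend epitope-region fragments to full-length domain fragments.

    Each region is embedded between a fixed scaffold prefix and suffix,
    padded to :data:`FRAGMENT_LENGTH` residues.  Repeated regions are
    made distinct by a single scaffold substitution, mirroring real
    fragments that share the epitope region but differ elsewhere.
    """
    seen: dict[str, int] = {}
    fragments = []
    for region in regions:
        region = region.replace("-", "")
        pad = FRAGMENT_LENGTH - len(DOMAIN_SUFFIX) - len(region)
        if pad < 1 or pad > len(DOMAIN_PREFIX):
            raise ValueError(f"region length {len(region)} outside supported range")
        prefix = DOMAIN_PREFIX[-pad:]
        ordinal = seen.get(region, 0)
        seen[region] = ordinal + 1
        if ordinal:
            k = ordinal - 1
            pos = _VARIANT_POSITIONS[k // len(_VARIANT_LETTERS)]
            letter = _VARIANT_LETTERS[k % len(_VARIANT_LETTERS)]
            prefix = prefix[:pos] + letter + prefix[pos + 1 :]
        fragments.append(prefix + region + DOMAIN_SUFFIX)
    return fragments


def build_reference_panel(
    aa_fragments: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    codon_table: dict[str, str] = CODON_TABLE,
    upstream_nt: str = SIGNAL_FLANK_NT,
    downstream_nt: str = DOWNSTREAM_FLANK_NT,
) -> list[TemplateAmplicon]:
    """Deterministically reverse-translate fragments into a template panel.

    Raises on duplicate input fragments (dereplicate first: one fragment,
    one template) and on non-amino-acid characters.
    """
    dupes = {f for f in aa_fragments if list(aa_fragments).count(f) > 1}
    if dupes:
        raise ValueError(f"duplicate input fragments: {sorted(dupes)}")
    if ids is None:
        ids = [f"T{i + 1:02d}" for i in range(len(aa_fragments))]
    if len(ids) != len(aa_fragments):
        raise ValueError("ids and aa_fragments length mismatch")
    panel = []
    for i, (tid, aa) in enumerate(zip(ids, aa_fragments)):
        nt = _synonymous_tag(reverse_translate(aa, codon_table), i)
        panel.append(
            TemplateAmplicon(tid, aa, nt, upstream_nt=upstream_nt, downstream_nt=downstream_nt)
        )
    if len({t.nt_sequence for t in panel}) != len(panel):
        raise ValueError("distinct fragments produced identical nt sequences")
    return panel


def default_panel(n: int = 10) -> list[TemplateAmplicon]:
    """Panel of the *n* most abundant published fragments (epitope regions
    extended to full repetitive-domain length)."""
    table = load_expression_profiles()
    regions = table["region"].tolist()[:n]
    return build_reference_panel(expand_regions(regions), ids=list(table.index[:n]))


def profile_mixture(profile: str = "p3", n: int = 10) -> dict[str, float]:
    """Mixture proportions over the default panel taken from one published
    expression-profile column, renormalised to sum to 1.

    Templates absent from the profile get proportion 0.
    """
    table = load_expression_profiles().iloc[:n]
    col = table[profile].astype(float)
    if col.sum() <= 0:
        raise ValueError(f"profile column {profile!r} empty over the first {n} templates")
    return (col / col.sum()).to_dict()


def generate_barcodes(
    n: int, seed: int = 0, length: int = 10, min_distance: int = 3
) -> list[str]:
    """Random sample barcodes with minimum pairwise Hamming distance.

    Distance >= 3 makes the 1-mismatch demultiplexing rule unambiguous.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    codes: list[str] = []
    arrs: list[np.ndarray] = []
    attempts = 0
    while len(codes) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("barcode generation did not converge")
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_distance for a in arrs):
            arrs.append(cand)
            codes.append("".join(bases[cand]))
    return codes


def homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(start, end) half-open intervals of runs of identical bases."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((start, i))
            start = i
    return runs


def _perturb_read(seq: str, runs: list[tuple[int, int]], model: ErrorModel, rng) -> str:
    # homopolymer +-1 events first (on the clean template run structure)
    if model.homopolymer_indel_rate > 0 and runs:
        hit = np.nonzero(rng.random(len(runs)) < model.homopolymer_indel_rate)[0]
        if len(hit):
            chars = list(seq)
            for ri in reversed(hit):  # right-to-left keeps coordinates valid
                start, end = runs[ri]
                if rng.random() < 0.5 and end - start >= 2:
                    del chars[start]
                else:
                    chars.insert(start, seq[start])
            seq = "".join(chars)
    if model.substitution_rate > 0:
        pos = np.nonzero(rng.random(len(seq)) < model.substitution_rate)[0]
        if len(pos):
            chars = list(seq)
            for p in pos:
                others = [b for b in "ACGT" if b != chars[p]]
                chars[p] = others[rng.integers(0, 3)]
            seq = "".join(chars)
    return seq


def simulate_reads(
    panel: Sequence[TemplateAmplicon],
    designs: Sequence[MixtureDesign],
    error_model: Optional[ErrorModel] = None,
) -> tuple[list[BarcodedRead], pd.DataFrame]:
    """Draw multiplexed reads for each design; returns reads + ground truth.

    Template draws are multinomial on the design proportions; read order
    within a sample is a seeded permutation.  Reproducible: the same
    panel, designs and error-model seed give byte-identical output.
    """
    if error_model is None:
        error_model = ErrorModel()
    by_id = {t.template_id: t for t in panel}
    for design in designs:
        unknown = set(design.proportions) - set(by_id)
        if unknown:
            raise ValueError(f"{design.sample_id}: unknown template ids {sorted(unknown)}")

    rng = np.random.default_rng(error_model.seed)
    reads: list[BarcodedRead] = []
    truth_rows = []
    for design in designs:
        template_ids = sorted(design.proportions)
        probs = np.array([design.proportions[t] for t in template_ids])
        counts = rng.multinomial(design.depth, probs)
        source = np.repeat(np.arange(len(template_ids)), counts)
        source = source[rng.permutation(len(source))]
        cache: dict[str, tuple[str, list[tuple[int, int]]]] = {}
        for i, ti in enumerate(source):
            tid = template_ids[ti]
            if tid not in cache:
                base = by_id[tid].read_template(design.barcode)
                cache[tid] = (base, homopolymer_runs(base))
            base, runs = cache[tid]
            seq = _perturb_read(base, runs, error_model, rng)
            read_id = f"{design.sample_id}_{i:06d}"
            reads.append(BarcodedRead(read_id, seq))
            truth_rows.append((read_id, design.sample_id, tid))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample_id", "template_id"])
    return reads, truth
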
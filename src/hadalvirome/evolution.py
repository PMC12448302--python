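"""SNV calling from pileups and codon-aware gene-level pN/pS.

The pileup abstraction is a per-site table of A/C/G/T counts with the
reference base; SNVs are called per non-reference allele at sufficiently
covered sites. pN/pS uses Nei–Gojobori-style site counting under the
standard genetic code with equal mutation rates: every codon contributes
its synonymous fraction of the nine single-base changes to S_sites, the
rest to N_sites (mutations to stop codons count as nonsynonymous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

MIN_COV = 5
MIN_FREQ = 0.05
MIN_ALT_COUNT = 2

BASES = "ACGT"
_CODON_AA = dict(standard_dna_table.forward_table)  # stops absent → None

__all__ = [
    "SNV", "GeneEvolMetrics", "call_snvs", "snv_density",
    "expected_sites", "classify_snv", "gene_pnps", "compare_metric_groups",
]


@dataclass(frozen=True)
class SNV:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    frequency: float
    coverage: int


@dataclass
class GeneEvolMetrics:
    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    pnps: float | None  # None when S_obs == 0 and N_obs > 0
    snvs_per_kb: float


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, None for stops."""
    return _CODON_AA.get(codon)


def call_snvs(
    pileup: pd.DataFrame,
    min_cov: int = MIN_COV,
    min_freq: float = MIN_FREQ,
    min_alt_count: int = MIN_ALT_COUNT,
) -> list[SNV]:
    """Call SNVs from a pileup table.

    ``pileup`` has columns contig, pos (1-based), ref, nA, nC, nG, nT. A
    position yields one SNV per non-reference base with frequency
    (count/coverage) ≥ ``min_freq`` and count ≥ ``min_alt_count``, at
    positions with coverage ≥ ``min_cov``. Zero-coverage positions are
    skipped silently.
    """
    out: list[SNV] = []
    counts = pileup[["nA", "nC", "nG", "nT"]].values
    coverage = counts.sum(axis=1)
    for row, cov in zip(pileup.itertuples(index=False), coverage):
        if cov < min_cov:
            continue
        ref = row.ref.upper()
        for b, c in zip(BASES, (row.nA, row.nC, row.nG, row.nT)):
            if b == ref or c < min_alt_count:
                continue
            freq = c / cov
            if freq >= min_freq:
                out.append(SNV(row.contig, int(row.pos), ref, b,
                               float(freq), int(cov)))
    return out


def covered_length(pileup: pd.DataFrame, min_cov: int = MIN_COV) -> int:
    """Number of positions with coverage ≥ min_cov."""
    cov = pileup[["nA", "nC", "nG", "nT"]].sum(axis=1)
    return int((cov >= min_cov).sum())


def snv_density(snvs: list[SNV], covered_length_bp: int) -> float:
    """SNVs per kilobase of sufficiently covered sequence.

    Counts distinct SNV positions (a multi-allelic site is one position).
    """
    if covered_length_bp <= 0:
        raise ValueError("covered length must be positive")
    positions = {(s.contig, s.position) for s in snvs}
    return 1000.0 * len(positions) / covered_length_bp


def expected_sites(sequence: str) -> tuple[float, float]:
    """(N_sites, S_sites) for an in-frame coding sequence.

    Each codon position contributes the synonymous fraction of its three
    single-base alternatives to S_sites and the rest to N_sites, so
    N_sites + S_sites = 3 × #codons exactly. Codons containing ambiguous
    bases are skipped (both totals unaffected).
    """
    seq = sequence.upper()
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    n_sites = s_sites = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) - set(BASES):
            continue
        ref_aa = _aa(codon)
        for pos in range(3):
            syn = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if _aa(mut) is not None and ref_aa is not None and _aa(mut) == ref_aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += (3 - syn) / 3.0
    return n_sites, s_sites


_RC = str.maketrans("ACGT", "TGCA")


def classify_snv(
    snv: SNV, gene_start: int, gene_end: int, strand: str, contig_seq: str
) -> str | None:
    """Classify one SNV as 'synonymous' or 'nonsynonymous' for a gene.

    Returns None when the SNV falls outside the gene. Minus-strand genes are
    evaluated on the reverse complement (codon 1 starts at ``gene_end``).
    """
    if not (gene_start <= snv.position <= gene_end):
        return None
    if strand == "+":
        offset = snv.position - gene_start
        ref_base, alt_base = snv.ref, snv.alt
        cds = contig_seq[gene_start - 1:gene_end].upper()
    else:
        offset = gene_end - snv.position
        ref_base, alt_base = snv.ref.translate(_RC), snv.alt.translate(_RC)
        cds = contig_seq[gene_start - 1:gene_end].upper().translate(_RC)[::-1]
    codon_i, codon_pos = divmod(offset, 3)
    codon = cds[3 * codon_i:3 * codon_i + 3]
    if len(codon) < 3:
        return None
    if codon[codon_pos] != ref_base:
        raise ValueError(
            f"SNV reference {snv.ref} at {snv.contig}:{snv.position} "
            f"disagrees with gene sequence")
    mut = codon[:codon_pos] + alt_base + codon[codon_pos + 1:]
    same = _aa(mut) == _aa(codon) and _aa(codon) is not None
    return "synonymous" if same else "nonsynonymous"


def gene_pnps(
    gene_id: str,
    gene_start: int,
    gene_end: int,
    strand: str,
    contig_seq: str,
    snvs: list[SNV],
    covered_bp: int | None = None,
) -> GeneEvolMetrics:
    """Gene-level pN/pS and SNV density from called SNVs.

    pN/pS = (N_obs/N_sites) / (S_obs/S_sites); None (undefined) when
    S_obs = 0; 0 when N_obs = 0 with S_obs > 0. Multi-allelic
    positions contribute one observation per alternate allele. SNVs outside
    the gene are ignored.
    """
    if strand == "+":
        cds = contig_seq[gene_start - 1:gene_end].upper()
    else:
        cds = contig_seq[gene_start - 1:gene_end].upper().translate(_RC)[::-1]
    n_sites, s_sites = expected_sites(cds)
    n_obs = s_obs = 0
    positions = set()
    for snv in snvs:
        klass = classify_snv(snv, gene_start, gene_end, strand, contig_seq)
        if klass is None:
            continue
        positions.add(snv.position)
        if klass == "synonymous":
            s_obs += 1
        else:
            n_obs += 1
    if s_obs > 0:
        pnps: float | None = (n_obs / n_sites) / (s_obs / s_sites)
    else:
        pnps = None  # undefined without synonymous observations
    length = covered_bp if covered_bp is not None else (gene_end - gene_start + 1)
    density = 1000.0 * len(positions) / length if length else 0.0
    return GeneEvolMetrics(gene_id, n_obs, s_obs, n_sites, s_sites, pnps, density)


def compare_metric_groups(
    values: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between metric groups.

    ``values`` holds one metric per genome/gene, ``groups`` the class label
    (trench, depth bin). Returns one row per group pair with medians, U and
    p; no multiplicity adjustment is applied.
    """
    from .ecology import wilcoxon_rank_sum

    labels = groups.dropna().unique()
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa = values[groups == a].dropna().values
            xb = values[groups == b].dropna().values
            if len(xa) == 0 or len(xb) == 0:
                raise ValueError("empty group")
            u, p = wilcoxon_rank_sum(xa, xb)
            rows.append({
                "group_a": a, "group_b": b,
                "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
                "U": u, "p": p,
            })
    return pd.DataFrame(rows)
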
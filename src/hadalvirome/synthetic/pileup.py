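"""Coding contigs, planted variants of known synonymy, and pileup profiles.

The pileup emulates per-site allele counts downstream of read mapping: site
coverage is Poisson around a mean, and base counts are multinomial over
(reference, planted alternates at their true frequencies, uniform
sequencing errors). No read-level artefacts (indels, mapping bias) are
modelled — the metric layer consumes counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..evolution import SNV, classify_snv

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)
                 if "".join(c) not in _STOPS]

__all__ = ["CodingContig", "PlantedVariant", "make_coding_contig",
           "plant_variants", "generate_pileup"]


@dataclass
class PlantedVariant:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    frequency: float
    synonymy: str  # synonymous | nonsynonymous | intergenic


@dataclass
class CodingContig:
    contig: str
    sequence: str
    genes: pd.DataFrame  # contig, gene_id, start, end, strand (1-based incl.)


def make_coding_contig(
    seed: int,
    contig_id: str = "contig_1",
    n_genes: int = 3,
    codons_per_gene: int = 300,
    intergenic: int = 60,
    strands: str | None = None,
) -> CodingContig:
    """Random contig with stop-free in-frame genes separated by spacers.

    Gene sequences are drawn codon-wise from the 61 sense codons so every
    gene translates cleanly; minus-strand genes carry the reverse complement
    of their coding sequence on the contig.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    comp = str.maketrans(BASES, "TGCA")
    parts: list[str] = []
    rows = []
    pos = 1
    for g in range(n_genes):
        spacer = "".join(rng.choice(list(BASES), size=intergenic))
        parts.append(spacer)
        pos += intergenic
        cds = "".join(rng.choice(_SENSE_CODONS) for _ in range(codons_per_gene))
        strand = (strands[g % len(strands)] if strands
                  else ("+" if g % 2 == 0 else "-"))
        on_contig = cds if strand == "+" else cds.translate(comp)[::-1]
        parts.append(on_contig)
        rows.append({"contig": contig_id, "gene_id": f"{contig_id}_g{g + 1}",
                     "start": pos, "end": pos + len(cds) - 1, "strand": strand})
        pos += len(cds)
    parts.append("".join(rng.choice(list(BASES), size=intergenic)))
    seq = "".join(parts)
    return CodingContig(contig_id, seq, pd.DataFrame(rows))


def _synonymy(contig: CodingContig, position: int, ref: str, alt: str) -> str:
    for row in contig.genes.itertuples():
        if row.start <= position <= row.end:
            snv = SNV(contig.contig, position, ref, alt, 0.5, 100)
            klass = classify_snv(snv, row.start, row.end, row.strand,
                                 contig.sequence)
            assert klass is not None
            return klass
    return "intergenic"


def plant_variants(
    seed: int,
    contig: CodingContig,
    n_variants: int = 30,
    freq_range: tuple[float, float] = (0.2, 0.8),
) -> list[PlantedVariant]:
    """Plant variants at distinct uniform positions with uniform alternates.

    All nine mutation types are equally likely, so in expectation the
    planted pool is selectively neutral; synonymy is recorded from the gene
    models and the standard genetic code. Frequencies are uniform over
    ``freq_range`` — the default keeps every variant far from the SNV-calling
    floor so recovery is a property of the caller, not of sampling luck.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    L = len(contig.sequence)
    if n_variants > L:
        raise ValueError("more variants than positions")
    positions = rng.choice(L, size=n_variants, replace=False) + 1
    out: list[PlantedVariant] = []
    for p in sorted(int(x) for x in positions):
        ref = contig.sequence[p - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        freq = float(rng.uniform(*freq_range))
        out.append(PlantedVariant(contig.contig, p, ref, alt, freq,
                                  _synonymy(contig, p, ref, alt)))
    return out


def generate_pileup(
    seed: int,
    contig: CodingContig,
    variants: list[PlantedVariant],
    mean_coverage: float = 100.0,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Pileup table (contig, pos, ref, nA, nC, nG, nT) with planted variants.

    Per site, coverage ~ Poisson(mean); each read carries a planted
    alternate with its true frequency, otherwise the reference with uniform
    error ``error_rate`` to the three other bases.
    """
    if mean_coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    L = len(contig.sequence)
    by_pos: dict[int, list[PlantedVariant]] = {}
    for v in variants:
        if not (1 <= v.position <= L):
            raise ValueError(f"planted position {v.position} outside contig")
        by_pos.setdefault(v.position, []).append(v)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cov = rng.poisson(mean_coverage, size=L)
    rows = []
    for p in range(1, L + 1):
        ref = contig.sequence[p - 1]
        probs = dict.fromkeys(BASES, 0.0)
        f_tot = sum(v.frequency for v in by_pos.get(p, ()))
        for v in by_pos.get(p, ()):
            probs[v.alt] += v.frequency
        rest = 1.0 - f_tot
        probs[ref] += rest * (1.0 - error_rate)
        for b in BASES:
            if b != ref:
                probs[b] += rest * error_rate / 3.0
        counts = rng.multinomial(cov[p - 1], [probs[b] for b in BASES])
        rows.append((contig.contig, p, ref, *counts))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref",
                                       "nA", "nC", "nG", "nT"])
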
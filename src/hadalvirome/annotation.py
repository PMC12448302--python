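"""Rule-based curation of auxiliary metabolic genes and lifestyle calls.

Candidate AMGs on viral contigs are kept only when every filter passes:
annotation confidence (bit score ≥ 60, auxiliary score ≤ 3), not on the
denylist of viral-housekeeping categories, flanked by at least two
viral-like genes among the two nearest neighbours on each side, and not
sitting near a contig end next to a tRNA or repeat (a classic signature of
mis-attached host sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MIN_BITSCORE = 60.0
MAX_AUX_SCORE = 3
MIN_VIRAL_NEIGHBOURS = 2
NEIGHBOUR_WINDOW = 2  # genes inspected on each side
DEFAULT_END_WINDOW = 5000  # bp from a contig end

DENYLIST = frozenset({
    "nucleotide metabolism",
    "DNA-related reactions",
    "modification of viral components",
    "ribosomal proteins",
    "transcriptional/translational regulators",
    "viral invasion",
})

LYSOGENY_MARKERS = frozenset({
    "integrase", "recombinase", "transposase", "excisionase",
    "ci_repressor", "cro_repressor", "parA", "parB",
})

__all__ = [
    "AnnotatedGene", "AMGRecord", "curate_amgs", "classify_lifestyle",
    "amg_abundance", "DENYLIST", "LYSOGENY_MARKERS",
]


@dataclass
class AnnotatedGene:
    contig: str
    gene_id: str
    index: int  # ordinal position on the contig, 0-based
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    is_viral_like: bool = False
    is_candidate_amg: bool = False
    is_lysogeny_marker: bool = False
    is_trna: bool = False
    function_id: str = ""
    bitscore: float = 0.0
    aux_score: int = 5
    denylist_category: str | None = None
    near_repeat: bool = False  # adjacency to inverted/direct repeat

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class AMGRecord:
    gene_id: str
    contig: str
    function_id: str
    passed_filters: frozenset = field(default_factory=frozenset)


def _check_ordering(genes: list[AnnotatedGene]) -> None:
    by_contig: dict[str, list[AnnotatedGene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, gs in by_contig.items():
        idx = [g.index for g in gs]
        if idx != sorted(idx) or [g.start for g in gs] != sorted(g.start for g in gs):
            raise ValueError(f"genes on contig {contig} are not position-ordered")


def curate_amgs(
    genes: list[AnnotatedGene],
    contig_lengths: dict[str, int],
    end_window: int = DEFAULT_END_WINDOW,
) -> list[AMGRecord]:
    """Apply the full AMG retention rule set.

    A candidate is kept iff bit score ≥ 60 AND auxiliary score ≤ 3 AND no
    denylist category AND ≥ 2 viral-like genes among its two nearest
    neighbours per side (counted jointly across both sides) AND NOT (within
    ``end_window`` bp of a contig end while adjacent to a tRNA gene or an
    annotated repeat). Unknown denylist labels raise.
    """
    _check_ordering(genes)
    for g in genes:
        if g.denylist_category is not None and g.denylist_category not in DENYLIST:
            raise ValueError(f"unknown denylist label {g.denylist_category!r}")

    by_contig: dict[str, list[AnnotatedGene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    out: list[AMGRecord] = []
    for contig, gs in by_contig.items():
        clen = contig_lengths[contig]
        for pos, g in enumerate(gs):
            if not g.is_candidate_amg:
                continue
            passed: set[str] = set()
            if g.bitscore >= MIN_BITSCORE:
                passed.add("bitscore")
            if g.aux_score <= MAX_AUX_SCORE:
                passed.add("aux_score")
            if g.denylist_category is None:
                passed.add("denylist")
            neighbours = (
                gs[max(0, pos - NEIGHBOUR_WINDOW):pos]
                + gs[pos + 1:pos + 1 + NEIGHBOUR_WINDOW]
            )
            if sum(n.is_viral_like for n in neighbours) >= MIN_VIRAL_NEIGHBOURS:
                passed.add("viral_neighbours")
            near_end = g.start <= end_window or g.end > clen - end_window
            adj = gs[max(0, pos - 1):pos] + gs[pos + 1:pos + 2]
            suspicious = any(n.is_trna for n in adj) or g.near_repeat or any(
                n.near_repeat for n in adj
            )
            if not (near_end and suspicious):
                passed.add("end_filter")
            if passed == {"bitscore", "aux_score", "denylist",
                          "viral_neighbours", "end_filter"}:
                out.append(AMGRecord(g.gene_id, contig, g.function_id,
                                     frozenset(passed)))
    return out


def classify_lifestyle(
    genes: list[AnnotatedGene],
    provirus: bool = False,
    upstream_lytic: bool | None = None,
) -> str:
    """Lifestyle call for one contig's genes.

    Temperate when any lysogeny-marker gene is present or the contig is an
    integrated provirus; otherwise lytic when upstream tools called lytic;
    otherwise unknown.
    """
    if provirus or any(g.is_lysogeny_marker for g in genes):
        return "temperate"
    if upstream_lytic:
        return "lytic"
    return "unknown"


def amg_abundance(
    amgs: list[AMGRecord],
    abundance: pd.DataFrame,
    contig_to_votu: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Function × sample abundance of retained AMGs.

    Abundance of function f in sample s is the summed RPKM of vOTUs carrying
    at least one retained AMG of f — each vOTU counted once per function
    regardless of copy number. ``contig_to_votu`` defaults to identity.
    """
    contig_to_votu = contig_to_votu or {}
    pairs: set[tuple[str, str]] = set()
    missing = []
    for amg in amgs:
        votu = contig_to_votu.get(amg.contig, amg.contig)
        if votu not in abundance.index:
            missing.append(amg.contig)
            continue
        pairs.add((amg.function_id, votu))
    if missing:
        raise ValueError(f"contigs not mapped to vOTUs in the table: {sorted(set(missing))}")
    functions = sorted({f for f, _ in pairs})
    out = pd.DataFrame(0.0, index=functions, columns=abundance.columns)
    for f, votu in pairs:
        out.loc[f] += abundance.loc[votu].values
    return out
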
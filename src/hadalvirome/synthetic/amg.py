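"""Constructed AMG-curation fixture with exact designed ground truth.

One contig carries seven candidate AMGs; exactly three are designed to pass
the full rule set, the other four each fail a single, different filter
(auxiliary score, bit score, denylist, genome-end adjacency to a tRNA).
"""

from __future__ import annotations

from ..annotation import AnnotatedGene

CONTIG_ID = "amg_demo_contig"
CONTIG_LENGTH = 19_800
EXPECTED_SURVIVORS = ("amg_pass_1", "amg_pass_2", "amg_pass_3")

__all__ = ["amg_demo_contig", "CONTIG_ID", "CONTIG_LENGTH", "EXPECTED_SURVIVORS"]


def amg_demo_contig() -> tuple[list[AnnotatedGene], dict[str, int]]:
    """Return (genes, contig_lengths) for the seven-candidate demo contig."""
    layout = [
        # (gene_id, viral_like, candidate, trna, bitscore, aux, denylist)
        ("viral_01", True, False, False, 0, 5, None),
        ("amg_pass_1", False, True, False, 80.0, 2, None),
        ("viral_02", True, False, False, 0, 5, None),
        ("amg_fail_aux", False, True, False, 80.0, 4, None),
        ("viral_03", True, False, False, 0, 5, None),
        ("amg_fail_bits", False, True, False, 50.0, 2, None),
        ("viral_04", True, False, False, 0, 5, None),
        ("amg_fail_denylist", False, True, False, 80.0, 2, "ribosomal proteins"),
        ("viral_05", True, False, False, 0, 5, None),
        ("amg_pass_2", False, True, False, 75.0, 3, None),
        ("viral_06", True, False, False, 0, 5, None),
        ("amg_pass_3", False, True, False, 90.0, 1, None),
        ("viral_07", True, False, False, 0, 5, None),
        ("trna_01", False, False, True, 0, 5, None),
        ("amg_fail_end", False, True, False, 80.0, 2, None),
        ("viral_08", True, False, False, 0, 5, None),
        ("viral_09", True, False, False, 0, 5, None),
    ]
    genes = []
    for i, (gid, viral, cand, trna, bits, aux, deny) in enumerate(layout):
        start = 6000 + i * 700
        genes.append(AnnotatedGene(
            contig=CONTIG_ID, gene_id=gid, index=i,
            start=start, end=start + 599, strand="+",
            is_viral_like=viral, is_candidate_amg=cand, is_trna=trna,
            function_id=f"K{10000 + i}", bitscore=float(bits),
            aux_score=aux, denylist_category=deny,
        ))
    return genes, {CONTIG_ID: CONTIG_LENGTH}
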
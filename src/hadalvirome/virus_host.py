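"""Virus–host linkage prediction: four evidence channels plus integration.

Channels and their retention thresholds:

* ``homology`` — nucleotide alignment hits (BLAST-outfmt-6-like rows) kept
  when query coverage ≥ 0.75 of the viral sequence, identity ≥ 70%,
  alignment length ≥ 1500 bp, bit score ≥ 50, e-value ≤ 1e-3 — all jointly.
* ``trna`` — a viral tRNA identical, full length, to a host tRNA (either
  strand).
* ``crispr`` — a host CRISPR spacer matching a full-length window of the
  viral genome (either strand) with ≤ 1 mismatch, identity ≥ 95% and
  coverage ≥ 95%.
* ``onf`` — oligonucleotide-frequency dissimilarity d2* ≤ 0.2 between viral
  and host genomes (k-mer counts centered by each sequence's own Markov
  background).

Integration keeps, per virus, candidates supported by the maximal number of
distinct methods; cross-phylum ties are resolved in favour of CRISPR/tRNA
evidence, and dropped entirely when no such evidence exists.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

HOMOLOGY_MIN_COVERAGE = 0.75
HOMOLOGY_MIN_IDENTITY = 70.0
HOMOLOGY_MIN_BITSCORE = 50.0
HOMOLOGY_MIN_LENGTH = 1500
HOMOLOGY_MAX_EVALUE = 1e-3
SPACER_MAX_MISMATCH = 1
SPACER_MIN_IDENTITY = 0.95
SPACER_MIN_COVERAGE = 0.95
SPACER_MIN_LENGTH = 15
D2STAR_MAX = 0.2

_COMP = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "EvidenceRecord",
    "VirusHostLink",
    "filter_homology",
    "match_trna",
    "match_spacers",
    "d2star",
    "onf_evidence",
    "integrate",
    "linkage_stats",
]


@dataclass(frozen=True)
class EvidenceRecord:
    virus: str
    host: str
    method: str  # homology | trna | crispr | onf
    score: float


@dataclass
class VirusHostLink:
    virus: str
    host: str
    methods: frozenset
    phylum: str


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------- homology

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
]


def filter_homology(hits: pd.DataFrame) -> list[EvidenceRecord]:
    """Apply the five homology thresholds jointly to a hit table.

    ``hits`` needs columns qseqid, sseqid, pident, length, evalue, bitscore
    and qlen (viral query length; coverage = length / qlen). Malformed rows
    are rejected with a log line rather than aborting the batch.
    """
    out: list[EvidenceRecord] = []
    for idx, row in hits.iterrows():
        try:
            pid = float(row["pident"])
            length = float(row["length"])
            bits = float(row["bitscore"])
            ev = float(row["evalue"])
            qlen = float(row["qlen"])
            if qlen <= 0 or length <= 0 or not (0 <= pid <= 100):
                raise ValueError("out-of-range fields")
        except (KeyError, TypeError, ValueError) as exc:
            logger.warning("filter_homology: rejecting row %s (%s)", idx, exc)
            continue
        coverage = length / qlen
        if (
            coverage >= HOMOLOGY_MIN_COVERAGE
            and pid >= HOMOLOGY_MIN_IDENTITY
            and bits >= HOMOLOGY_MIN_BITSCORE
            and length >= HOMOLOGY_MIN_LENGTH
            and ev <= HOMOLOGY_MAX_EVALUE
        ):
            out.append(EvidenceRecord(str(row["qseqid"]), str(row["sseqid"]),
                                      "homology", bits))
    return out


# -------------------------------------------------------------------- tRNA

def match_trna(
    viral_trnas: dict[str, str], host_trnas: dict[str, str]
) -> list[EvidenceRecord]:
    """Exact full-length tRNA duplicates between viruses and hosts.

    Keys are ``(trna_id, genome_id)`` tuples or ``"trnaID|genomeID"``
    strings; values are sequences. Both strands are searched. Evidence score
    is the tRNA length.
    """
    def parse(items):
        for key, seq in items.items():
            if isinstance(key, tuple):
                tid, gid = key
            else:
                tid, _, gid = str(key).partition("|")
            yield tid, gid, seq.upper()

    host_index: dict[str, set[str]] = defaultdict(set)
    for _, gid, seq in parse(host_trnas):
        host_index[seq].add(gid)
        host_index[revcomp(seq)].add(gid)

    seen: set[tuple[str, str]] = set()
    out: list[EvidenceRecord] = []
    for _, virus, seq in parse(viral_trnas):
        for host in host_index.get(seq, ()):  # revcomp already indexed
            if (virus, host) not in seen:
                seen.add((virus, host))
                out.append(EvidenceRecord(virus, host, "trna", float(len(seq))))
    return out


# ------------------------------------------------------------------ CRISPR

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_hamming(spacer: str, genome: np.ndarray) -> int:
    """Minimum Hamming distance of the spacer over all full-length windows."""
    L = len(spacer)
    if genome.size < L:
        return L + 1
    windows = np.lib.stride_tricks.sliding_window_view(genome, L)
    mism = (windows != _encode(spacer)).sum(axis=1)
    return int(mism.min())


def match_spacers(
    spacers: dict, viral_genomes: dict[str, str]
) -> list[EvidenceRecord]:
    """CRISPR spacer hits against viral genomes.

    ``spacers`` maps ``(spacer_id, host_id)`` tuples or ``"spacerID|hostID"``
    strings to spacer sequences. A spacer matches a viral genome iff some
    full-length window on either strand has ≤ 1 mismatch AND identity ≥ 95%
    AND coverage ≥ 95% (full-length windows give coverage 1.0). The joint
    identity constraint bites for spacers shorter than 20 nt, where a single
    mismatch already drops identity below 95%. Spacers with non-ACGT symbols
    are skipped with a warning; evidence score is the mismatch count.
    """
    enc = {v: _encode(g.upper()) for v, g in viral_genomes.items()}
    out: list[EvidenceRecord] = []
    seen: set[tuple[str, str]] = set()
    for key, seq in spacers.items():
        if isinstance(key, tuple):
            sid, host = key
        else:
            sid, _, host = str(key).partition("|")
        seq = seq.upper()
        if len(seq) < SPACER_MIN_LENGTH:
            logger.warning("match_spacers: spacer %s below %d nt; skipped",
                           sid, SPACER_MIN_LENGTH)
            continue
        if set(seq) - set("ACGT"):
            logger.warning("match_spacers: spacer %s has non-ACGT symbols; skipped", sid)
            continue
        max_mm_identity = int((1.0 - SPACER_MIN_IDENTITY) * len(seq))
        allowed = min(SPACER_MAX_MISMATCH, max_mm_identity)
        rc = revcomp(seq)
        for virus, genome in enc.items():
            if (virus, host) in seen:
                continue
            mm = min(_best_hamming(seq, genome), _best_hamming(rc, genome))
            if mm <= allowed:  # coverage is 1.0 by full-length construction
                seen.add((virus, host))
                out.append(EvidenceRecord(virus, host, "crispr", float(mm)))
    return out


# --------------------------------------------------------------------- d2*

def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers over the sequence and its reverse complement.

    Windows containing non-ACGT symbols are dropped.
    """
    base = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        base[b] = i
    counts = np.zeros(4**k, dtype=np.float64)
    for s in (seq, revcomp(seq)):
        code = base[_encode(s)]
        valid = code >= 0
        if len(code) < k:
            continue
        idx = np.zeros(len(code) - k + 1, dtype=np.int64)
        ok = np.ones(len(idx), dtype=bool)
        for off in range(k):
            c = code[off : off + len(idx)]
            idx = idx * 4 + np.where(c >= 0, c, 0)
            ok &= valid[off : off + len(idx)]
        np.add.at(counts, idx[ok], 1.0)
    return counts


def _expected_counts(seq: str, k: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """(observed, expected) k-mer counts under the sequence's own
    order-``order`` Markov model, both strands pooled."""
    obs = _kmer_counts(seq, k)
    ctx = _kmer_counts(seq, order)  # order-mer counts
    ext = _kmer_counts(seq, order + 1)  # (order+1)-mer counts
    total = obs.sum()
    n_ctx = ctx.sum()
    # transition P(b | w) and stationary P(w) from pooled counts
    ctx_p = ctx / n_ctx
    trans = ext.reshape(4**order, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        trans_p = trans / trans.sum(axis=1, keepdims=True)
    trans_p = np.nan_to_num(trans_p)

    # P(w1..wk) = P(first order-mer) * prod transitions; computed by dynamic
    # programming over k-mer indices.
    probs = ctx_p.copy()
    for _ in range(order, k):
        # probs currently over length-L words, indexed base-4; extend by one
        L_idx = probs.shape[0]
        ctx_idx = np.arange(L_idx) % (4**order)
        step = trans_p[ctx_idx]  # (L_idx, 4)
        probs = (probs[:, None] * step).reshape(L_idx * 4)
    exp = probs * total
    return obs, exp


def d2star(
    x: str, y: str, k: int = 6, markov_order: int = 2
) -> float:
    """d2* dissimilarity in [0, 1] between two sequences.

    Counts k-mers over both strands, centers them by each sequence's own
    order-r Markov expectation (Ñ_w = N_w − E_w), and computes

        S = Σ_w Ñ^x Ñ^y / √(E^x E^y)
        d2* = ½ (1 − S / (√Σ(Ñ^x)²/E^x · √Σ(Ñ^y)²/E^y)).

    k-mers with zero expected count in either sequence are excluded from the
    sums (tally logged). Requires length ≥ 10·4^markov_order and k > order.
    """
    if k <= markov_order:
        raise ValueError("k must exceed markov_order")
    floor = 10 * 4**markov_order
    for name, s in (("x", x), ("y", y)):
        if len(s) < floor:
            raise ValueError(f"sequence {name} shorter than estimability floor {floor}")
    ox, ex = _expected_counts(x.upper(), k, markov_order)
    oy, ey = _expected_counts(y.upper(), k, markov_order)
    ok = (ex > 0) & (ey > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.debug("d2star: %d k-mer(s) with zero expectation excluded", dropped)
    cx = ox[ok] - ex[ok]
    cy = oy[ok] - ey[ok]
    num = np.sum(cx * cy / np.sqrt(ex[ok] * ey[ok]))
    nx = math.sqrt(np.sum(cx**2 / ex[ok]))
    ny = math.sqrt(np.sum(cy**2 / ey[ok]))
    if nx == 0 or ny == 0:
        return 0.5
    s = num / (nx * ny)
    return float(0.5 * (1.0 - s))


def onf_evidence(
    viruses: dict[str, str],
    hosts: dict[str, str],
    k: int = 6,
    markov_order: int = 2,
    threshold: float = D2STAR_MAX,
) -> list[EvidenceRecord]:
    """All virus-host pairs with d2* ≤ threshold."""
    out = []
    host_stats = {h: _expected_counts(s.upper(), k, markov_order) for h, s in hosts.items()}
    for v, vs in viruses.items():
        ov, ev = _expected_counts(vs.upper(), k, markov_order)
        for h, (oh, eh) in host_stats.items():
            ok = (ev > 0) & (eh > 0)
            cv, ch = ov[ok] - ev[ok], oh[ok] - eh[ok]
            nx = math.sqrt(np.sum(cv**2 / ev[ok]))
            ny = math.sqrt(np.sum(ch**2 / eh[ok]))
            if nx == 0 or ny == 0:
                d = 0.5
            else:
                s = np.sum(cv * ch / np.sqrt(ev[ok] * eh[ok])) / (nx * ny)
                d = float(0.5 * (1.0 - s))
            if d <= threshold:
                out.append(EvidenceRecord(v, h, "onf", d))
    return out


# -------------------------------------------------------------- integration

def integrate(
    evidence: list[EvidenceRecord], taxonomy: dict[str, str]
) -> list[VirusHostLink]:
    """Integrate method-level evidence into per-virus host assignments.

    Per virus: a single candidate host is kept outright; among multiple
    candidates only those supported by the maximal number of distinct
    methods survive; if the survivors still span more than one phylum, only
    those with CRISPR or tRNA support are kept, and when none has such
    support all are dropped. Idempotent and invariant to evidence order.
    """
    methods_by_pair: dict[tuple[str, str], set[str]] = defaultdict(set)
    for ev in evidence:
        if ev.host not in taxonomy:
            raise ValueError(f"host {ev.host!r} missing from taxonomy map")
        methods_by_pair[(ev.virus, ev.host)].add(ev.method)

    by_virus: dict[str, list[tuple[str, set[str]]]] = defaultdict(list)
    for (virus, host), methods in methods_by_pair.items():
        by_virus[virus].append((host, methods))

    links: list[VirusHostLink] = []
    for virus in sorted(by_virus):
        cands = by_virus[virus]
        if len(cands) > 1:
            top = max(len(m) for _, m in cands)
            cands = [(h, m) for h, m in cands if len(m) == top]
            phyla = {taxonomy[h] for h, _ in cands}
            if len(phyla) > 1:
                cands = [(h, m) for h, m in cands if m & {"crispr", "trna"}]
                if not cands:
                    logger.info(
                        "integrate: virus %s dropped (cross-phylum tie without "
                        "CRISPR/tRNA support)", virus)
                    continue
        for host, methods in sorted(cands):
            links.append(VirusHostLink(virus, host, frozenset(methods),
                                       taxonomy[host]))
    return links


# ------------------------------------------------------------ linkage stats

@dataclass
class LinkageStatsReport:
    """Virus-to-host-ratio table and the Spearman correlations over it."""

    vhr: pd.DataFrame  # virus, host, sample, virus_rpkm, host_rpkm, vhr, lifestyle
    correlations: pd.DataFrame  # comparison × (rho, p, n), overall & per lifestyle
    lytic_temperate_ratio: pd.Series  # per-sample abundance ratio
    excluded: int = 0  # pair-samples dropped for zero host abundance


def linkage_stats(
    links: list[VirusHostLink],
    virus_abundance: pd.DataFrame,
    host_abundance: pd.DataFrame,
    lifestyles: dict[str, str] | None = None,
) -> LinkageStatsReport:
    """Per-pair-per-sample VHR plus host/virus abundance correlations.

    VHR = viral RPKM / host RPKM for samples where the host is present;
    zero-host pair-samples are excluded and tallied. Correlations are
    Spearman over pair-sample observations: host vs virus abundance and host
    abundance vs VHR, overall and within each lifestyle class.
    """
    lifestyles = lifestyles or {}
    common = [s for s in virus_abundance.columns if s in host_abundance.columns]
    rows = []
    excluded = 0
    for link in links:
        if link.virus not in virus_abundance.index or link.host not in host_abundance.index:
            continue
        for s in common:
            v = float(virus_abundance.loc[link.virus, s])
            h = float(host_abundance.loc[link.host, s])
            if h <= 0:
                excluded += 1
                continue
            rows.append({
                "virus": link.virus, "host": link.host, "sample": s,
                "virus_rpkm": v, "host_rpkm": h, "vhr": v / h,
                "lifestyle": lifestyles.get(link.virus, "unknown"),
            })
    vhr = pd.DataFrame(rows, columns=["virus", "host", "sample", "virus_rpkm",
                                      "host_rpkm", "vhr", "lifestyle"])

    def corr(sub: pd.DataFrame, a: str, b: str, label: str):
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            return {"comparison": label, "rho": float("nan"),
                    "p": float("nan"), "n": len(sub)}
        rho, p = spearmanr(sub[a], sub[b])
        return {"comparison": label, "rho": float(rho), "p": float(p), "n": len(sub)}

    recs = [
        corr(vhr, "host_rpkm", "virus_rpkm", "host_vs_virus"),
        corr(vhr, "host_rpkm", "vhr", "host_vs_vhr"),
    ]
    for ls, sub in vhr.groupby("lifestyle"):
        recs.append(corr(sub, "host_rpkm", "virus_rpkm", f"host_vs_virus[{ls}]"))
        recs.append(corr(sub, "host_rpkm", "vhr", f"host_vs_vhr[{ls}]"))
    correlations = pd.DataFrame(recs)

    lt = pd.Series(dtype=float)
    if lifestyles:
        lytic = [v for v, l in lifestyles.items() if l == "lytic" and v in virus_abundance.index]
        temp = [v for v, l in lifestyles.items() if l == "temperate" and v in virus_abundance.index]
        if lytic and temp:
            num = virus_abundance.loc[lytic].sum(axis=0)
            den = virus_abundance.loc[temp].sum(axis=0)
            lt = num / den.replace(0, np.nan)
    return LinkageStatsReport(vhr=vhr, correlations=correlations,
                              lytic_temperate_ratio=lt, excluded=excluded)
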
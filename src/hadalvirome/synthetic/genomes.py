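"""Viral and host genomes with planted virus–host linkage signals.

Backgrounds are order-2 Markov sequences with genome-specific composition.
Four channels can be planted per (virus, host) pair:

* ``homology`` — a ≥1500 bp viral segment copied into the host with
  substitutions at 20% of positions (80% identity, comfortably above the
  70% retention floor); the corresponding alignment-hit row is emitted from
  the planting bookkeeping, since alignment engines are upstream of this
  pipeline. Decoy hit rows failing exactly one threshold each are added for
  negative coverage.
* ``trna`` — one identical 75-nt tRNA-like sequence inserted into both
  genomes and listed in both tRNA sets.
* ``crispr`` — a 25–40 nt spacer copied from the virus into the host's
  spacer set, exactly or with exactly one planted mismatch (alternating by
  planting order).
* ``onf`` — the viral genome is emitted from the host's own Markov model,
  so the d2* compositional distance is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..virus_host import HIT_COLUMNS, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

HOST_LEN = 12_000
VIRUS_LEN = 6_000
HOMOLOGY_VIRUS_LEN = 2_400
HOMOLOGY_SEGMENT = 2_000
HOMOLOGY_MUT_FRACTION = 0.20
TRNA_LEN = 75
PHYLA = (
    "Pseudomonadota", "Bacteroidota", "Chloroflexota", "Planctomycetota",
    "Thermoproteota", "Actinomycetota", "Acidobacteriota", "Nanoarchaeota",
)

__all__ = ["VirusHostFixture", "generate_virus_host_genomes", "default_planting"]


@dataclass
class VirusHostFixture:
    viruses: dict[str, str]
    hosts: dict[str, str]
    spacers: dict[tuple[str, str], str]  # (spacer_id, host_id) -> sequence
    viral_trnas: dict[tuple[str, str], str]  # (trna_id, virus_id) -> sequence
    host_trnas: dict[tuple[str, str], str]
    hits: pd.DataFrame  # BLAST-like rows incl. qlen; planted + decoys
    taxonomy: dict[str, str]  # host -> phylum
    truth: list[dict] = field(default_factory=list)  # virus, host, channel


def _markov_model(rng: np.random.Generator, order: int = 2,
                  concentration: float = 0.6) -> np.ndarray:
    """Random order-``order`` transition matrix, rows Dirichlet-distributed.

    Low concentration gives each genome a distinctive composition, which
    keeps unrelated virus-host d2* pairs well above the 0.2 threshold.
    """
    return rng.dirichlet(np.full(4, concentration), size=4**order)


def _markov_sequence(rng: np.random.Generator, model: np.ndarray, length: int,
                     order: int = 2) -> str:
    seq = np.empty(length, dtype=np.uint8)
    ctx = 0
    seq[:order] = BASES[rng.integers(0, 4, size=order)]
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    ctx = 0
    for i in range(order):
        ctx = ctx * 4 + lut[int(seq[i])]
    # cumulative transition rows let one uniform draw pick the next base
    cum = model.cumsum(axis=1)
    u = rng.random(length)
    for i in range(order, length):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        seq[i] = BASES[b]
        ctx = (ctx * 4 + b) % (4**order)
    return seq.tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> tuple[str, int]:
    """Substitute a uniform ``fraction`` of positions; gap-free."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    k = int(round(fraction * len(arr)))
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode(), k


def default_planting(n_viruses: int, n_hosts: int) -> list[tuple[int, int, str]]:
    """Two planted pairs per channel, distinct viruses, cycling hosts."""
    channels = ["homology", "trna", "crispr", "onf"]
    plan = []
    v = 0
    for ch in channels:
        for _ in range(2):
            if v >= n_viruses:
                return plan
            plan.append((v, v % n_hosts, ch))
            v += 1
    return plan


def generate_virus_host_genomes(
    seed: int,
    n_viruses: int = 20,
    n_hosts: int = 10,
    planted: list[tuple[int, int, str]] | None = None,
) -> VirusHostFixture:
    """Generate genomes, spacer/tRNA sets, hit rows and linkage truth.

    ``planted`` lists (virus index, host index, channel) triples; defaults
    to :func:`default_planting`. Unplanted pairs carry no signal and are
    absent from the truth list.
    """
    if n_viruses < 1 or n_hosts < 1:
        raise ValueError("need at least one virus and one host")
    planted = default_planting(n_viruses, n_hosts) if planted is None else planted
    for v, h, ch in planted:
        if not (0 <= v < n_viruses and 0 <= h < n_hosts):
            raise ValueError(f"planted pair ({v}, {h}) out of range")
        if ch not in {"homology", "trna", "crispr", "onf"}:
            raise ValueError(f"unknown channel {ch!r}")

    root = np.random.SeedSequence(seed)
    s_hosts, s_viruses, s_plant = root.spawn(3)
    rng_h = np.random.default_rng(s_hosts)
    rng_v = np.random.default_rng(s_viruses)
    rng_p = np.random.default_rng(s_plant)

    host_ids = [f"MAG_{i + 1:03d}" for i in range(n_hosts)]
    virus_ids = [f"vOTU_{i + 1:04d}" for i in range(n_viruses)]
    host_models = {h: _markov_model(rng_h) for h in host_ids}
    hosts = {h: _markov_sequence(rng_h, host_models[h], HOST_LEN) for h in host_ids}
    taxonomy = {h: PHYLA[i % len(PHYLA)] for i, h in enumerate(host_ids)}

    by_virus: dict[int, list[tuple[int, str]]] = {}
    for v, h, ch in planted:
        by_virus.setdefault(v, []).append((h, ch))

    viruses: dict[str, str] = {}
    for i, vid in enumerate(virus_ids):
        chans = {ch for _, ch in by_virus.get(i, [])}
        if "onf" in chans:
            host_idx = next(h for h, ch in by_virus[i] if ch == "onf")
            model = host_models[host_ids[host_idx]]
            viruses[vid] = _markov_sequence(rng_v, model, VIRUS_LEN)
        elif "homology" in chans:
            viruses[vid] = _markov_sequence(rng_v, _markov_model(rng_v),
                                            HOMOLOGY_VIRUS_LEN)
        else:
            viruses[vid] = _markov_sequence(rng_v, _markov_model(rng_v), VIRUS_LEN)

    spacers: dict[tuple[str, str], str] = {}
    viral_trnas: dict[tuple[str, str], str] = {}
    host_trnas: dict[tuple[str, str], str] = {}
    hit_rows: list[dict] = []
    truth: list[dict] = []

    for k, (v, h, ch) in enumerate(planted):
        vid, hid = virus_ids[v], host_ids[h]
        vseq, hseq = viruses[vid], hosts[hid]
        if ch == "homology":
            start = int(rng_p.integers(0, len(vseq) - HOMOLOGY_SEGMENT + 1))
            segment = vseq[start:start + HOMOLOGY_SEGMENT]
            mutated, n_mut = _mutate(rng_p, segment, HOMOLOGY_MUT_FRACTION)
            ins = int(rng_p.integers(0, len(hseq) - len(mutated) + 1))
            hosts[hid] = hseq[:ins] + mutated + hseq[ins + len(mutated):]
            ident = 100.0 * (1 - n_mut / HOMOLOGY_SEGMENT)
            matches = HOMOLOGY_SEGMENT - n_mut
            hit_rows.append({
                "qseqid": vid, "sseqid": hid, "pident": round(ident, 2),
                "length": HOMOLOGY_SEGMENT, "mismatch": n_mut, "gapopen": 0,
                "qstart": start + 1, "qend": start + HOMOLOGY_SEGMENT,
                "sstart": ins + 1, "send": ins + HOMOLOGY_SEGMENT,
                "evalue": 1e-100, "bitscore": float(2 * matches - 3 * n_mut),
                "qlen": len(vseq),
            })
        elif ch == "trna":
            t = _markov_sequence(rng_p, _markov_model(rng_p), TRNA_LEN)
            pos_v = int(rng_p.integers(0, len(vseq) - TRNA_LEN))
            pos_h = int(rng_p.integers(0, len(hosts[hid]) - TRNA_LEN))
            viruses[vid] = vseq[:pos_v] + t + vseq[pos_v + TRNA_LEN:]
            hosts[hid] = hosts[hid][:pos_h] + t + hosts[hid][pos_h + TRNA_LEN:]
            viral_trnas[(f"trna_v{k}", vid)] = t
            host_trnas[(f"trna_h{k}", hid)] = t
        elif ch == "crispr":
            length = int(rng_p.integers(25, 41))
            pos = int(rng_p.integers(0, len(vseq) - length))
            spacer = vseq[pos:pos + length]
            mismatches = k % 2  # alternate exact / one-mismatch plantings
            if mismatches:
                arr = np.frombuffer(spacer.encode(), dtype=np.uint8).copy()
                p = int(rng_p.integers(0, length))
                arr[p] = rng_p.choice(BASES[BASES != arr[p]])
                spacer = arr.tobytes().decode()
            spacers[(f"spacer_{k}", hid)] = spacer
        # onf planting happened at virus construction time
        truth.append({"virus": vid, "host": hid, "channel": ch})

    # decoy hits: each fails exactly one homology threshold
    decoy_virus = virus_ids[-1]
    decoy_host = host_ids[-1]
    qlen = len(viruses[decoy_virus])
    base = {
        "qseqid": decoy_virus, "sseqid": decoy_host, "pident": 85.0,
        "length": 2000, "mismatch": 300, "gapopen": 0, "qstart": 1,
        "qend": 2000, "sstart": 1, "send": 2000, "evalue": 1e-50,
        "bitscore": 1000.0, "qlen": max(qlen, 2200),
    }
    for fail in ({"pident": 69.0}, {"length": 1400, "qend": 1400, "send": 1400},
                 {"bitscore": 40.0}, {"evalue": 0.01},
                 {"qlen": 6000}):  # coverage 2000/6000 < 0.75
        row = dict(base)
        row.update(fail)
        hit_rows.append(row)

    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)
    return VirusHostFixture(
        viruses=viruses, hosts=hosts, spacers=spacers,
        viral_trnas=viral_trnas, host_trnas=host_trnas, hits=hits,
        taxonomy=taxonomy, truth=truth,
    )
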
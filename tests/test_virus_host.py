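"""Evidence channels, the d2* statistic, and integration rules."""

import itertools
import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from hadalvirome import virus_host as vh
from hadalvirome.virus_host import EvidenceRecord


def make_hit(**kw):
    row = {"qseqid": "v1", "sseqid": "h1", "pident": 71.0, "length": 2000,
           "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": 2000,
           "sstart": 1, "send": 2000, "evalue": 1e-10, "bitscore": 60.0,
           "qlen": 2500}
    row.update(kw)
    return row


class TestFilterHomology:
    def test_all_thresholds_met_retained(self):
        hits = pd.DataFrame([make_hit()])
        assert len(vh.filter_homology(hits)) == 1

    @pytest.mark.parametrize("bad", [
        {"pident": 69.0},
        {"length": 1400},
        {"bitscore": 49.0},
        {"evalue": 0.01},
        {"qlen": 3000},  # coverage 2000/3000 < 0.75
    ])
    def test_each_threshold_rejects_alone(self, bad):
        hits = pd.DataFrame([make_hit(**bad)])
        assert vh.filter_homology(hits) == []

    def test_malformed_row_skipped_not_fatal(self):
        hits = pd.DataFrame([make_hit(pident="not-a-number"), make_hit()])
        assert len(vh.filter_homology(hits)) == 1


class TestMatchTrna:
    T = "ACGT" * 18 + "ACG"  # 75 nt

    def test_identical_sequence_matches(self):
        ev = vh.match_trna({("t1", "v1"): self.T}, {("t2", "h1"): self.T})
        assert [(e.virus, e.host) for e in ev] == [("v1", "h1")]

    def test_single_substitution_breaks_match(self):
        other = "T" + self.T[1:]
        assert vh.match_trna({("t1", "v1"): self.T}, {("t2", "h1"): other}) == []

    def test_reverse_complement_matches(self):
        ev = vh.match_trna({("t1", "v1"): vh.revcomp(self.T)},
                           {("t2", "h1"): self.T})
        assert len(ev) == 1


def oracle_spacer_match(spacer: str, genome: str) -> bool:
    """Independent oracle: enumerate all <=1-substitution variants of the
    spacer and search both genome strands by substring lookup, applying the
    identity floor jointly."""
    L = len(spacer)
    strands = (genome, vh.revcomp(genome))

    def found(pattern):
        return any(pattern in s for s in strands)

    if found(spacer):
        return True
    if (L - 1) / L < 0.95:  # one mismatch would break the identity floor
        return False
    for i, ref in enumerate(spacer):
        for b in "ACGT":
            if b != ref and found(spacer[:i] + b + spacer[i + 1:]):
                return True
    return False


class TestMatchSpacers:
    def test_exact_and_one_mismatch_thresholds(self):
        rng = np.random.default_rng(1)
        genome = "".join(rng.choice(list("ACGT"), 3000))
        spacer30 = genome[100:130]
        mm30 = "A" + spacer30[1:] if spacer30[0] != "A" else "C" + spacer30[1:]
        ev = vh.match_spacers({("s1", "hA"): spacer30, ("s2", "hB"): mm30},
                              {"v1": genome})
        assert {(e.host) for e in ev} == {"hA", "hB"}

    def test_short_spacer_identity_floor_wins(self):
        # 19 nt with 1 mismatch: 18/19 = 94.7% < 95% -> no match
        rng = np.random.default_rng(2)
        genome = "".join(rng.choice(list("ACGT"), 2000))
        s19 = genome[50:69]
        mm19 = ("A" if s19[0] != "A" else "C") + s19[1:]
        ev = vh.match_spacers({("s1", "h1"): mm19}, {"v1": genome})
        assert ev == []
        # but the exact 19-mer still matches
        ev2 = vh.match_spacers({("s1", "h1"): s19}, {"v1": genome})
        assert len(ev2) == 1

    def test_non_acgt_spacer_skipped(self):
        ev = vh.match_spacers({("s1", "h1"): "ACGTN" * 6}, {"v1": "ACGT" * 100})
        assert ev == []

    def test_matches_variant_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            genome = "".join(rng.choice(list("ACGT"), 5000))
            # half the spacers are genome-derived (with 0-2 injected
            # substitutions), half are random
            L = int(rng.integers(20, 41))
            if rep % 2 == 0:
                start = int(rng.integers(0, 5000 - L))
                spacer = list(genome[start:start + L])
                for _ in range(int(rng.integers(0, 3))):
                    p = int(rng.integers(0, L))
                    spacer[p] = rng.choice([b for b in "ACGT" if b != spacer[p]])
                spacer = "".join(spacer)
            else:
                spacer = "".join(rng.choice(list("ACGT"), L))
            got = bool(vh.match_spacers({("s", "h"): spacer}, {"v": genome}))
            assert got == oracle_spacer_match(spacer, genome)


def oracle_d2star(x: str, y: str, k: int, order: int) -> float:
    """Independent direct-formula transcription of d2* using dictionaries."""
    def counts(seq, m):
        c = {}
        for s in (seq, vh.revcomp(seq)):
            for i in range(len(s) - m + 1):
                w = s[i:i + m]
                c[w] = c.get(w, 0) + 1
        return c

    def expected(seq):
        km = counts(seq, k)
        ctx = counts(seq, order)
        ext = counts(seq, order + 1)
        total = sum(km.values())
        nctx = sum(ctx.values())
        exp = {}
        for word in ("".join(p) for p in itertools.product("ACGT", repeat=k)):
            pr = ctx.get(word[:order], 0) / nctx
            for i in range(order, k):
                w = word[i - order:i]
                denom = sum(ext.get(w + b, 0) for b in "ACGT")
                pr *= (ext.get(w + word[i], 0) / denom) if denom else 0.0
            exp[word] = pr * total
        return km, exp

    ox, ex = expected(x)
    oy, ey = expected(y)
    num = sx = sy = 0.0
    for w in ex:
        if ex[w] > 0 and ey[w] > 0:
            cx = ox.get(w, 0) - ex[w]
            cy = oy.get(w, 0) - ey[w]
            num += cx * cy / math.sqrt(ex[w] * ey[w])
            sx += cx * cx / ex[w]
            sy += cy * cy / ey[w]
    return 0.5 * (1 - num / (math.sqrt(sx) * math.sqrt(sy)))


class TestD2Star:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(4)
        s = "".join(rng.choice(list("ACGT"), 2000))
        assert vh.d2star(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), 2000))
        b = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=2000))
        d1, d2 = vh.d2star(a, b), vh.d2star(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(6)
        a = "".join(rng.choice(list("ACGT"), 2000))
        b = "".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=2000))
        got = vh.d2star(a, b, k=3, markov_order=1)
        want = oracle_d2star(a, b, k=3, order=1)
        assert got == pytest.approx(want, abs=1e-10)

    def test_rejects_short_sequences(self):
        with pytest.raises(ValueError, match="floor"):
            vh.d2star("ACGT" * 10, "ACGT" * 200)

    def test_same_composition_closer_than_foreign(self, vh_fixture):
        # a virus emitted from its host's Markov model sits closer to that
        # host than to hosts with foreign composition
        onf = [t for t in vh_fixture.truth if t["channel"] == "onf"]
        for t in onf:
            v = vh_fixture.viruses[t["virus"]]
            own = vh.d2star(v, vh_fixture.hosts[t["host"]])
            others = [vh.d2star(v, s) for h, s in vh_fixture.hosts.items()
                      if h != t["host"]]
            assert own < min(others)


class TestPlantedHomologyAlignmentOracle:
    def test_blastn_confirms_all_five_thresholds(self, vh_fixture, tmp_path):
        t = next(x for x in vh_fixture.truth if x["channel"] == "homology")
        q = tmp_path / "v.fa"
        s = tmp_path / "h.fa"
        q.write_text(f">{t['virus']}\n{vh_fixture.viruses[t['virus']]}\n")
        s.write_text(f">{t['host']}\n{vh_fixture.hosts[t['host']]}\n")
        out = subprocess.run(
            ["blastn", "-query", str(q), "-subject", str(s), "-task", "blastn",
             "-dust", "no", "-outfmt", "6 pident length bitscore evalue qlen"],
            capture_output=True, text=True, check=True).stdout
        rows = [line.split("\t") for line in out.strip().splitlines()]
        best = max(rows, key=lambda r: float(r[2]))
        pident, length, bits, evalue, qlen = map(float, best)
        assert pident >= 70 and length >= 1500 and bits >= 50
        assert evalue <= 1e-3 and length / qlen >= 0.75


class TestIntegrate:
    TAX = {"hA": "P1", "hB": "P2", "hC": "P1"}

    def test_multi_method_support_wins(self):
        ev = [EvidenceRecord("v", "hA", "homology", 1),
              EvidenceRecord("v", "hA", "trna", 1),
              EvidenceRecord("v", "hB", "onf", 0.1)]
        links = vh.integrate(ev, self.TAX)
        assert [(l.virus, l.host) for l in links] == [("v", "hA")]

    def test_cross_phylum_tie_resolved_by_crispr_trna(self):
        ev = [EvidenceRecord("v", "hA", "homology", 1),
              EvidenceRecord("v", "hB", "crispr", 0)]
        links = vh.integrate(ev, self.TAX)
        assert [(l.virus, l.host) for l in links] == [("v", "hB")]

    def test_cross_phylum_tie_without_crispr_trna_drops_all(self):
        ev = [EvidenceRecord("v", "hA", "homology", 1),
              EvidenceRecord("v", "hB", "onf", 0.1)]
        assert vh.integrate(ev, self.TAX) == []

    def test_same_phylum_tie_keeps_both(self):
        ev = [EvidenceRecord("v", "hA", "homology", 1),
              EvidenceRecord("v", "hC", "onf", 0.1)]
        links = vh.integrate(ev, self.TAX)
        assert {l.host for l in links} == {"hA", "hC"}

    def test_single_candidate_single_method_kept(self):
        ev = [EvidenceRecord("v", "hB", "onf", 0.15)]
        links = vh.integrate(ev, self.TAX)
        assert [(l.virus, l.host, set(l.methods)) for l in links] == \
            [("v", "hB", {"onf"})]

    def test_idempotent_and_order_invariant(self):
        ev = [EvidenceRecord("v1", "hA", "homology", 1),
              EvidenceRecord("v1", "hA", "trna", 1),
              EvidenceRecord("v1", "hB", "onf", 0.1),
              EvidenceRecord("v2", "hB", "crispr", 0),
              EvidenceRecord("v2", "hC", "homology", 2)]
        base = vh.integrate(ev, self.TAX)
        for perm in itertools.permutations(ev):
            got = vh.integrate(list(perm), self.TAX)
            assert [(l.virus, l.host, l.methods) for l in got] == \
                [(l.virus, l.host, l.methods) for l in base]
        again = vh.integrate(ev + ev, self.TAX)
        assert [(l.virus, l.host) for l in again] == [(l.virus, l.host) for l in base]

    def test_unknown_host_taxonomy_raises(self):
        with pytest.raises(ValueError, match="taxonomy"):
            vh.integrate([EvidenceRecord("v", "hZ", "onf", 0.1)], self.TAX)


class TestLinkageStats:
    def test_vhr_arithmetic_and_exclusions(self):
        links = [vh.VirusHostLink("v1", "h1", frozenset({"trna"}), "P1")]
        va = pd.DataFrame({"s1": [10.0], "s2": [4.0]}, index=["v1"])
        ha = pd.DataFrame({"s1": [5.0], "s2": [0.0]}, index=["h1"])
        rep = vh.linkage_stats(links, va, ha)
        assert rep.vhr["vhr"].tolist() == [2.0]
        assert rep.excluded == 1

    def test_positive_association_detected(self):
        rng = np.random.default_rng(8)
        n = 100
        host = rng.lognormal(1, 0.5, n)
        virus = 0.5 * host + rng.normal(0, 0.05, n)
        samples = [f"s{i}" for i in range(n)]
        va = pd.DataFrame([virus], index=["v1"], columns=samples)
        ha = pd.DataFrame([host], index=["h1"], columns=samples)
        links = [vh.VirusHostLink("v1", "h1", frozenset({"trna"}), "P1")]
        rep = vh.linkage_stats(links, va, ha)
        row = rep.correlations.set_index("comparison").loc["host_vs_virus"]
        assert row["rho"] > 0 and row["p"] < 0.05

    def test_all_hosts_absent_gives_empty_report(self):
        links = [vh.VirusHostLink("v1", "h1", frozenset({"trna"}), "P1")]
        va = pd.DataFrame({"s1": [10.0]}, index=["v1"])
        ha = pd.DataFrame({"s1": [0.0]}, index=["h1"])
        rep = vh.linkage_stats(links, va, ha)
        assert rep.vhr.empty and rep.excluded == 1
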
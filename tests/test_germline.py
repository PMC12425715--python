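"""Germline annotation: RSS scanning, template search, functionality,
subgroup clustering, and the GFF3 round trip."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from ovig.dna import revcomp, translate
from ovig.germline import (
    HEPTAMER,
    NONAMER,
    annotate_locus,
    assign_subgroups,
    classify_functionality,
    find_rss,
    locate_segments,
    pairwise_identity,
)
from ovig.io import read_germline, write_germline
from ovig.simulate import make_toy_genome
from ovig.types import GeneSegment, RssMatch


def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mm(a, b):
    return sum(x != y or x == "N" for x, y in zip(a, b))


def brute_force_rss(seq, spacer_class, hb, nb, tol):
    """Independent all-offset scan testing every offset, spacer and strand."""
    base = {"RSS12": 12, "RSS23": 23}[spacer_class]
    out = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(L):
            for sp in range(base - tol, base + tol + 1):
                j = i + 7 + sp
                if j + 9 > L:
                    continue
                hm = _mm(s[i : i + 7], HEPTAMER)
                nm = _mm(s[j : j + 9], NONAMER)
                if hm <= hb and nm <= nb:
                    start = i if strand == "+" else L - i - 7
                    out.append((start, sp, strand, hm, nm))
    return sorted(out)


class TestFindRss:
    def test_planted_consensus_plus_strand(self):
        g = HEPTAMER + "A" * 23 + NONAMER
        hits = find_rss(g, "RSS23", 0, 0, 0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.heptamer_start, h.strand, h.spacer_len) == (0, "+", 23)
        assert (h.heptamer_mismatches, h.nonamer_mismatches) == (0, 0)

    def test_planted_consensus_minus_strand(self):
        g = revcomp(HEPTAMER + "A" * 23 + NONAMER)
        hits = find_rss(g, "RSS23", 0, 0, 0)
        assert len(hits) == 1
        assert hits[0].strand == "-"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("spacer_class", ["RSS12", "RSS23"])
    def test_equals_brute_force_on_random_sequence(self, seed, spacer_class):
        rng = np.random.default_rng(seed)
        # plant a few degenerate copies so the scan has work to do
        seq = list(_rand_dna(rng, 10_000))
        base = {"RSS12": 12, "RSS23": 23}[spacer_class]
        for pos in (500, 3000, 7000):
            motif = HEPTAMER + _rand_dna(rng, base) + NONAMER
            motif = list(motif)
            motif[rng.integers(0, 7)] = "ACGT"[rng.integers(0, 4)]
            seq[pos : pos + len(motif)] = motif
        seq = "".join(seq)
        got = [
            (h.heptamer_start, h.spacer_len, h.strand,
             h.heptamer_mismatches, h.nonamer_mismatches)
            for h in find_rss(seq, spacer_class, 1, 2, 1)
        ]
        assert sorted(got) == brute_force_rss(seq, spacer_class, 1, 2, 1)

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(5)
        seq = _rand_dna(rng, 4000)
        fwd = find_rss(seq, "RSS12", 1, 2, 1)
        rev = find_rss(revcomp(seq), "RSS12", 1, 2, 1)
        L = len(seq)

        def key(h):
            return (h.heptamer_start, h.strand, h.spacer_len)

        # a + hit at heptamer_start s maps to a - hit at L - s - 7
        mapped = sorted(
            (L - h.heptamer_start - 7, "-" if h.strand == "+" else "+",
             h.spacer_len)
            for h in fwd
        )
        assert mapped == sorted(key(h) for h in rev)

    def test_empty_and_invalid_input(self):
        assert find_rss("", "RSS12") == []
        with pytest.raises(ValueError):
            find_rss("ACGU", "RSS12")
        with pytest.raises(ValueError):
            find_rss("ACGT", "RSS9")


class TestLocateSegments:
    def test_planted_template_with_rss(self, igh_ref):
        rng = np.random.default_rng(3)
        v = igh_ref.seq("IGHV1")
        genome = (
            _rand_dna(rng, 400) + v + HEPTAMER + _rand_dna(rng, 23) + NONAMER
            + _rand_dna(rng, 400)
        )
        segs = locate_segments(genome, {"IGH|V|tpl": v}, "IGH", "V")
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (400, 400 + len(v))
        assert len(segs[0].rss) == 1 and segs[0].rss[0].spacer_class == "RSS23"

    def test_duplicated_template_yields_two_segments(self, igh_ref):
        rng = np.random.default_rng(4)
        v = igh_ref.seq("IGHV2")
        genome = _rand_dna(rng, 200) + v + _rand_dna(rng, 5000) + v + _rand_dna(rng, 200)
        segs = locate_segments(genome, {"IGH|V|tpl": v}, "IGH", "V")
        starts = sorted(s.start for s in segs)
        assert starts == [200, 200 + len(v) + 5000]
        assert segs[0].end <= segs[1].start

    def test_mutated_template_recovered_near_planting_site(self, igh_ref):
        rng = np.random.default_rng(6)
        v = igh_ref.seq("IGHV3")
        mutated = list(v)
        for pos in rng.choice(len(v), size=len(v) // 10, replace=False):
            mutated[pos] = "ACGT"[rng.integers(0, 4)]
        mutated = "".join(mutated)
        genome = _rand_dna(rng, 300) + mutated + _rand_dna(rng, 300)
        segs = locate_segments(genome, {"IGH|V|tpl": v}, "IGH", "V",
                               min_identity=0.85)
        assert len(segs) == 1
        # sliding-window identity oracle: best gapless placement
        best = max(
            range(len(genome) - len(v) + 1),
            key=lambda i: sum(
                a == b for a, b in zip(genome[i : i + len(v)], v)
            ),
        )
        assert abs(segs[0].start - best) <= 3
        ident = sum(
            a == b
            for a, b in zip(genome[segs[0].start : segs[0].end], v)
        ) / len(v)
        assert 0.85 <= ident <= 1.0

    def test_nonoverlap_within_group(self, igh_ref):
        rng = np.random.default_rng(8)
        v1, v2 = igh_ref.seq("IGHV1"), igh_ref.seq("IGHV2")
        genome = _rand_dna(rng, 100) + v1 + _rand_dna(rng, 600) + v2 + _rand_dna(rng, 100)
        segs = locate_segments(
            genome, {"IGH|V|a": v1, "IGH|V|b": v2}, "IGH", "V"
        )
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start

    def test_template_name_mismatch_is_error(self, igh_ref):
        with pytest.raises(ValueError):
            locate_segments("ACGT" * 100, {"IGK|V|x": "ACGT" * 20}, "IGH", "V")


class TestClassifyFunctionality:
    def _v_segment(self, seq, rss_ok=True):
        rss = [RssMatch(0, 23, "RSS23", "+", 0, 0, "downstream_of_segment")]
        return GeneSegment(
            name="V_test", locus="IGH", seg_type="V", start=0, end=len(seq),
            rss=rss if rss_ok else [],
        )

    def test_intact_v_with_rss_is_functional(self, igh_ref):
        seq = igh_ref.seq("IGHV1")
        seg = self._v_segment(seq)
        assert classify_functionality(seg, seq) == "functional"
        assert seg.cys2_nt == igh_ref.get("IGHV1").cys2_nt

    def test_missing_rss_is_orf(self, igh_ref):
        seq = igh_ref.seq("IGHV1")
        seg = self._v_segment(seq, rss_ok=False)
        assert classify_functionality(seg, seq) == "ORF"

    def test_inframe_stop_is_pseudogene_regardless_of_rss(self, igh_ref):
        seq = igh_ref.seq("IGHV1")
        mid = (len(seq) // 6) * 3
        seq = seq[:mid] + "TAA" + seq[mid + 3 :]
        seg = self._v_segment(seq)
        assert classify_functionality(seg, seq) == "pseudogene"

    def test_frameshift_vs_template_is_pseudogene(self, igh_ref):
        seq = igh_ref.seq("IGHV1")
        seg = self._v_segment(seq)
        assert classify_functionality(seg, seq, template_len=len(seq) + 1) == (
            "pseudogene"
        )

    def test_length_mismatch_is_error(self, igh_ref):
        seq = igh_ref.seq("IGHV1")
        seg = self._v_segment(seq)
        with pytest.raises(ValueError):
            classify_functionality(seg, seq + "A")


class TestSubgroups:
    def _segments(self, seqs):
        segs, seqmap = [], {}
        for i, s in enumerate(seqs):
            segs.append(
                GeneSegment(name=f"V{i}", locus="IGH", seg_type="V",
                            start=i * 1000, end=i * 1000 + len(s))
            )
            seqmap[f"V{i}"] = s
        return segs, seqmap

    def test_identical_sequences_share_subgroup(self):
        segs, seqs = self._segments(["ACGTACGTACGT" * 5] * 2)
        labels = assign_subgroups(segs, seqs, 0.75)
        assert labels["V0"] == labels["V1"]

    def test_dissimilar_sequences_split(self):
        rng = np.random.default_rng(11)
        segs, seqs = self._segments([_rand_dna(rng, 120), _rand_dna(rng, 120)])
        labels = assign_subgroups(segs, seqs, 0.75)
        assert labels["V0"] != labels["V1"]

    def test_matches_graph_component_oracle(self):
        rng = np.random.default_rng(12)
        base = _rand_dna(rng, 150)
        seqs = []
        for _ in range(10):
            s = list(base if rng.random() < 0.5 else _rand_dna(rng, 150))
            for pos in rng.choice(150, size=rng.integers(0, 30), replace=False):
                s[pos] = "ACGT"[rng.integers(0, 4)]
            seqs.append("".join(s))
        segs, seqmap = self._segments(seqs)
        labels = assign_subgroups(segs, seqmap, 0.75)
        g = nx.Graph()
        g.add_nodes_from(seqmap)
        names = list(seqmap)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if pairwise_identity(seqmap[names[i]], seqmap[names[j]]) >= 0.75:
                    g.add_edge(names[i], names[j])
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            assert len({labels[n] for n in comp}) == 1
        # distinct components get distinct labels
        assert len({frozenset(c) for c in nx.connected_components(g)}) == len(
            set(labels.values())
        )


class TestAnnotationRoundTrip:
    def test_planted_genome_recovers_all_segments(self, igh_ref, tmp_path):
        genome = make_toy_genome(igh_ref, seed=21)
        templates = {
            t: {
                f"IGH|{t}|{s.name}": igh_ref.seq(s.name)
                for s in igh_ref.by_type(t)
            }
            for t in "VDJC"
        }
        ann = annotate_locus(genome, templates, "IGH")
        counts = {t: len(ann.by_type(t)) for t in "VDJC"}
        assert counts == {"V": 4, "D": 4, "J": 2, "C": 1}
        # recovered sequences equal the planted ones
        planted = sorted(igh_ref.seq(s.name) for s in igh_ref.segments)
        found = sorted(ann.sequences.values())
        assert found == planted
        # every functional V translates without stops; pseudogenes are
        # flagged for a stated reason
        for s in ann.by_type("V"):
            if s.functionality == "functional":
                assert "*" not in translate(ann.seq(s.name))
        # D segments carry two RSS12, V and J one RSS
        for s in ann.by_type("D"):
            assert len(s.rss) == 2
            assert all(r.spacer_class == "RSS12" for r in s.rss)
        for s in ann.by_type("V") + ann.by_type("J"):
            assert len(s.rss) == 1

    def test_gff3_round_trip_identity(self, igh_ref, tmp_path):
        genome = make_toy_genome(igh_ref, seed=22)
        templates = {
            "V": {
                f"IGH|V|{s.name}": igh_ref.seq(s.name)
                for s in igh_ref.by_type("V")
            },
            "J": {
                f"IGH|J|{s.name}": igh_ref.seq(s.name)
                for s in igh_ref.by_type("J")
            },
        }
        ann = annotate_locus(genome, templates, "IGH")
        write_germline(ann, tmp_path / "ref", seqid="toy")
        back = read_germline(tmp_path / "ref")
        assert back.sequences == ann.sequences
        assert back.segments == ann.segments
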
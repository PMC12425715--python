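"""Junction decomposition, P/N attribution, CDR3 extraction, histograms."""

from __future__ import annotations

import numpy as np
import pytest

from ovig.assign import assign_vdj
from ovig.dna import revcomp
from ovig.junction import (
    Solution,
    canonical_solutions,
    decompose_junction,
    enumerate_decompositions,
    extract_cdr3,
    junction_histograms,
    maximal_p_split,
)
from ovig.stats import fit_geometric_deletion, trunc_geom_pmf
from ovig.types import (
    JunctionDecomposition,
    Read,
    Rearrangement,
    SegmentAlignment,
    SimulationConfig,
)
from ovig.simulate import simulate_repertoire


def _truth_tuple(t):
    return (
        t.d_name, t.v3_del, t.d5_del, t.d3_del, t.j5_del,
        len(t.p1), len(t.n1), len(t.p2), len(t.p3), len(t.n2), len(t.p4),
    )


def _measured_tuple(r, ref):
    j = r.junction
    if r.d_call is not None:
        d5, d3 = j.d5_del, j.d3_del
    else:
        d5 = d3 = 0
    return (
        r.d_call, j.v3_del, d5, d3, j.j5_del,
        len(j.p1), len(j.n1), len(j.p2), len(j.p3), len(j.n2), len(j.p4),
    )


class TestPSplit:
    def test_p_is_revcomp_of_undeleted_end_read_inward(self):
        # germline V ending ...CA, undeleted: hairpin opening yields TG
        p, n, q = maximal_p_split("TGCCC", left_end="GGGTCA", right_start=None)
        assert p == "TG"
        assert n == "CCC" and q == ""

    def test_p_empty_when_end_deleted(self):
        p, n, q = maximal_p_split("TGAAA", left_end=None, right_start=None)
        assert (p, n, q) == ("", "TGAAA", "")

    def test_right_side_p(self):
        # germline J starting TG...: right-side P is CA
        p, n, q = maximal_p_split("AAACA", left_end=None, right_start="TGGCC")
        assert (p, n, q) == ("", "AAA", "CA")

    def test_cap_respected(self):
        left = "ATATATAT"  # long palindromic potential
        gap = revcomp(left)[:6] + "G"
        p, n, q = maximal_p_split(gap, left_end=left, right_start=None, p_cap=4)
        assert len(p) <= 4

    def test_split_matches_exhaustive_oracle(self):
        """Greedy split equals the lexicographically-maximal valid
        (|P_left|, |P_right|) pair over an exhaustive enumeration."""
        rng = np.random.default_rng(33)
        bases = "ACGT"
        for _ in range(300):
            left = "".join(bases[i] for i in rng.integers(0, 4, 10))
            right = "".join(bases[i] for i in rng.integers(0, 4, 10))
            gap = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(0, 9)))
            p, n, q = maximal_p_split(gap, left, right, p_cap=4)
            assert p + n + q == gap
            valid = []
            for k1 in range(0, min(4, len(gap)) + 1):
                if k1 and gap[:k1] != revcomp(left[-k1:]):
                    continue
                rem = gap[k1:]
                for k2 in range(0, min(4, len(rem)) + 1):
                    if k2 and rem[len(rem) - k2 :] != revcomp(right[:k2]):
                        continue
                    valid.append((k1, k2))
            assert (len(p), len(q)) == max(valid)


class TestDecomposition:
    def test_identity_case_all_zero(self, igh_ref):
        cfg = SimulationConfig(
            seed=70, n_reads=10, del_cap_v3=0, del_cap_d5=0, del_cap_d3=0,
            del_cap_j5=0, p_prob=0.0, n_len_max=0, shm_rate=0.0,
            seq_error_rate=0.0,
        )
        reads, truth = simulate_repertoire(cfg, igh_ref)
        for read, t in zip(reads, truth):
            r = assign_vdj(read, igh_ref)
            j = decompose_junction(r, igh_ref)
            assert (j.v3_del, j.d5_del, j.d3_del, j.j5_del) == (0, 0, 0, 0)
            assert j.np1 == "" and j.np2 == ""
            assert j.d_seq == igh_ref.seq(t.d_name)

    def test_truth_recovery_and_class_membership(self, igh_ref, run_shm0):
        """Exact recovery on unambiguous junctions; canonical-class
        membership on ambiguous ones; concatenation invariant always."""
        tr = run_shm0["by_id"]
        cfg = run_shm0["config"]
        d_refs = {s.name: igh_ref.seq(s.name) for s in igh_ref.by_type("D")}
        n_unamb = 0
        for r in run_shm0["rearrangements"]:
            t = tr[r.read_id]
            j = r.junction
            # concatenation invariant
            if not j.flagged_overlap:
                region = r.sequence[r.v_aln.read_end : r.j_aln.read_start]
                assert region == j.p1 + j.n1 + j.p2 + j.d_seq + j.p3 + j.n2 + j.p4
            if t.ambiguous_junction:
                continue
            n_unamb += 1
            assert _measured_tuple(r, igh_ref) == _truth_tuple(t)
        assert n_unamb >= 300

    def test_ambiguous_reads_land_in_canonical_class(self, igh_ref, run_shm0):
        tr = run_shm0["by_id"]
        cfg = run_shm0["config"]
        d_refs = {s.name: igh_ref.seq(s.name) for s in igh_ref.by_type("D")}
        checked = 0
        for r in run_shm0["rearrangements"]:
            t = tr[r.read_id]
            if not t.ambiguous_junction or checked >= 150:
                continue
            v = igh_ref.seq(t.v_name)
            jg = igh_ref.seq(t.j_name)
            g_a = max(0, len(v) - cfg.del_cap_v3 - 4)
            g_b = min(len(jg), cfg.del_cap_j5 + 4)
            r0 = None
            # window from read coordinates: germline V position g_a maps
            # to prefix + g_a because the retained V starts the insert
            prefix = r.v_aln.read_start - r.v_aln.germ_start
            start = prefix + g_a
            end = r.j_aln.read_start - r.j_aln.germ_start + g_b
            window = r.sequence[start:end]
            sols = enumerate_decompositions(
                window, v, g_a, jg, g_b, d_refs,
                cap_v3=cfg.del_cap_v3, cap_d5=cfg.del_cap_d5,
                cap_d3=cfg.del_cap_d3, cap_j5=cfg.del_cap_j5,
                parsimony_only=True,
            )
            canon = canonical_solutions(sols, d_refs)
            got = Solution(*_measured_tuple(r, igh_ref))
            assert got in canon
            checked += 1
        assert checked >= 50

    def test_overlap_reported_as_flag_not_exception(self, igh_ref):
        v = igh_ref.get("IGHV1")
        jseg = igh_ref.get("IGHJ1")
        va = SegmentAlignment("IGHV1", 0, 294, 0, 294, 1, 1.0,
                              blocks=[(0, 294, 0, 294)])
        ja = SegmentAlignment("IGHJ1", 280, 328, 0, 48, 1, 1.0,
                              blocks=[(280, 328, 0, 48)])
        r = Rearrangement(
            read_id="x", locus="IGH", v_call="IGHV1", j_call="IGHJ1",
            v_aln=va, j_aln=ja, sequence="A" * 340,
        )
        j = decompose_junction(r, igh_ref)
        assert j.flagged_overlap


class TestCdr3:
    def test_truth_cdr3_recovered_on_unambiguous(self, igh_ref, run_shm0):
        tr = run_shm0["by_id"]
        n = 0
        for r in run_shm0["rearrangements"]:
            t = tr[r.read_id]
            if t.ambiguous_junction:
                continue
            assert (r.cdr3_nt or "") == t.cdr3_nt
            n += 1
        assert n >= 300

    def test_mod3_for_all_productive(self, run_shm0, run_shm2):
        for run in (run_shm0, run_shm2):
            prods = [
                r for r in run["rearrangements"] if r.productive and r.cdr3_nt
            ]
            assert prods
            assert all(len(r.cdr3_nt) % 3 == 0 for r in prods)

    def test_mutated_anchor_excluded_with_reason(self, igh_ref, run_shm0):
        r = next(
            r for r in run_shm0["rearrangements"]
            if r.productive and r.cdr3_nt
        )
        seg = igh_ref.get(r.v_call)
        from ovig.junction import germ_to_read

        cys2_read = germ_to_read(r.v_aln, seg.cys2_nt)
        seq = r.sequence[:cys2_read] + "TAA" + r.sequence[cys2_read + 3 :]
        r2 = assign_vdj(Read(r.read_id, seq), igh_ref)
        extract_cdr3(r2, igh_ref)
        assert r2.cdr3_nt is None
        assert r2.cdr3_fail_reason == "missing_anchor"


class TestHistograms:
    def _stub(self, sample, cdr3_len, v3=0):
        va = SegmentAlignment("V", 0, 10, 0, 10, 1, 1.0)
        ja = SegmentAlignment("J", 20, 30, 0, 10, 1, 1.0)
        r = Rearrangement(
            read_id="x", locus="IGH", v_call="V", j_call="J",
            v_aln=va, j_aln=ja, sample_id=sample,
            cdr3_nt="A" * cdr3_len,
        )
        r.junction = JunctionDecomposition(v3_del=v3)
        return r

    def test_small_example_arithmetic(self):
        rs = [self._stub("s1", 27), self._stub("s1", 27), self._stub("s1", 30)]
        h = junction_histograms(rs)
        cdr3 = h["cdr3_len"].set_index("value")
        assert cdr3.loc[27, "count"] == 2
        assert cdr3.loc[27, "fraction"] == pytest.approx(2 / 3)
        assert cdr3.loc[30, "fraction"] == pytest.approx(1 / 3)
        summ = h["summary"]
        mean = summ[summ.statistic == "cdr3_len"]["mean"].iloc[0]
        assert mean == pytest.approx(28.0)

    def test_empty_input_yields_empty_tables(self):
        h = junction_histograms([])
        assert all(len(df) == 0 for df in h.values())

    def test_mean_equals_direct_recomputation(self, run_shm0):
        h = junction_histograms(run_shm0["rearrangements"])
        direct = np.mean(
            [len(r.cdr3_nt) for r in run_shm0["rearrangements"] if r.cdr3_nt]
        )
        summ = h["summary"]
        mean = summ[summ.statistic == "cdr3_len"]["mean"].iloc[0]
        assert mean == pytest.approx(direct)

    def test_generator_deletion_draws_follow_law(self, run_shm0):
        """KS-style check of the drawn 3'V-deletion lengths against the
        truncated-geometric generating law."""
        cfg = run_shm0["config"]
        draws = np.array([t.v3_del for t in run_shm0["truth"]])
        pmf = trunc_geom_pmf(cfg.del_p_v3, cfg.del_cap_v3)
        cdf = np.cumsum(pmf)
        emp = np.array(
            [np.mean(draws <= k) for k in range(cfg.del_cap_v3 + 1)]
        )
        assert np.max(np.abs(emp - cdf)) < 0.05

    def test_corrected_deletion_mean_recovery(self, run_shm0):
        cfg = run_shm0["config"]
        vals = [
            r.junction.v3_del
            for r in run_shm0["rearrangements"]
            if not r.junction.flagged_overlap
        ]
        fit = fit_geometric_deletion(vals, cap=cfg.del_cap_v3)
        k = np.arange(cfg.del_cap_v3 + 1)
        law_mean = float((k * trunc_geom_pmf(cfg.del_p_v3, cfg.del_cap_v3)).sum())
        assert abs(fit["mean_hat"] - law_mean) / law_mean < 0.08
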
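"""Two-locus LD statistics and block detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import founderhap as fh
from founderhap.errors import LDError
from founderhap.model import Marker, MarkerPanel
from oracles import r2_indicator_oracle


def snp_panel(n):
    return MarkerPanel(
        tuple(Marker(id=f"m{i}", kind="snp", alleles=frozenset("AC")) for i in range(n))
    )


def haps_from_counts(counts):
    """counts: {(a, b): n} two-locus haplotype table."""
    return [pair for pair, n in counts.items() for _ in range(n)]


class TestPairwiseLD:
    def test_perfect_coupling(self):
        haps = haps_from_counts({("A", "A"): 5, ("C", "C"): 5})
        stats = fh.pairwise_ld(haps, 0, 1)
        assert stats["r2"] == pytest.approx(1.0)
        assert stats["Dprime"] == pytest.approx(1.0)

    def test_equilibrium(self):
        haps = haps_from_counts(
            {("A", "A"): 25, ("A", "C"): 25, ("C", "A"): 25, ("C", "C"): 25}
        )
        stats = fh.pairwise_ld(haps, 0, 1)
        assert stats["D"] == pytest.approx(0.0)
        assert stats["r2"] == pytest.approx(0.0)

    def test_hand_computed_table(self):
        """Counts AB x4, aB x2, ab x2: D = 8/64, r^2 = 1/3, D' = 1."""
        haps = haps_from_counts({("A", "B"): 4, ("a", "B"): 2, ("a", "b"): 2})
        stats = fh.pairwise_ld(haps, 0, 1)
        assert stats["D"] == pytest.approx(0.125)
        assert stats["r2"] == pytest.approx(1 / 3)
        assert stats["Dprime"] == pytest.approx(1.0)

    def test_monomorphic_convention_and_strict(self):
        haps = haps_from_counts({("A", "A"): 3, ("A", "C"): 3})
        stats = fh.pairwise_ld(haps, 0, 1)
        assert (stats["D"], stats["r2"], stats["Dprime"]) == (0.0, 0.0, 0.0)
        with pytest.raises(LDError, match="monomorphic"):
            fh.pairwise_ld(haps, 0, 1, strict=True)

    def test_missing_and_multiallelic_error(self):
        with pytest.raises(LDError, match="MISSING"):
            fh.pairwise_ld([("A", "A"), (None, "C")], 0, 1)
        with pytest.raises(LDError, match="biallelic"):
            fh.pairwise_ld([("A", "A"), ("C", "A"), ("G", "A")], 0, 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_r2_equals_squared_indicator_correlation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        haps = [
            (str(rng.choice(["A", "C"])), str(rng.choice(["A", "C"])))
            for _ in range(n)
        ]
        if len({h[0] for h in haps}) < 2 or len({h[1] for h in haps}) < 2:
            return
        stats = fh.pairwise_ld(haps, 0, 1)
        assert stats["r2"] == pytest.approx(r2_indicator_oracle(haps, 0, 1))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_dprime_is_one_in_complete_ld(self, seed):
        """When at most 3 of the 4 two-locus haplotypes occur, D' = 1."""
        rng = np.random.default_rng(seed)
        combos = [("A", "A"), ("A", "C"), ("C", "A"), ("C", "C")]
        picked = rng.choice(4, size=3, replace=False)
        counts = {combos[i]: int(rng.integers(1, 20)) for i in picked}
        haps = haps_from_counts(counts)
        if len({h[0] for h in haps}) < 2 or len({h[1] for h in haps}) < 2:
            return
        stats = fh.pairwise_ld(haps, 0, 1)
        assert stats["Dprime"] == pytest.approx(1.0)


class TestLDMatrix:
    def test_two_marker_matrix_matches_pairwise(self):
        haps = [("A", "A"), ("A", "C"), ("C", "A"), ("C", "C"), ("A", "A")]
        m = fh.ld_matrix(haps, snp_panel(2))
        stats = fh.pairwise_ld(haps, 0, 1)
        assert m.r2.iloc[0, 1] == pytest.approx(stats["r2"])
        assert m.dprime.iloc[0, 1] == pytest.approx(stats["Dprime"])

    def test_symmetry_random(self):
        rng = np.random.default_rng(0)
        haps = [tuple(rng.choice(["A", "C"], 5)) for _ in range(40)]
        m = fh.ld_matrix(haps, snp_panel(5))
        assert np.allclose(m.r2.values, m.r2.values.T)
        assert np.allclose(m.dprime.values, m.dprime.values.T)

    def test_spectrum_joint_frequency_recount(self, panel16, pop14):
        """Off-diagonal r2 from an IBS-like spectrum matches a brute-force
        recount of two-locus joint frequencies."""
        weights = (45, 20, 12, 8, 6, 4, 3, 2)
        idx = [panel16.index_of(m) for m in pop14.ids]
        haps = []
        for w, (h, _) in zip(weights, fh.ibs_like_spectrum(panel16)):
            haps += [tuple(h[i] for i in idx)] * w
        m = fh.ld_matrix(haps, pop14)
        rng = np.random.default_rng(1)
        for _ in range(10):
            i, j = sorted(rng.choice(len(pop14), 2, replace=False))
            if pop14.ids[i] in m.monomorphic or pop14.ids[j] in m.monomorphic:
                continue
            assert m.r2.iloc[i, j] == pytest.approx(
                r2_indicator_oracle(haps, i, j)
            )

    def test_too_few_markers(self):
        with pytest.raises(LDError, match="at least 2"):
            fh.ld_matrix([("A",)], snp_panel(1))

    def test_monomorphic_flagged_zeroed(self):
        haps = [("A", "A", "A"), ("A", "C", "C"), ("A", "C", "A")]
        m = fh.ld_matrix(haps, snp_panel(3))
        assert m.monomorphic == ("m0",)
        assert m.r2.loc["m0", "m0"] == 0.0


class TestDetectBlocks:
    def _matrix(self, mat, ids=None):
        import pandas as pd

        k = len(mat)
        ids = ids or tuple(f"m{i}" for i in range(k))
        df = pd.DataFrame(np.array(mat, dtype=float), index=ids, columns=ids)
        return fh.LDMatrix(
            marker_ids=tuple(ids), r2=df, dprime=df, d_raw=df,
            p_major=None, monomorphic=(),
        )

    def test_all_pairs_one_single_block(self):
        m = self._matrix(np.ones((5, 5)))
        blocks = fh.detect_blocks(m, "r2", 0.9)
        assert [(b.start, b.end) for b in blocks] == [(0, 4)]

    def test_uncorrelated_first_marker_excluded(self):
        mat = np.ones((4, 4))
        mat[0, 1:] = mat[1:, 0] = 0.0
        blocks = fh.detect_blocks(self._matrix(mat), "r2", 0.9)
        assert [(b.start, b.end) for b in blocks] == [(1, 3)]

    def test_planted_core_recovered(self):
        """A 10-marker perfect-LD core with 2 independent flanking markers on
        each side comes back exactly."""
        rng = np.random.default_rng(2)
        n = 400
        core = rng.integers(0, 2, n)
        cols = [rng.integers(0, 2, n), rng.integers(0, 2, n)]
        cols += [core] * 10
        cols += [rng.integers(0, 2, n), rng.integers(0, 2, n)]
        haps = [tuple("AC"[cols[m][i]] for m in range(14)) for i in range(n)]
        m = fh.ld_matrix(haps, snp_panel(14))
        blocks = fh.detect_blocks(m, "dprime", 0.9)
        assert any((b.start, b.end) == (2, 11) for b in blocks)
        for b in blocks:
            assert not (b.start < 2 <= b.end or b.start <= 11 < b.end)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_blocks_disjoint_and_locally_maximal(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        mat = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                mat[i, j] = mat[j, i] = rng.random()
        m = self._matrix(mat)
        blocks = fh.detect_blocks(m, "r2", 0.5)
        spans = [(b.start, b.end) for b in blocks]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for b in blocks:
            assert all(
                mat[i, j] >= 0.5
                for i in range(b.start, b.end + 1)
                for j in range(i + 1, b.end + 1)
            )
            # not extendable rightwards
            if b.end + 1 < k:
                assert any(
                    mat[i, b.end + 1] < 0.5 for i in range(b.start, b.end + 1)
                )

    def test_threshold_validation(self):
        m = self._matrix(np.ones((3, 3)))
        with pytest.raises(ValueError):
            fh.detect_blocks(m, "r2", 0.0)
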
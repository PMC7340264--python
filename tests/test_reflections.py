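import gemmi
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pairladder as pl
from pairladder.reflections import (
    ReflectionFileError,
    enumerate_unique_indices,
    friedel_reduce,
)


def brute_force_d(cell: pl.UnitCell, hkl) -> float:
    """Independent route: build the reciprocal basis by matrix inversion."""
    m = cell.orthogonalization_matrix  # columns = direct basis vectors
    recip = np.linalg.inv(m)  # rows = reciprocal basis vectors
    s = np.asarray(hkl, dtype=float) @ recip  # scattering vector
    return 1.0 / np.linalg.norm(s)


class TestDSpacing:
    def test_cubic_axis(self, cubic_cell):
        assert cubic_cell.d_spacing((1, 0, 0)) == pytest.approx(10.0)

    def test_cubic_diagonal(self, cubic_cell):
        assert cubic_cell.d_spacing((1, 1, 0)) == pytest.approx(10.0 / np.sqrt(2))

    def test_monoclinic_vs_brute_force(self):
        cell = pl.UnitCell(45.20, 73.10, 52.57, 90.0, 109.25, 90.0)
        d = cell.d_spacing((2, 0, 0))
        assert d == pytest.approx(brute_force_d(cell, (2, 0, 0)), rel=1e-10)

    def test_friedel_symmetric(self, cubic_cell):
        assert cubic_cell.d_spacing((1, 2, 3)) == pytest.approx(
            cubic_cell.d_spacing((-1, -2, -3))
        )

    def test_zero_index_rejected(self, cubic_cell):
        with pytest.raises(ValueError):
            cubic_cell.d_spacing((0, 0, 0))

    def test_random_cells_against_gemmi_and_brute_force(self):
        """Full triclinic formula agrees with two independent routes."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            abc = rng.uniform(5, 80, 3)
            ang = rng.uniform(70, 110, 3)
            try:
                cell = pl.UnitCell(*abc, *ang)
            except ValueError:
                continue  # non-positive-definite draw
            hkl = rng.integers(-8, 9, 3)
            if not hkl.any():
                continue
            d = cell.d_spacing(hkl)
            assert d == pytest.approx(brute_force_d(cell, hkl), rel=1e-10)
            g = gemmi.UnitCell(*abc, *ang)
            assert d == pytest.approx(g.calculate_d(tuple(int(x) for x in hkl)), rel=1e-9)


class TestFriedelReduce:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((1, 2, 3), (1, 2, 3)),
            ((-1, -2, -3), (1, 2, 3)),
            ((0, -1, 2), (0, 1, -2)),
            ((0, 0, -5), (0, 0, 5)),
        ],
    )
    def test_canonical_form(self, raw, expected):
        assert tuple(friedel_reduce(raw)) == expected

    def test_mates_collapse(self):
        rng = np.random.default_rng(1)
        hkl = rng.integers(-10, 11, (200, 3))
        hkl = hkl[hkl.any(axis=1)]
        assert np.array_equal(friedel_reduce(hkl), friedel_reduce(-hkl))


class TestMakeShells:
    def test_explicit_edges_from_cli_example(self):
        sch = pl.make_shells(2.4, edges=[2.3, 2.2, 2.1, 2.0])
        assert sch.n_shells == 4
        assert sch.edges == (2.4, 2.3, 2.2, 2.1, 2.0)

    def test_exact_division(self):
        sch = pl.make_shells(1.5, 1.4, width=0.05)
        assert sch.edges == (1.5, 1.45, 1.4)

    def test_last_shell_truncated(self):
        sch = pl.make_shells(1.52, 1.44, width=0.05)
        assert sch.edges == (1.52, 1.47, 1.44)

    def test_non_monotonic_edges_rejected(self):
        with pytest.raises(ValueError):
            pl.make_shells(2.4, edges=[2.2, 2.3])

    def test_boundary_belongs_to_shell_it_bounds_below(self):
        sch = pl.make_shells(2.4, edges=[2.3, 2.2])
        # d exactly on an interior edge joins the shell whose lower-d
        # boundary it is; the outer edge is inclusive
        assert sch.assign([2.3])[0] == 0
        assert sch.assign([2.2])[0] == 1
        assert sch.assign([2.4])[0] == 0
        assert sch.assign([2.41])[0] == -1
        assert sch.assign([2.19])[0] == -1

    @given(
        d_start=st.floats(1.6, 4.0),
        span=st.floats(0.2, 1.0),
        width=st.floats(0.03, 0.3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shells_partition_range(self, d_start, span, width):
        sch = pl.make_shells(d_start, d_start - span, width=width)
        edges = np.array(sch.edges)
        assert np.all(np.diff(edges) < 0)
        # no gaps/overlaps: every interior point maps to exactly one shell
        rng = np.random.default_rng(0)
        pts = rng.uniform(sch.d_min, sch.d_max, 200)
        ix = sch.assign(pts)
        assert np.all(ix >= 0) and np.all(ix < sch.n_shells)
        lo = edges[ix + 1]
        hi = edges[ix]
        ok = (pts >= lo) & (pts < hi) | (pts == sch.d_max)
        assert ok.all()


class TestMergedIO:
    def _toy(self, tmp_path):
        cell = pl.UnitCell(10, 11, 12)
        return pl.MergedSet(
            cell,
            [(1, 0, 0), (0, 1, 0), (1, 1, 1)],
            [10.0, 20.0, 30.0],
            [1.0, 2.0, 3.0],
            [0, 1, 0],
        )

    def test_flag_count_inferred(self, tmp_path):
        p = tmp_path / "m.hkl"
        pl.write_merged(self._toy(tmp_path), p)
        back = pl.read_merged(p)
        assert back.flag_count == 2
        assert back.kind == "F"

    def test_round_trip_bit_exact(self, tmp_path, small_bundle):
        _, merged, _, _ = small_bundle
        p1, p2 = tmp_path / "a.hkl", tmp_path / "b.hkl"
        pl.write_merged(merged, p1)
        back = pl.read_merged(p1)
        pl.write_merged(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(back.hkl, merged.hkl)
        assert back.flag_count == merged.flag_count

    def test_intensity_kind_amplitude_conversion(self, tmp_path):
        p = tmp_path / "i.hkl"
        p.write_text(
            "# CELL 10 10 10 90 90 90\n# KIND I\n"
            "1 0 0 25.0 1 0\n0 1 0 -4.0 1 1\n"
        )
        m = pl.read_merged(p)
        assert m.kind == "I"
        # |Fo| = sqrt(max(I, 0)): negative merged intensities clip to zero
        assert m.amplitudes().tolist() == [5.0, 0.0]

    def test_missing_cell_header(self, tmp_path):
        p = tmp_path / "bad.hkl"
        p.write_text("# KIND F\n1 0 0 10 1 0\n")
        with pytest.raises(ReflectionFileError, match="CELL"):
            pl.read_merged(p)

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "empty.hkl"
        p.write_text("# CELL 10 10 10 90 90 90\n# KIND F\n")
        with pytest.raises(ReflectionFileError, match="no reflections"):
            pl.read_merged(p)

    def test_bad_sigma_reports_line(self, tmp_path):
        p = tmp_path / "sig.hkl"
        p.write_text("# CELL 10 10 10 90 90 90\n1 0 0 10 0 0\n")
        with pytest.raises(ReflectionFileError, match="line 2"):
            pl.read_merged(p)


class TestUnmergedIO:
    def test_toy_file(self, tmp_path):
        p = tmp_path / "u.hkl"
        p.write_text(
            "!FORMAT=XDS_ASCII\n"
            "!UNIT_CELL_CONSTANTS= 10 11 12 90 90 90\n"
            "1 0 0 100.0 5.0\n1 0 0 102.0 5.0\n1 0 0 98.0 5.0\n"
            "0 1 0 50.0 2.0\n0 1 0 55.0 2.0\n0 1 0 45.0 2.0\n"
        )
        u = pl.read_unmerged(p)
        assert len(u) == 6
        assert u.cell.a == 10
        assert len(np.unique(u.unique_keys(), axis=0)) == 2

    def test_cell_from_argument_when_no_header(self, tmp_path):
        p = tmp_path / "u.hkl"
        p.write_text("1 0 0 10 1\n")
        with pytest.raises(ReflectionFileError, match="cell"):
            pl.read_unmerged(p)
        u = pl.read_unmerged(p, cell=pl.UnitCell(9, 9, 9))
        assert u.cell.a == 9

    def test_zero_sigma_dropped_and_counted(self, tmp_path):
        p = tmp_path / "u.hkl"
        p.write_text(
            "!UNIT_CELL_CONSTANTS= 10 10 10 90 90 90\n"
            "1 0 0 10 1\n1 0 0 12 0\n"
        )
        u = pl.read_unmerged(p)
        assert len(u) == 1
        assert u.n_dropped == 1

    def test_negative_intensity_retained(self, tmp_path):
        p = tmp_path / "u.hkl"
        p.write_text("!UNIT_CELL_CONSTANTS= 10 10 10 90 90 90\n1 0 0 -3.5 1\n")
        u = pl.read_unmerged(p)
        assert u.intensity[0] == -3.5


class TestSelectResolution:
    def test_cutoff_above_all(self, cubic_cell):
        m = pl.MergedSet(cubic_cell, [(1, 0, 0)], [1.0], [0.1], [0])
        assert len(m.select_resolution(50.0)) == 0

    def test_cutoff_zero_identity(self, small_bundle):
        _, merged, _, _ = small_bundle
        assert len(merged.select_resolution(0)) == len(merged)

    def test_counting_on_known_d(self, cubic_cell):
        # d values 10, 5, 2 for (1,0,0), (2,0,0), (5,0,0)
        m = pl.MergedSet(
            cubic_cell, [(1, 0, 0), (2, 0, 0), (5, 0, 0)], [1, 1, 1], [1, 1, 1], [0, 0, 0]
        )
        assert len(m.select_resolution(4.0)) == 2
        assert len(m.select_resolution(2.0)) == 3  # inclusive at the boundary

    @given(a=st.floats(1.3, 3.0), b=st.floats(1.3, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_and_monotone(self, small_bundle, a, b):
        """Cutting at B then at A >= B equals cutting at A directly."""
        _, merged, _, _ = small_bundle
        hi, lo = max(a, b), min(a, b)
        once = merged.select_resolution(hi)
        twice = merged.select_resolution(lo).select_resolution(hi)
        assert np.array_equal(once.hkl, twice.hkl)
        again = once.select_resolution(hi)
        assert np.array_equal(once.hkl, again.hkl)


class TestEnumeration:
    def test_counts_match_direct_filter(self, cubic_cell):
        uniq = enumerate_unique_indices(cubic_cell, 2.5)
        d = cubic_cell.d_spacing(uniq)
        assert (d >= 2.5).all()
        # every index canonical and unique
        assert np.array_equal(friedel_reduce(uniq), uniq)
        assert len(np.unique(uniq, axis=0)) == len(uniq)
        # brute-force count over a full box
        grid = np.stack(
            np.meshgrid(*[np.arange(-4, 5)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        grid = grid[grid.any(axis=1)]
        keys = np.unique(friedel_reduce(grid), axis=0)
        n_expected = int((cubic_cell.d_spacing(keys) >= 2.5).sum())
        assert len(uniq) == n_expected
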
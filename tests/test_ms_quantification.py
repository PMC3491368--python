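"""XIC extraction, superposition deconvolution, relative abundances."""

import math

import numpy as np
import pandas as pd
import pytest

from readerscope import ms_quantification as mq
from readerscope.ptm_chemistry import precursor_mz
from readerscope.synthetic_data import (
    _h4_truth_vector,
    h4_spectra_scenario,
    simulate_spectra,
)


def simplex_grid_search(a: np.ndarray, o: np.ndarray, step: float = 0.001):
    """Exhaustive oracle: best mixing direction on the simplex.

    For each grid point x, the optimal template scale is solved in closed
    form, so the search maximizes <Ax,o>^2 / ||Ax||^2.
    """
    k = a.shape[1]
    gram = a.T @ a
    proj = a.T @ o
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if k == 2:
        grid = np.column_stack([ticks, 1.0 - ticks])
    elif k == 3:
        x1, x2 = np.meshgrid(ticks, ticks, indexing="ij")
        keep = x1 + x2 <= 1.0 + 1e-12
        grid = np.column_stack([x1[keep], x2[keep], 1.0 - x1[keep] - x2[keep]])
    else:
        raise ValueError("oracle supports 2-3 members")
    num = (grid @ proj) ** 2
    den = np.einsum("ij,jk,ik->i", grid, gram, grid)
    den[den == 0] = np.inf
    return grid[int(np.argmax(num / den))]


@pytest.fixture
def simple_peaklist():
    scans = [
        mq.Scan(0.0, 1, np.array([500.000, 600.0]), np.array([10.0, 1.0])),
        mq.Scan(1.0, 1, np.array([500.004, 500.0045]), np.array([20.0, 5.0])),
        mq.Scan(2.0, 1, np.array([500.006]), np.array([30.0])),
        mq.Scan(3.0, 1, np.array([]), np.array([])),
    ]
    return mq.PeakList(scans)


class TestXIC:
    def test_ppm_window_acceptance(self, simple_peaklist):
        xic = mq.extract_xic(simple_peaklist, 500.000, 10.0)
        # 10 ppm of 500 = 0.005: peaks at 500.004/500.0045 in, 500.006 out
        assert xic.intensity.tolist() == [10.0, 25.0, 0.0, 0.0]

    def test_empty_ms1_all_zero(self):
        pl = mq.PeakList([mq.Scan(0.0, 1, np.array([]), np.array([]))])
        assert mq.extract_xic(pl, 500.0, 10.0).intensity.tolist() == [0.0]

    def test_bad_tolerance(self, simple_peaklist):
        with pytest.raises(mq.QuantificationError):
            mq.extract_xic(simple_peaklist, 500.0, 0.0)


class TestIntegration:
    def test_trapezoid_example(self):
        xic = mq.XIC(500.0, 10.0, np.array([0.0, 1, 2, 3]), np.array([0.0, 10, 10, 0]))
        assert mq.integrate_peak(xic, (0, 3)) == pytest.approx(20.0)

    def test_all_zero_trace(self):
        xic = mq.XIC(500.0, 10.0, np.arange(4.0), np.zeros(4))
        assert mq.integrate_peak(xic, (0, 3)) == 0.0

    def test_linearity(self):
        rt = np.arange(5.0)
        y = np.array([0.0, 3, 7, 2, 0])
        a1 = mq.integrate_peak(mq.XIC(1, 1, rt, y), (0, 4))
        a2 = mq.integrate_peak(mq.XIC(1, 1, rt, 2 * y), (0, 4))
        assert a2 == pytest.approx(2 * a1)

    def test_empty_window_warns(self):
        xic = mq.XIC(500.0, 10.0, np.arange(4.0), np.ones(4))
        with pytest.warns(UserWarning):
            assert mq.integrate_peak(xic, (10, 11)) == 0.0


class TestChannelPairing:
    @pytest.mark.parametrize(
        "d0,d5,ratio,flag",
        [(1000, 500, 2.0, "ok"), (7, 7, 1.0, "ok"), (5, 0, math.inf, "d5_zero")],
    )
    def test_cases(self, d0, d5, ratio, flag):
        r, f = mq.pair_channels(d0, d5)
        assert r == ratio and f == flag

    def test_both_zero_flagged_missing(self):
        r, f = mq.pair_channels(0, 0)
        assert math.isnan(r) and f == "missing"


def _mixture_spectrum(group, weights, rng=None, noise=0.0):
    mz, inten = [], []
    for frag, w in zip(group.fragments, weights):
        ions = frag.mz_values()
        base = np.full(ions.size, w / ions.size)
        if noise > 0:
            base = base * rng.lognormal(0, noise, ions.size)
        mz.append(ions)
        inten.append(base)
    return np.concatenate(mz), np.concatenate(inten)


class TestDeconvolution:
    def test_two_way_noiseless_exact(self, h4_groups):
        mono = next(g for g in h4_groups if len(g) == 4)
        sub = mono  # use first two members' templates within the full group
        mz, inten = _mixture_spectrum(sub, [0.7, 0.3, 0.0, 0.0])
        res = mq.deconvolve_isobaric(mz, inten, sub)
        assert res.proportions == pytest.approx([0.7, 0.3, 0.0, 0.0], abs=1e-6)

    def test_pure_isomer(self, h4_groups):
        tri = next(
            g for g in h4_groups if len(g) == 4 and g.members[0].n_acetyl == 3
        )
        mz, inten = _mixture_spectrum(tri, [0.0, 0.0, 1.0, 0.0])
        res = mq.deconvolve_isobaric(mz, inten, tri)
        assert res.proportions == pytest.approx([0, 0, 1.0, 0], abs=1e-9)

    def test_scale_invariance(self, h4_groups, rng):
        tri = next(
            g for g in h4_groups if len(g) == 4 and g.members[0].n_acetyl == 3
        )
        mz, inten = _mixture_spectrum(tri, [0.4, 0.3, 0.2, 0.1], rng, noise=0.05)
        p1 = mq.deconvolve_isobaric(mz, inten, tri).proportions
        p2 = mq.deconvolve_isobaric(mz, 137.0 * inten, tri).proportions
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_no_fragments_matched_is_identification_failure(self, h4_groups):
        tri = next(g for g in h4_groups if len(g) == 4)
        with pytest.raises(mq.IdentificationError):
            mq.deconvolve_isobaric(
                np.array([100.0]), np.array([5.0]), tri
            )

    def test_three_way_noisy_recovery_matches_grid_oracle(self, h4_groups, rng):
        """Planted (0.5, 0.3, 0.2) mixtures of triacetyl isomers, 5% noise.

        The NNLS route is cross-checked against the exhaustive simplex grid
        search (step 0.001) on every replicate.
        """
        from readerscope.ms_quantification import _template_matrix
        from readerscope.ptm_chemistry import isobaric_groups

        tri4 = next(
            g for g in h4_groups if len(g) == 4 and g.members[0].n_acetyl == 3
        )
        (tri,) = isobaric_groups(tri4.members[:3])
        row_mz, a = _template_matrix(tri, 20.0)
        errs = []
        for _ in range(20):
            mz, inten = _mixture_spectrum(tri, [0.5, 0.3, 0.2], rng, noise=0.05)
            res = mq.deconvolve_isobaric(mz, inten, tri)
            o = np.zeros(row_mz.size)
            for v, w in zip(mz, inten):
                i = int(np.argmin(np.abs(row_mz - v)))
                o[i] += w
            oracle = simplex_grid_search(a, o, step=0.001)
            assert res.proportions == pytest.approx(oracle, abs=0.005)
            errs.append(np.abs(res.proportions - [0.5, 0.3, 0.2]).mean())
        assert np.mean(errs) <= 0.02


class TestRelativeAbundance:
    def test_two_singleton_forms(self, h4_groups):
        un = next(g for g in h4_groups if g.members[0].n_acetyl == 0)
        tetra = next(g for g in h4_groups if g.members[0].n_acetyl == 4)
        tab = mq.relative_abundance([(un, 300.0), (tetra, 100.0)], [None, None])
        assert sorted(tab["abundance_pct"]) == pytest.approx([25.0, 75.0])

    def test_isobaric_split_plus_distinct(self, h4_groups):
        un = next(g for g in h4_groups if g.members[0].n_acetyl == 0)
        mono = next(
            g for g in h4_groups if len(g) == 4 and g.members[0].n_acetyl == 1
        )
        dec = mq.DeconvolutionResult(
            mono, np.array([0.5, 0.5, 0.0, 0.0]), 0.0, np.zeros(4, bool)
        )
        tab = mq.relative_abundance([(mono, 400.0), (un, 200.0)], [dec, None])
        vals = sorted(v for v in tab["abundance_pct"] if v > 0)
        assert vals == pytest.approx([100 / 3] * 3)

    def test_normalization_and_permutation_invariance(self, h4_groups):
        groups = [g for g in h4_groups if len(g) == 1]
        tab1 = mq.relative_abundance(
            [(g, a) for g, a in zip(groups, [10.0, 30.0])], [None, None]
        )
        tab2 = mq.relative_abundance(
            [(g, a) for g, a in zip(groups[::-1], [30.0, 10.0])], [None, None]
        )
        assert tab1["abundance_pct"].sum() == pytest.approx(100.0)
        m1 = dict(zip(tab1["form"], tab1["abundance_pct"]))
        m2 = dict(zip(tab2["form"], tab2["abundance_pct"]))
        assert m1 == pytest.approx(m2)

    def test_zero_family_dropped_with_warning(self, h4_groups):
        un = next(g for g in h4_groups if g.members[0].n_acetyl == 0)
        with pytest.warns(UserWarning):
            tab = mq.relative_abundance([(un, 0.0)], [None])
        assert tab.empty


class TestDegreeOfAcetylation:
    def _table(self, pct_by_nac):
        rows = []
        for form_i in range(16):
            nac = bin(form_i).count("1")
            rows.append(
                {
                    "form": f"f{form_i}",
                    "n_acetyl": nac,
                    "abundance_pct": pct_by_nac[nac](),
                }
            )
        return pd.DataFrame(rows)

    def test_all_on_tetra(self):
        tab = self._table({k: (lambda: 0.0) for k in range(4)} | {4: lambda: 100.0})
        doa = mq.degree_of_acetylation(tab)
        assert doa["tetra"] == 100.0 and doa.drop("tetra").sum() == 0.0

    def test_uniform_gives_binomial_totals(self):
        tab = self._table({k: (lambda: 6.25) for k in range(5)})
        doa = mq.degree_of_acetylation(tab)
        assert doa.tolist() == pytest.approx([6.25, 25.0, 37.5, 25.0, 6.25])

    def test_totals_sum_to_hundred(self, rng):
        pct = rng.dirichlet(np.ones(16)) * 100
        rows = [
            {"form": f"f{i}", "n_acetyl": bin(i).count("1"), "abundance_pct": p}
            for i, p in enumerate(pct)
        ]
        doa = mq.degree_of_acetylation(pd.DataFrame(rows))
        assert doa.sum() == pytest.approx(100.0)


class TestPeaklistIO:
    def test_tsv_roundtrip(self, tmp_path):
        vec = _h4_truth_vector("input")
        pl, _, _ = simulate_spectra(h4_spectra_scenario(vec, seed=3))
        path = tmp_path / "run.tsv"
        mq.write_peaklist_tsv(pl, path)
        back = mq.read_peaklist_tsv(path)
        assert len(back.scans) == len(pl.scans)
        for a, b in zip(pl.scans, back.scans):
            assert a.ms_level == b.ms_level
            assert b.mz == pytest.approx(a.mz, abs=1e-5)
            assert b.intensity == pytest.approx(a.intensity, rel=1e-3)

    def test_mgf_reading(self, tmp_path):
        from pyteomics import mgf

        spectra = [
            {
                "m/z array": np.array([100.0, 200.0]),
                "intensity array": np.array([1.0, 2.0]),
                "params": {"title": "s1", "pepmass": (750.5, None), "rtinseconds": 33.0},
            }
        ]
        path = tmp_path / "run.mgf"
        mgf.write(spectra, str(path))
        pl = mq.read_peaklist_mgf(path)
        assert len(pl.scans) == 1
        assert pl.scans[0].precursor_mz == pytest.approx(750.5)
        assert pl.scans[0].rt == pytest.approx(33.0)

    def test_unordered_scans_rejected(self):
        scans = [
            mq.Scan(5.0, 1, np.array([]), np.array([])),
            mq.Scan(1.0, 1, np.array([]), np.array([])),
        ]
        with pytest.raises(mq.QuantificationError):
            mq.PeakList(scans)


class TestEndToEnd:
    def test_noiseless_single_form_exact(self):
        forms = {"K5ac-K8ac-K12ac-K16ac": 100.0}
        pl, truth, groups = simulate_spectra(
            h4_spectra_scenario(forms, seed=0, noise_sigma=0.0)
        )
        tab = mq.quantify(pl, [g for g in groups if g.members[0].n_acetyl == 4])
        assert tab["abundance_pct"].iloc[0] == pytest.approx(100.0)

    def test_recovery_within_two_points_at_snr20(self):
        vec = _h4_truth_vector("input")
        for seed in range(3):
            pl, truth, groups = simulate_spectra(
                h4_spectra_scenario(vec, seed=seed, noise_sigma=0.05)
            )
            tab = mq.quantify(pl, groups)
            merged = tab.merge(truth, on="form")
            assert (merged["abundance_pct"] - merged["true_pct"]).abs().max() <= 2.0
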
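import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perfconc as pc
from perfconc.asl import PerfusionWeightedSet
from perfconc.pet import CBFMap


@pytest.fixture(scope="module")
def sd_acq(phantom, sd_params):
    return pc.simulate_asl_sd(phantom, sd_params, n_pairs=16)


@pytest.fixture(scope="module")
def te_acq(phantom, scheme, te_params):
    return pc.simulate_asl_te(phantom, scheme, te_params)


class TestPairwiseSubtract:
    def test_equal_label_control_gives_zero(self, mid_grid, sd_params):
        ph = pc.build_phantom(mid_grid, None, seed=0)
        ph.true_cbf[:] = 0.0
        acq = pc.simulate_asl_sd(ph, sd_params, n_pairs=2)
        pw = pc.pairwise_subtract(acq)
        assert np.all(pw.dm_volumes == 0.0)

    def test_mean_of_identical_pairs_equals_single_pair(self, sd_acq):
        pw = pc.pairwise_subtract(sd_acq)
        single = sd_acq.volumes[..., 0] - sd_acq.volumes[..., 1]
        assert np.allclose(pw.dm_volumes[..., 0], single, atol=1e-15)
        assert pw.effective_plds[0] == sd_acq.params.post_label_delay

    def test_te_acquisition_rejected(self, te_acq):
        with pytest.raises(ValueError):
            pc.pairwise_subtract(te_acq)


class TestHadamardDecode:
    def test_identical_volumes_decode_to_zero(self, phantom, scheme, te_params):
        acq = pc.simulate_asl_te(phantom, scheme, te_params)
        acq.volumes[:] = phantom.m0[..., None]
        pw = pc.hadamard_decode(acq)
        assert np.allclose(pw.dm_volumes, 0.0, atol=1e-12)

    def test_decode_is_linear(self, te_acq, phantom, scheme, te_params):
        a, b = 2.5, -0.7
        other = pc.simulate_asl_te(
            pc.build_phantom(phantom.grid, None, gm_cbf=45.0, wm_cbf=15.0, seed=3),
            scheme, te_params,
        )
        combo = pc.ASLAcquisition(
            grid=te_acq.grid, volumes=a * te_acq.volumes + b * other.volumes,
            m0=te_acq.m0, params=te_params, scheme=scheme,
        )
        lhs = pc.hadamard_decode(combo).dm_volumes
        rhs = a * pc.hadamard_decode(te_acq).dm_volumes + b * pc.hadamard_decode(other).dm_volumes
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_timing_attached_to_decoded_set(self, te_acq, scheme):
        pw = pc.hadamard_decode(te_acq)
        plds, lds = pc.hadamard_timing(scheme)
        assert np.array_equal(pw.effective_plds, plds)
        assert np.array_equal(pw.sub_bolus_lds, lds)


class TestQuantifySdCbf:
    def test_zero_dm_gives_zero_cbf(self, phantom, sd_params):
        pw = PerfusionWeightedSet(
            grid=phantom.grid, dm_volumes=np.zeros(phantom.grid.shape + (1,)),
            effective_plds=[2000.0], sub_bolus_lds=[1800.0],
        )
        m = pc.quantify_sd_cbf(pw, phantom.m0, sd_params)
        assert np.all(m.values == 0.0)

    def test_noiseless_recovery_where_att_below_pld(self, phantom, sd_acq, sd_params):
        """The closed form inverts the simulated signal exactly wherever
        the label has fully arrived (ATT ≤ PLD)."""
        m = pc.quantify_sd_cbf(pc.pairwise_subtract(sd_acq), sd_acq.m0, sd_params)
        sel = phantom.brain_mask & (phantom.true_att <= sd_params.post_label_delay)
        assert sel.any()
        err = np.abs(m.values[sel] / phantom.true_cbf[sel] - 1.0)
        assert err.max() < 0.02

    def test_homogeneity_in_dm_and_m0(self, phantom, sd_acq, sd_params):
        pw = pc.pairwise_subtract(sd_acq)
        m1 = pc.quantify_sd_cbf(pw, phantom.m0, sd_params)
        pw2 = PerfusionWeightedSet(
            grid=pw.grid, dm_volumes=pw.dm_volumes * 2.0,
            effective_plds=pw.effective_plds, sub_bolus_lds=pw.sub_bolus_lds,
        )
        m2 = pc.quantify_sd_cbf(pw2, phantom.m0 * 2.0, sd_params)
        assert np.allclose(m1.values, m2.values, rtol=1e-12)


class TestFitTeCbfAtt:
    def test_noiseless_recovery_f50_att1200(self, mid_grid, scheme, te_params):
        ph = pc.build_phantom(
            mid_grid, None, gm_cbf=50.0, wm_cbf=25.0, att_range=(1200.0, 1200.0), seed=0
        )
        ph.true_att[ph.brain_mask] = 1200.0
        acq = pc.simulate_asl_te(ph, scheme, te_params)
        cbf, att = pc.fit_te_cbf_att(
            pc.hadamard_decode(acq), acq.m0, te_params, mask=ph.brain_mask
        )
        gm = ph.tissue_mask("gm")
        assert np.abs(cbf.values[gm] / 50.0 - 1.0).max() < 0.02
        assert np.abs(att.values[gm] - 1200.0).max() < 50.0

    def test_zero_signal_flags_invalid(self, mid_grid, scheme, te_params):
        ph = pc.build_phantom(mid_grid, None, seed=0)
        ph.true_cbf[:] = 0.0
        acq = pc.simulate_asl_te(ph, scheme, te_params)
        cbf, att = pc.fit_te_cbf_att(pc.hadamard_decode(acq), acq.m0, te_params)
        inside = ph.m0 > 0
        assert np.all(cbf.values[inside] == 0.0)
        assert np.all(att.values[inside] == 200.0)  # lower bound
        assert not cbf.valid[inside].any()

    def test_f_unbiased_across_att_sweep(self, scheme, te_params):
        """Noiseless f recovery within 2% for true ATT from 700 to 1700 ms
        (the identifiable range of the N=8 free-lunch scheme)."""
        atts = np.arange(700.0, 1701.0, 100.0)
        g = pc.VoxelGrid((atts.size, 1, 1), (2.0, 2.0, 2.0))
        f_true, m0v = 50.0, 1.0
        plds, lds = pc.hadamard_timing(scheme)
        dm = np.stack(
            [
                pc.buxton_signal(f_true, atts.reshape(-1, 1, 1), ld + pld, ld, m0v, te_params)
                for pld, ld in zip(plds, lds)
            ],
            axis=-1,
        )
        pw = PerfusionWeightedSet(grid=g, dm_volumes=dm, effective_plds=plds, sub_bolus_lds=lds)
        cbf, att = pc.fit_te_cbf_att(pw, np.full(g.shape, m0v), te_params)
        assert np.abs(cbf.values[:, 0, 0] / f_true - 1.0).max() < 0.02
        assert np.abs(att.values[:, 0, 0] - atts).max() < 50.0

    def test_too_few_sub_boli_rejected(self, phantom, te_params):
        pw = PerfusionWeightedSet(
            grid=phantom.grid, dm_volumes=np.zeros(phantom.grid.shape + (2,)),
            effective_plds=[500.0, 200.0], sub_bolus_lds=[250.0, 250.0],
        )
        with pytest.raises(ValueError):
            pc.fit_te_cbf_att(pw, phantom.m0, te_params)


def test_sd_and_te_quantification_agree_noiseless(mid_grid, scheme, sd_params, te_params):
    """Both routes invert the same kinetic model: on noiseless data with
    ATT below the single-delay PLD they agree within 3%."""
    ph = pc.build_phantom(mid_grid, None, att_range=(800.0, 1600.0), seed=4)
    sd = pc.simulate_asl_sd(ph, sd_params, n_pairs=2)
    m_sd = pc.quantify_sd_cbf(pc.pairwise_subtract(sd), sd.m0, sd_params)
    te = pc.simulate_asl_te(ph, scheme, te_params)
    m_te, _ = pc.fit_te_cbf_att(pc.hadamard_decode(te), te.m0, te_params, mask=ph.brain_mask)
    sel = ph.brain_mask
    assert np.abs(m_te.values[sel] / m_sd.values[sel] - 1.0).max() < 0.03


class TestNormalization:
    def _map(self, phantom, values=None):
        vals = phantom.true_cbf if values is None else values
        return CBFMap(grid=phantom.grid, values=vals.copy(), modality="pet",
                      valid=phantom.brain_mask.copy())

    def test_normalize_sets_brain_mean_exactly(self, phantom):
        m = pc.normalize_to_wb(self._map(phantom), 48.1, phantom.brain_mask)
        assert m.masked_mean(phantom.brain_mask) == pytest.approx(48.1, rel=1e-12)

    def test_normalize_is_idempotent_and_shape_preserving(self, phantom):
        m1 = pc.normalize_to_wb(self._map(phantom), 50.0, phantom.brain_mask)
        m2 = pc.normalize_to_wb(m1, 50.0, phantom.brain_mask)
        assert np.allclose(m1.values, m2.values, rtol=1e-14)
        base = self._map(phantom)
        ratio = m1.values[phantom.brain_mask] / base.values[phantom.brain_mask]
        assert np.allclose(ratio, ratio[0])

    def test_relative_cbf_uniform_map_is_ones(self, phantom):
        vals = np.where(phantom.brain_mask, 37.0, 0.0)
        r = pc.relative_cbf(self._map(phantom, vals), phantom.brain_mask)
        assert np.allclose(r.values[phantom.brain_mask], 1.0)
        assert r.scale == "relative"

    def test_relative_cbf_scale_invariant(self, phantom):
        r1 = pc.relative_cbf(self._map(phantom), phantom.brain_mask)
        scaled = self._map(phantom, phantom.true_cbf * 5.0)
        r2 = pc.relative_cbf(scaled, phantom.brain_mask)
        assert np.allclose(r1.values, r2.values, rtol=1e-12)

    def test_two_reference_regions_differ_by_mean_ratio(self, phantom):
        m = self._map(phantom)
        whole = pc.relative_cbf(m, phantom.brain_mask)
        gm_ref = pc.relative_cbf(m, phantom.tissue_mask("gm"))
        ratio = m.masked_mean(phantom.brain_mask) / m.masked_mean(phantom.tissue_mask("gm"))
        sel = phantom.brain_mask
        assert np.allclose(gm_ref.values[sel] / whole.values[sel], ratio, rtol=1e-12)

    def test_empty_reference_rejected(self, phantom):
        with pytest.raises(ValueError):
            pc.relative_cbf(self._map(phantom), np.zeros(phantom.grid.shape, dtype=bool))
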
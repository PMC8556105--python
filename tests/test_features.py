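"""Feature assembly, sliding windows, scaling."""

import numpy as np
import pytest

from metalsite.curation import ProteinChain
from metalsite.features import (
    CHANNELS,
    FeatureLayout,
    assemble_features,
    extract_windows,
    scale_features,
)
from metalsite.io_formats import (
    PCPTable,
    PSSMProfile,
    ScalarTrack,
    TopologyTrack,
    ValidationError,
)


def _inputs(rng, L=10, n_pcp=553):
    seq = "".join(rng.choice(list("ACDEFGHIKL"), L))
    return dict(
        chain=seq,
        pssm=PSSMProfile("c", rng.integers(-9, 10, (L, 20)), seq),
        pcp_table=PCPTable(
            [f"P{i}" for i in range(n_pcp)],
            [""] * n_pcp,
            rng.normal(size=(n_pcp, 20)),
        ),
        rasa=ScalarTrack("c", "rASA", rng.random(L)),
        zcoord=ScalarTrack("c", "Zcoord", rng.normal(0, 10, L)),
        topo=TopologyTrack("c", tuple(
            rng.choice(["inside", "membrane", "outside"], L))),
    )


class TestAssembly:
    def test_full_channel_set_is_578_columns(self, rng):
        fm = assemble_features(**_inputs(rng))
        assert fm.n_columns == 20 + 553 + 1 + 1 + 3 == 578
        assert fm.channels == CHANNELS

    @pytest.mark.parametrize(
        "channels,width",
        [
            (("PSSM",), 20),
            (("PSSM", "PCP"), 573),
            (("PSSM", "PCP", "rASA"), 574),
            (("PSSM", "PCP", "rASA", "Zcoord"), 575),
            (("rASA", "TOPO"), 4),
        ],
    )
    def test_ablation_subsets_have_summed_widths(self, rng, channels, width):
        fm = assemble_features(**_inputs(rng), channels=channels)
        assert fm.n_columns == width

    def test_pcp_columns_are_table_lookups(self):
        table = PCPTable(["P", "Q"], ["", ""],
                         np.arange(40, dtype=float).reshape(2, 20))
        fm = assemble_features("AC", pcp_table=table, channels=("PCP",))
        # STANDARD_AA order: A is column 0, C column 1
        np.testing.assert_allclose(fm.block[:, 0], [0.0, 1.0])   # property P
        np.testing.assert_allclose(fm.block[:, 1], [20.0, 21.0])  # property Q

    def test_length_mismatch_names_the_channel(self, rng):
        kw = _inputs(rng, L=10, n_pcp=3)
        kw["rasa"] = ScalarTrack("c", "rASA", rng.random(9))
        with pytest.raises(ValidationError, match="rASA"):
            assemble_features(**kw)

    def test_channel_order_is_fixed_regardless_of_request_order(self, rng):
        kw = _inputs(rng, n_pcp=4)
        a = assemble_features(**kw, channels=("TOPO", "PSSM"))
        b = assemble_features(**kw, channels=("PSSM", "TOPO"))
        np.testing.assert_array_equal(a.block, b.block)
        assert a.channels == b.channels == ("PSSM", "TOPO")


class TestWindows:
    def _fm(self, rng, L=5, d=4):
        from metalsite.features import FeatureMatrix

        return FeatureMatrix("c", rng.normal(size=(L, d)),
                             [f"PSSM_{i}" for i in range(d)], ("PSSM",))

    def test_interior_window_rows(self, rng):
        fm = self._fm(rng)
        ws = extract_windows(fm, None, 3)
        np.testing.assert_array_equal(
            ws[2].vector, fm.block[1:4].reshape(-1)
        )

    def test_zero_padding_at_both_termini(self, rng):
        fm = self._fm(rng)
        ws = extract_windows(fm, None, 3)
        first = ws[0].vector.reshape(3, -1)
        last = ws[-1].vector.reshape(3, -1)
        assert np.all(first[0] == 0)
        np.testing.assert_array_equal(first[1:], fm.block[:2])
        assert np.all(last[2] == 0)
        np.testing.assert_array_equal(last[:2], fm.block[-2:])

    def test_repeat_padding_copies_terminal_rows(self, rng):
        fm = self._fm(rng)
        ws = extract_windows(fm, None, 5, padding="repeat")
        first = ws[0].vector.reshape(5, -1)
        np.testing.assert_array_equal(first[0], fm.block[0])
        np.testing.assert_array_equal(first[1], fm.block[0])

    def test_w1_is_identity_on_rows(self, rng):
        fm = self._fm(rng)
        ws = extract_windows(fm, None, 1)
        for i, s in enumerate(ws):
            np.testing.assert_array_equal(s.vector, fm.block[i])

    @pytest.mark.parametrize("w", [1, 3, 9, 17, 31])
    def test_sample_count_equals_chain_length(self, rng, w):
        fm = self._fm(rng, L=8)
        ws = extract_windows(fm, None, w)
        assert len(ws) == 8
        assert all(s.vector.shape == (w * 4,) for s in ws)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            extract_windows(self._fm(rng), None, 4)

    def test_labels_follow_center_residue(self, rng):
        fm = self._fm(rng)
        labels = ["a", "b", "c", "d", "e"]
        ws = extract_windows(fm, labels, 3)
        assert [s.label for s in ws] == labels


class TestScaling:
    def _fms(self, rng, n=3):
        from metalsite.features import FeatureMatrix

        return [
            FeatureMatrix(f"c{i}", rng.normal(2, 5, size=(6, 4)),
                          ["a", "b", "c", "d"], ("PSSM",))
            for i in range(n)
        ]

    def test_round_trip_inversion(self, rng):
        fms = self._fms(rng)
        scaled, _, scaler = scale_features(fms, method="zscore")
        for orig, sc in zip(fms, scaled):
            back = scaler.inverse_transform(sc.block)
            assert np.max(np.abs(back - orig.block)) < 1e-9

    def test_minmax_maps_range_to_unit(self):
        from metalsite.features import FeatureMatrix

        fm = FeatureMatrix("c", np.array([[0.0], [10.0]]), ["x"], ("rASA",))
        scaled, _, _ = scale_features([fm], method="minmax")
        np.testing.assert_allclose(scaled[0].block[:, 0], [0.0, 1.0])

    def test_constant_column_minmax_zero_with_warning(self):
        from metalsite.features import FeatureMatrix

        fm = FeatureMatrix("c", np.full((4, 1), 7.0), ["x"], ("rASA",))
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, _, _ = scale_features([fm], method="minmax")
        np.testing.assert_allclose(scaled[0].block, 0.0)

    def test_constant_column_zscore_passes_through(self):
        from metalsite.features import FeatureMatrix

        fm = FeatureMatrix("c", np.full((4, 1), 7.0), ["x"], ("rASA",))
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, _, _ = scale_features([fm], method="zscore")
        np.testing.assert_allclose(scaled[0].block, 7.0)

    def test_scaler_fitted_on_training_rows_only(self, rng):
        fms = self._fms(rng, n=2)
        shifted = self._fms(np.random.default_rng(99), n=1)
        _, applied, scaler = scale_features(fms, shifted, method="zscore")
        expected = scaler.transform(shifted[0].block)
        np.testing.assert_allclose(applied[0].block, expected)
        assert applied[0].scaling_state == "fitted"


def test_layout_mismatch_diff_is_readable(rng):
    a = FeatureLayout(("PSSM",), (20,), 9, "zero")
    b = FeatureLayout(("PSSM",), (20,), 7, "zero")
    assert "window: 9 != 7" in a.diff(b)
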
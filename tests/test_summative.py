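"""Digestible-fraction arithmetic and the summative TDN equation."""

import math

import numpy as np
import pytest

from feedenergy import (DegradabilityRecord, DndfMethod, FeedComposition,
                        FeedTable, METHOD_ORDER, MissingDegradabilityError,
                        digestible_cp, digestible_fa, digestible_nfc,
                        dndf_from_degradability, dndf_rocha_junior,
                        dndf_surface_law, predict_all, predict_tdn)
from feedenergy.summative import pivot_tdn


class TestDigestibleFractions:
    @pytest.mark.parametrize("cp,adicp,cls,expected", [
        (8.0, 2.6, "forage", 5.416455),        # exp(-1.2*ADICP/CP) form
        (10.3, 3.3, "concentrate", 8.98),      # linear form
        (12.0, 0.0, "forage", 12.0),           # no bound protein
        (12.0, 0.0, "concentrate", 12.0),
    ])
    def test_digestible_cp(self, cp, adicp, cls, expected):
        assert digestible_cp(cp, adicp, cls) == pytest.approx(expected,
                                                              abs=1e-6)

    def test_digestible_cp_zero_cp_is_error(self):
        with pytest.raises(ValueError, match="cp"):
            digestible_cp(0.0, 0.0, "forage")

    @pytest.mark.parametrize("ee,expected", [
        (2.4, 1.4), (1.0, 0.0), (0.8, 0.0),    # clamped, never negative
    ])
    def test_digestible_fa(self, ee, expected):
        assert digestible_fa(ee) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("nfc,fap,expected", [
        (28.2, 1.0, 27.636), (0.0, 1.0, 0.0), (61.0, 1.0, 59.78),
        (50.0, 1.1, 53.9),
    ])
    def test_digestible_nfc(self, nfc, fap, expected):
        assert digestible_nfc(nfc, fap) == pytest.approx(expected,
                                                         abs=1e-9)


class TestDndf:
    def test_surface_law_value(self):
        assert dndf_surface_law(57.3, 5.8, 6.7) == pytest.approx(
            24.979038, abs=1e-6)

    def test_rocha_junior_value(self):
        assert dndf_rocha_junior(77.9, 6.0, 6.6) == pytest.approx(
            38.516451, abs=1e-6)

    @pytest.mark.parametrize("fn,scale", [
        (dndf_surface_law, 0.75), (dndf_rocha_junior, 0.6232)])
    def test_lignin_limits(self, fn, scale):
        assert fn(60.0, 4.0, 0.0) == pytest.approx(scale * 56.0, abs=1e-12)
        assert fn(60.0, 4.0, 56.0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            fn(60.0, 4.0, 57.0)

    @pytest.mark.parametrize("fn", [dndf_surface_law, dndf_rocha_junior])
    def test_strictly_decreasing_in_lignin(self, fn):
        """More lignin always means less digestible fiber."""
        for ndf, ndicp in [(60.0, 4.0), (77.9, 6.0), (30.0, 1.0)]:
            grid = np.linspace(1e-6, (ndf - ndicp) * (1 - 1e-9), 400)
            vals = [fn(ndf, ndicp, L) for L in grid]
            assert all(b < a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("ndfd,ndf,coeff,expected", [
        (60.6, 57.3, 1.0, 34.7238),
        (60.6, 57.3, 0.75, 26.04285),
        (0.0, 57.3, 1.0, 0.0),
    ])
    def test_from_degradability(self, ndfd, ndf, coeff, expected):
        assert dndf_from_degradability(ndfd, ndf, coeff) == pytest.approx(
            expected, abs=1e-9)

    def test_from_degradability_range_check(self):
        with pytest.raises(ValueError):
            dndf_from_degradability(101.0, 50.0)


def make_feed(feed_id="f", feed_class="forage", cp=8.0, ee=1.5, ndf=60.0,
              ndicp=4.0, lignin=5.0, adicp=2.0, ash=6.0, **degr):
    nfc = 100.0 - cp - (ndf - ndicp) - ee - ash
    comp = FeedComposition(feed_id=feed_id, feed_class=feed_class, dm=90.0,
                           cp=cp, ee=ee, ndf=ndf, adf=0.6 * ndf,
                           lignin=lignin, ndicp=ndicp, adicp=adicp,
                           nfc=nfc, ash=ash)
    rec = DegradabilityRecord(feed_id=feed_id, **degr) if degr else None
    return comp, rec


class TestPredictTdn:
    def test_identity_holds(self):
        comp, rec = make_feed(ivndfd_48=50.0)
        p = predict_tdn(comp, rec, DndfMethod.IVdNDF)
        assert p.tdn_1x == pytest.approx(
            p.d_cp + 2.25 * p.d_fa + p.d_nfc + p.d_ndf - 7.0, abs=1e-12)

    def test_near_zero_feed_keeps_only_endogenous_loss(self):
        comp, _ = make_feed(cp=1e-6, ee=0.0, ndf=1e-3, ndicp=0.0,
                            lignin=0.0, adicp=0.0, ash=99.99)
        p = predict_tdn(comp, None, DndfMethod.LSdNDF)
        assert p.tdn_1x == pytest.approx(-7.0, abs=0.02)

    def test_missing_degradability_names_method_and_field(self):
        comp, rec = make_feed(isndfd_48=50.0)
        with pytest.raises(MissingDegradabilityError,
                           match="IVdNDF.*ivndfd_48"):
            predict_tdn(comp, rec, DndfMethod.IVdNDF)
        predict_tdn(comp, rec, DndfMethod.ISdNDF)  # present -> fine

    def test_paper_cells(self, example_table):
        corn = example_table.composition("Discarded corn")
        corn_d = example_table.degradability("Discarded corn")
        assert predict_tdn(corn, corn_d, DndfMethod.LSdNDF).tdn_1x == \
            pytest.approx(57.7, abs=0.1)
        citrus = example_table.composition("Citrus pulp")
        citrus_d = example_table.degradability("Citrus pulp")
        assert predict_tdn(citrus, citrus_d, DndfMethod.IVdNDF).tdn_1x == \
            pytest.approx(84.0, abs=0.1)

    def test_surface_law_consistent_degradability_equivalence(self):
        """Setting IVNDFD to the surface-law-implied value makes the in
        vitro model coincide with the chemistry-only model exactly."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            ndf = rng.uniform(25.0, 78.0)
            ndicp = rng.uniform(0.02, 0.15) * ndf
            lignin = rng.uniform(0.01, 0.95) * (ndf - ndicp)
            comp, _ = make_feed(ndf=ndf, ndicp=ndicp, lignin=lignin,
                                cp=rng.uniform(4.0, 15.0),
                                ee=rng.uniform(0.0, 3.0), ash=5.0,
                                adicp=0.3 * ndicp)
            rec = DegradabilityRecord(
                "f", ivndfd_48=100.0 * dndf_surface_law(ndf, ndicp, lignin)
                / ndf)
            a = predict_tdn(comp, rec, DndfMethod.IVdNDF).tdn_1x
            b = predict_tdn(comp, None, DndfMethod.LSdNDF).tdn_1x
            assert a == pytest.approx(b, abs=1e-9)


class TestPredictAll:
    def test_full_grid_and_ordering(self, example_table,
                                    example_predictions):
        assert len(example_predictions) == 60
        # deterministic ordering: feed row order x fixed method order
        first_five = [p.method for p in example_predictions[:5]]
        assert first_five == list(METHOD_ORDER)
        assert example_predictions[0].feed_id == "Discarded corn"

    def test_unit_vs_three_quarter_coefficient(self, example_predictions):
        by = {(p.feed_id, p.method): p.tdn_1x for p in example_predictions}
        for (fid, m), v in by.items():
            if m is DndfMethod.IVdNDF:
                assert v >= by[(fid, DndfMethod.IVdNDF_075)]

    def test_chemistry_only_methods_ignore_degradability(self,
                                                         example_table):
        stripped = FeedTable([(c, None) for c, _ in example_table])
        want = [DndfMethod.LSdNDF, DndfMethod.RochaJunior]
        a = predict_all(stripped, want)
        b = [p for p in predict_all(example_table, want)]
        assert [p.tdn_1x for p in a] == [p.tdn_1x for p in b]
        assert len(a) == 24

    def test_empty_table_empty_predictions(self):
        assert predict_all(FeedTable([])) == []

    def test_pivot_shape(self, example_predictions):
        wide = pivot_tdn(example_predictions)
        assert wide.shape == (12, 5)
        assert list(wide.columns) == [m.value for m in METHOD_ORDER]
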
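import numpy as np
import pytest

from lamigain.data_model_io import (
    BLANK,
    compute_snr,
    read_trial_table,
    screen_sites,
    write_trial_table,
)
from lamigain.errors import FormatError, IntegrityError, UndefinedStatisticError
from lamigain.synthetic_data import make_ground_truth, simulate_probe

from conftest import make_small_table


def _tables_equal(a, b, rates_only=False):
    assert a.probe_id == b.probe_id
    assert a.site_ids == b.site_ids
    np.testing.assert_allclose(a.relative_depth, b.relative_depth)
    np.testing.assert_allclose(a.directions, b.directions)
    np.testing.assert_array_equal(a.n_trials, b.n_trials)
    np.testing.assert_array_equal(a.rates, b.rates)
    if not rates_only and a.psth is not None:
        np.testing.assert_array_equal(a.psth, b.psth)
        np.testing.assert_allclose(a.time_ms, b.time_ms)


@pytest.mark.parametrize("dialect", ["hdf5", "csv"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_round_trip_identity(tmp_path, dialect, seed):
    """write ∘ read is the identity for rates in both dialects."""
    table = make_small_table(n_sites=3, seed=seed, with_psth=(dialect == "hdf5"))
    path = tmp_path / f"probe.{dialect}"
    write_trial_table(table, path, dialect=dialect)
    back = read_trial_table(path, dialect=dialect)
    _tables_equal(table, back, rates_only=(dialect == "csv"))


def test_hdf5_round_trip_of_generated_probe(tmp_path):
    truth = make_ground_truth({}, seed=5)
    ds = simulate_probe(truth, seed=6)
    path = tmp_path / "probe.h5"
    write_trial_table(ds.table, path)
    back = read_trial_table(path)
    _tables_equal(ds.table, back)
    assert back.rates.shape == (
        back.n_sites,
        back.n_conditions,
        int(back.n_trials.max()),
    )


def test_csv_missing_blank_is_integrity_error(tmp_path):
    table = make_small_table()
    path = tmp_path / "probe.csv"
    write_trial_table(table, path, dialect="csv")
    text = path.read_text()
    kept = [l for l in text.splitlines() if f",{BLANK}," not in l]
    path.write_text("\n".join(kept))
    with pytest.raises(IntegrityError, match="blank"):
        read_trial_table(path, dialect="csv")


def test_csv_duplicate_trial_keys_rejected(tmp_path):
    table = make_small_table()
    path = tmp_path / "probe.csv"
    write_trial_table(table, path, dialect="csv")
    lines = path.read_text().splitlines()
    lines.append(lines[1])
    path.write_text("\n".join(lines))
    with pytest.raises(IntegrityError, match="duplicate"):
        read_trial_table(path, dialect="csv")


def test_csv_missing_column_is_format_error(tmp_path):
    path = tmp_path / "probe.csv"
    path.write_text("probe_id,site_id,condition,trial,rate\np,s0,blank,0,1.0\n")
    with pytest.raises(FormatError, match="relative_depth"):
        read_trial_table(path, dialect="csv")


def test_table_requires_trials_for_every_condition():
    table = make_small_table()
    with pytest.raises(IntegrityError):
        table.n_trials = np.zeros_like(table.n_trials)
        table.validate()


def make_small_table_with_psth(psth3, rates3, time_ms):
    """Build a 1-trial-per-condition table from explicit PSTHs."""
    from lamigain.data_model_io import TrialResponseTable

    n_sites, n_cond, _ = psth3.shape
    return TrialResponseTable(
        probe_id="psth-probe",
        site_ids=[f"s{i}" for i in range(n_sites)],
        relative_depth=np.linspace(0.1, 0.9, n_sites),
        area_label="A17",
        directions=np.arange(n_cond - 1) * (360.0 / (n_cond - 1)),
        rates=rates3,
        n_trials=np.ones(n_cond, dtype=int),
        psth=psth3[:, :, None, :],
        time_ms=time_ms,
    )


class TestSnr:
    time_ms = np.arange(-99.0, 300.0, 2.0)

    def _window_pattern(self, rng):
        # a PSTH varying only inside the analysis window
        p = np.zeros_like(self.time_ms)
        mask = (self.time_ms >= 0) & (self.time_ms <= 200)
        p[mask] = rng.normal(10.0, 2.0, mask.sum())
        return p

    def test_identical_condition_and_blank_gives_snr_one(self):
        rng = np.random.default_rng(0)
        p = self._window_pattern(rng)
        psth = np.tile(p, (1, 7, 1, 1)).reshape(1, 7, len(self.time_ms))
        table = make_small_table_with_psth(
            psth, psth.mean(axis=2, keepdims=True), self.time_ms
        )
        res = compute_snr(table, 0)
        assert res.snr == pytest.approx(1.0)
        assert not res.passes

    def test_snr_exactly_eight_fails_strict_threshold(self):
        rng = np.random.default_rng(1)
        blank = self._window_pattern(rng)
        mask = (self.time_ms >= 0) & (self.time_ms <= 200)
        centered = blank - blank[mask].mean()
        # condition PSTH with exactly 8x the blank window variance
        cond = blank + (np.sqrt(8.0) - 1.0) * np.where(mask, centered, 0.0)
        psth = np.stack([cond] * 6 + [blank])[None]
        table = make_small_table_with_psth(
            psth, psth.mean(axis=2, keepdims=True), self.time_ms
        )
        res = compute_snr(table, 0)
        assert res.snr == pytest.approx(8.0)
        assert not res.passes

    def test_snr_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(2)
        psth = rng.uniform(0.0, 50.0, (1, 7, len(self.time_ms)))
        table = make_small_table_with_psth(
            psth, psth.mean(axis=2, keepdims=True), self.time_ms
        )
        res = compute_snr(table, 0)
        mask = (self.time_ms >= 0) & (self.time_ms <= 200)

        def var2pass(x):
            m = sum(x) / len(x)
            return sum((v - m) ** 2 for v in x) / (len(x) - 1)

        oracle = max(var2pass(psth[0, c, mask]) for c in range(6)) / var2pass(
            psth[0, 6, mask]
        )
        assert res.snr == pytest.approx(oracle, rel=1e-12)

    def test_snr_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        psth = rng.uniform(0.0, 50.0, (1, 7, len(self.time_ms)))
        table = make_small_table_with_psth(
            psth, psth.mean(axis=2, keepdims=True), self.time_ms
        )
        base = compute_snr(table, 0).snr
        shifted = make_small_table_with_psth(
            psth + 13.0, psth.mean(axis=2, keepdims=True) + 13.0, self.time_ms
        )
        scaled = make_small_table_with_psth(
            psth * 3.0, psth.mean(axis=2, keepdims=True) * 3.0, self.time_ms
        )
        assert compute_snr(shifted, 0).snr == pytest.approx(base, rel=1e-12)
        assert compute_snr(scaled, 0).snr == pytest.approx(base, rel=1e-12)

    def test_zero_blank_variance_is_undefined(self):
        rng = np.random.default_rng(4)
        psth = rng.uniform(0.0, 50.0, (1, 7, len(self.time_ms)))
        psth[0, 6] = 5.0  # flat blank
        table = make_small_table_with_psth(
            psth, psth.mean(axis=2, keepdims=True), self.time_ms
        )
        with pytest.raises(UndefinedStatisticError):
            compute_snr(table, 0)


class TestScreening:
    def _three_site_table(self, snr_targets):
        time_ms = np.arange(-99.0, 300.0, 2.0)
        rng = np.random.default_rng(5)
        mask = (time_ms >= 0) & (time_ms <= 200)
        blank = np.zeros_like(time_ms)
        blank[mask] = rng.normal(10.0, 1.0, mask.sum())
        centered = np.where(mask, blank - blank[mask].mean(), 0.0)
        psth = np.empty((len(snr_targets), 7, len(time_ms)))
        for s, target in enumerate(snr_targets):
            cond = blank + (np.sqrt(target) - 1.0) * centered
            psth[s] = np.stack([cond] * 6 + [blank])
        return make_small_table_with_psth(
            psth, psth.mean(axis=2, keepdims=True), time_ms
        )

    def test_strict_threshold_at_eight(self):
        table = self._three_site_table([7.9, 8.0, 8.1])
        survivors = screen_sites(table)
        ids = {p.site_id for p in survivors}
        assert "s0" not in ids  # 7.9 < 8
        assert "s2" in ids  # 8.1 > 8
        # the threshold is strict: a site whose SNR equals the threshold
        # exactly is excluded
        middle = compute_snr(table, 1)
        assert middle.snr == pytest.approx(8.0)
        at_threshold = screen_sites(table, threshold=middle.snr)
        assert "s1" not in {p.site_id for p in at_threshold}

    def test_zero_threshold_keeps_all_defined_sites(self):
        table = self._three_site_table([7.9, 8.0, 8.1])
        assert len(screen_sites(table, threshold=0.0)) == 3

    def test_survivors_sorted_by_depth_and_idempotent(self):
        table = self._three_site_table([20.0, 30.0, 25.0])
        survivors = screen_sites(table)
        depths = [p.relative_depth for p in survivors]
        assert depths == sorted(depths)
        again = screen_sites(table)
        assert [p.site_id for p in again] == [p.site_id for p in survivors]

    def test_planted_unresponsive_site_is_excluded(self):
        truth = make_ground_truth({}, seed=31)
        ds = simulate_probe(truth, seed=32, n_unresponsive_sites=2)
        survivors = screen_sites(ds.table)
        ids = {p.site_id for p in survivors}
        assert len(ids) == ds.table.n_sites - 2
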
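import pytest

from murmuration.records import MurmurationRecord


@pytest.fixture
def make_record():
    """Factory for valid records with per-test field overrides."""

    counter = {"n": 0}

    def _make(**overrides) -> MurmurationRecord:
        counter["n"] += 1
        base = dict(
            record_id=f"T{counter['n']:04d}",
            survey_year=2,
            day_index=60,
            report_lag_days="today",
            flock_size=1200,
            duration_min=20.0,
            end_seen=True,
            ending="roost_en_masse",
            temperature_c=6.0,
        )
        base.update(overrides)
        return MurmurationRecord(**base)

    return _make
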
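import pytest
from hypothesis import settings

from caudawhip.series import VertebraRecord, VertebralSeries

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from caudawhip.synthetic import SyntheticSeriesSpec


def make_series(rows, specimen_id="test", missing=(), **kwargs):
    """Build a series from (position, length, height) tuples."""
    return VertebralSeries(
        specimen_id=specimen_id,
        records=tuple(
            VertebraRecord(position=p, centrum_length_cm=l, total_height_cm=h)
            for p, l, h in rows
        ),
        missing_positions=tuple(missing),
        **kwargs,
    )


@pytest.fixture
def simple_series():
    """Three stout proximal vertebrae: lengths 10, 9, 8; heights 25, 20, 15."""
    return make_series([(1, 10.0, 25.0), (2, 9.0, 20.0), (3, 8.0, 15.0)])


@pytest.fixture
def vienna_like_spec():
    """Synthetic tail shaped like the Vienna Plateosaurus: 43 caudals,
    Ca1 ~25 cm tall, crossing planted at Ca25, total length near 2 m."""
    return SyntheticSeriesSpec(
        n_vertebrae=43,
        ca1_height_cm=25.0,
        ca1_length_cm=6.0,
        height_taper=0.93,
        tp_true=25,
        noise_sd_cm=0.0,
        seed=7,
    )
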
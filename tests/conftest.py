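import numpy as np
import pytest

from fretstab import fret, simulate

#: Acceptor grid used throughout: 0-3.09 µM two-fold dilution series.
GRID = np.asarray(simulate.DEFAULT_ACCEPTOR_GRID)


@pytest.fixture
def crosstalk():
    return fret.CrosstalkModel(delta=0.12, alpha=0.30)


@pytest.fixture
def noiseless_plate():
    """Noise-free simulated titration plate at the default design point."""
    return simulate.simulate_titration_plate(simulate.FretSimConfig())


@pytest.fixture
def noiseless_series(noiseless_plate):
    xt = fret.estimate_crosstalk(
        noiseless_plate.donor_only, noiseless_plate.acceptor_only
    )
    return fret.TitrationSeries.from_readings(noiseless_plate.sample, xt)


def make_reading(well="W1", channel="DD", intensity=100.0, *, sample_id="s",
                 replicate=1, donor_conc=1.0, acceptor_conc=0.5,
                 inhibitor_conc=0.0):
    return fret.ChannelReading(
        sample_id=sample_id,
        well=well,
        replicate=replicate,
        donor_conc=donor_conc,
        acceptor_conc=acceptor_conc,
        inhibitor_conc=inhibitor_conc,
        channel=channel,
        intensity=intensity,
    )


def make_well(well, dd, aa, da, **kw):
    return [
        make_reading(well=well, channel="DD", intensity=dd, **kw),
        make_reading(well=well, channel="AA", intensity=aa, **kw),
        make_reading(well=well, channel="DA", intensity=da, **kw),
    ]
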
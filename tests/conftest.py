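import numpy as np
import pytest

from nirfish.crossval import build_day_groups
from nirfish.labels import SampleLabel, SpectrumSet
from nirfish.preprocess import apply_pretreatment
from nirfish.simulate import preset, simulate_study


def make_spectrum_set(n_days=3, replicates=2, p=10, site="M", term=3, rng=None):
    """Small hand-rolled paired SpectrumSet: random intensities, valid labels."""
    rng = rng or np.random.default_rng(7)
    wl = np.linspace(1000.0, 1000.0 + 10 * (p - 1), p)
    rows, labels, days = [], [], []
    for d in range(1, n_days + 1):
        for fish, group in ((2 * d - 1, "C"), (2 * d, "T")):
            for rep in range(1, replicates + 1):
                rows.append(rng.normal(size=p))
                labels.append(SampleLabel(site, fish, group, term, rep))
                days.append(d)
    return SpectrumSet(wl, np.array(rows), labels, np.array(days))


@pytest.fixture(scope="session")
def strong_study():
    """Strong-effect synthetic study (fixed seed), with ground truth."""
    return simulate_study(preset("strong", seed=1))


@pytest.fixture(scope="session")
def strong_m3(strong_study):
    """Muscle / short-term slice of the strong study: SNV + day-centered, with scheme."""
    spectra, _ = strong_study
    sub = spectra.select(site="M", term_hours=3)
    treated = apply_pretreatment(sub, "snv")
    return treated, build_day_groups(treated, term_hours=3)
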
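import numpy as np
import pytest

from finsomnia.scoring import ScoringParams


@pytest.fixture
def params_strict():
    """Scorer with no interruption tolerance and no smoothing."""
    return ScoringParams(speed_threshold=4.0, smooth_window_s=0.0,
                         min_sleep_s=60.0, min_interrupt_s=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_generic_csv(path, rows, header="time_s,x,y", comments=()):
    lines = [f"# {c}" for c in comments] + [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def generic_csv_factory(tmp_path):
    def factory(rows, name="fish.csv", **kw):
        return make_generic_csv(tmp_path / name, rows, **kw)

    return factory
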
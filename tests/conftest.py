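import warnings

import pytest

from feedenergy import (METHOD_ORDER, load_example_feeds, predict_all)


@pytest.fixture(scope="session")
def example_table():
    return load_example_feeds()


@pytest.fixture(scope="session")
def example_predictions(example_table):
    return predict_all(example_table, METHOD_ORDER)


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
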
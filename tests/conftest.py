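import pytest

import hdmks


@pytest.fixture(scope="session")
def ex1_series():
    return hdmks.solve(hdmks.get_example("ex1"), 3)


@pytest.fixture(scope="session")
def ex2c1_series():
    return hdmks.solve(hdmks.get_example("ex2_case1"), 4)


@pytest.fixture(scope="session")
def ex2c2_series():
    return hdmks.solve(hdmks.get_example("ex2_case2"), 2)


@pytest.fixture(scope="session")
def ex3_series():
    return hdmks.solve(hdmks.get_example("ex3"), 2)


@pytest.fixture(scope="session")
def all_example_series(ex1_series, ex2c1_series, ex2c2_series, ex3_series):
    return {"ex1": ex1_series, "ex2_case1": ex2c1_series,
            "ex2_case2": ex2c2_series, "ex3": ex3_series}
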
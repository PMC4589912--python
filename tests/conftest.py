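import pandas as pd
import pytest

import sepsisbn as s


@pytest.fixture(scope="session")
def paper_like_truth():
    return s.default_truth("paper-like")


@pytest.fixture(scope="session")
def paper_like_cohort(paper_like_truth):
    """Full 12-group cohort at n = 10/group, seed 0."""
    return s.generate_cohort(paper_like_truth, s.enumerate_design(), 10, seed=0)


@pytest.fixture(scope="session")
def bal_table(paper_like_cohort) -> pd.DataFrame:
    return paper_like_cohort["bal"].data


@pytest.fixture(scope="session")
def four_var_strong():
    """Discretized 4-variable table with strong effects (CLP, LungInsult, NE, EO)."""
    tables = s.generate_cohort(s.default_truth("strong"), s.enumerate_design(), 17, seed=7)
    sub = tables["bal"].data[["CLP", "LungInsult", "NE", "EO"]]
    table, _ = s.discretize(sub)
    return table
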
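import numpy as np
import pandas as pd
import pytest

from eirmix.data_prep import Predictor, PredictorSchema, load_long_table


@pytest.fixture(scope="session")
def toy_schema():
    return PredictorSchema((
        Predictor(name="ability", level="person", kind="continuous"),
        Predictor(name="grade", level="person", kind="nominal",
                  categories=("g5", "g6", "g8"), reference="g5"),
        Predictor(name="fmt", level="item", kind="nominal",
                  categories=("mc", "open"), reference="mc"),
        Predictor(name="rt", level="person_by_item", kind="continuous"),
    ))


def build_toy_frame(n_persons=4, n_items=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    ability = rng.standard_normal(n_persons)
    grades = rng.choice(["g5", "g6", "g8"], n_persons)
    fmts = rng.choice(["mc", "open"], n_items)
    for j in range(n_persons):
        for i in range(n_items):
            rows.append({
                "person_id": f"p{j}", "item_id": f"i{i}",
                "response": int(rng.random() < 0.5),
                "ability": ability[j], "grade": grades[j],
                "fmt": fmts[i], "rt": rng.standard_normal(),
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_frame():
    return build_toy_frame()


@pytest.fixture()
def toy_table(toy_frame, toy_schema):
    return load_long_table(toy_frame, toy_schema)


@pytest.fixture(scope="session")
def crossed_sim():
    """Small crossed logistic dataset with known parameters."""
    rng = np.random.default_rng(515)
    J, I = 60, 8
    x_person = np.repeat(rng.standard_normal(J), I)
    x_item = np.tile(rng.standard_normal(I), J)
    pj = np.repeat(np.arange(J), I)
    ii = np.tile(np.arange(I), J)
    theta = rng.normal(0, np.sqrt(0.7), J)
    b = rng.normal(0, np.sqrt(0.7), I)
    eta = 0.3 + 0.8 * x_person - 0.5 * x_item + theta[pj] + b[ii]
    y = (rng.random(J * I) < 1 / (1 + np.exp(-eta))).astype(int)
    X = np.column_stack([np.ones(J * I), x_person, x_item])
    return {"y": y, "X": X, "pj": pj, "ii": ii}
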
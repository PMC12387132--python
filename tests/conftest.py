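import numpy as np
import pandas as pd
import pytest

from readsem import consensus, corr_db


@pytest.fixture(scope="session")
def reference_solution():
    """Printed standardized solution: loadings dict, path matrix, labels."""
    return (
        dict(consensus.REFERENCE_LOADINGS),
        consensus.reference_b_matrix(),
        consensus.CONSTRUCTS,
    )


def write_toy_database(tmp_path, records, classifications, matrices):
    """Write the three CSV schemas from row dictionaries; return paths."""
    rec_path = tmp_path / "records.csv"
    cls_path = tmp_path / "classifications.csv"
    mat_path = tmp_path / "matrices.csv"
    pd.DataFrame(records).to_csv(rec_path, index=False)
    pd.DataFrame(classifications).to_csv(cls_path, index=False)
    pd.DataFrame(matrices).to_csv(mat_path, index=False)
    return rec_path, cls_path, mat_path


@pytest.fixture
def toy_csvs(tmp_path):
    """Three-record valid database spanning two matrices."""
    classifications = [
        {"subtest_id": "Vocab", "battery": "W", "broad": "Gc", "narrow": "VL", "quality": "good"},
        {"subtest_id": "MatRea", "battery": "W", "broad": "Gf", "narrow": "I", "quality": "good"},
        {"subtest_id": "WordID", "battery": "R", "broad": "LD", "narrow": "LD", "quality": "good"},
        {"subtest_id": "WordAtt", "battery": "R", "broad": "PD", "narrow": "PD", "quality": "good"},
        {"subtest_id": "Arith", "battery": "W", "broad": "Gwm", "narrow": "WM", "quality": "poor"},
    ]
    matrices = [
        {"matrix_id": "m1", "battery": "W", "sample_kind": "normative",
         "group_label": "age6", "default_n": 100, "supersedes_matrix_ids": ""},
        {"matrix_id": "m2", "battery": "R", "sample_kind": "concurrent_validity",
         "group_label": "all", "default_n": 50, "supersedes_matrix_ids": ""},
    ]
    records = [
        {"matrix_id": "m1", "subtest_a": "Vocab", "subtest_b": "MatRea",
         "n": 100, "r": 0.5, "same_subtest_cross_version": False},
        {"matrix_id": "m2", "subtest_a": "WordID", "subtest_b": "WordAtt",
         "n": 50, "r": 0.7, "same_subtest_cross_version": False},
        {"matrix_id": "m2", "subtest_a": "Vocab", "subtest_b": "WordID",
         "n": "", "r": 0.4, "same_subtest_cross_version": False},
    ]
    return write_toy_database(tmp_path, records, classifications, matrices)


def make_records(z_values, v_values, clusters, pair=("Gc", "Gf")):
    """Build bucketed CorrelationRecord objects from z, v, cluster arrays.

    v is realized through N = 3 + 1/v (rounded), so tests that need exact
    v should pick v = 1/(N-3) for integer N.
    """
    records = []
    counter = {}
    for z, v, c in zip(z_values, v_values, clusters):
        N = int(round(3 + 1.0 / v))
        counter[c] = counter.get(c, 0) + 1
        records.append(
            corr_db.CorrelationRecord(
                matrix_id=str(c),
                subtest_a=f"a{c}_{counter[c]}",
                subtest_b=f"b{c}_{counter[c]}",
                N=N,
                r=float(np.tanh(z)),
                bucket=tuple(sorted(pair)),
            )
        )
    return records
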
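"""Shared fixtures: small hand-built matrices and a planted instance whose
optimum is provable by brute force."""

from __future__ import annotations

import numpy as np
import pytest

from tissuescope import ExpressionMatrix, MTICatalog, parse_sample_id


def make_matrix(feature_ids, sample_ids, values) -> ExpressionMatrix:
    samples = [parse_sample_id(s) for s in sample_ids]
    return ExpressionMatrix(feature_ids, samples, np.asarray(values, dtype=float))


@pytest.fixture
def small_sample_ids():
    return ["T_colon_1", "T_colon_2", "N_colon_1", "T_lung_1", "N_lung_1", "T_breast_1"]


@pytest.fixture
def small_matrix(small_sample_ids):
    rng = np.random.default_rng(42)
    values = 9.0 + rng.normal(0, 1, size=(4, len(small_sample_ids)))
    return make_matrix(["feat-a", "feat-b", "feat-c", "feat-d"], small_sample_ids, values)


@pytest.fixture
def planted_instance():
    """8 tissues, planted subset of 4 where 3 targets are exact negatives of
    the miRNA; outside the subset the targets follow the miRNA positively.

    By construction the planted subset is the unique loss minimizer at k=4:
    its loss attains the lower bound -a (all correlations exactly -1), and
    any subset containing an off-subset tissue mixes in positively-coupled
    points so at least one correlation exceeds -1.  The in-test brute-force
    oracle confirms uniqueness.
    """
    sample_ids = [
        "T_colon_1", "T_colon_2", "N_colon_1", "T_lung_1",
        "N_lung_1", "T_breast_1", "N_breast_1", "T_ovary_1",
    ]
    planted = ("N_colon_1", "T_colon_1", "T_colon_2", "T_lung_1")
    base = 9.0
    m = base + np.array([0.5, -1.0, 1.5, -0.5, 0.3, 1.1, -0.8, 0.9])
    inside = np.array([s in planted for s in sample_ids])
    targets = []
    for scale in (1.0, 0.7, 1.3):
        y = np.where(inside, base - scale * (m - base), base + scale * (m - base))
        targets.append(y)
    mirna_matrix = make_matrix(["mir-x"], sample_ids, m[None, :])
    mrna_matrix = make_matrix(["g1", "g2", "g3"], sample_ids, np.vstack(targets))
    catalog = MTICatalog.from_pairs([("mir-x", g) for g in ("g1", "g2", "g3")])
    return mirna_matrix, mrna_matrix, catalog, planted
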
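"""Tensor assembly, normalization, Tucker3/PARAFAC fitting, and feature
influence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cellgraphs import (
    FeatureTensor,
    assemble_tensor,
    fit_parafac,
    fit_tucker3,
    influence_scores,
    normalize_tensor,
    plant_influence_tensor,
    select_components,
    select_dims_diffit,
)
from cellgraphs.metrics import LABEL_COLUMNS, METRIC_NAMES
from cellgraphs.multiway import congruence, denormalize_tensor, tucker_fit_grid, unfold


def _table(values_by_sample):
    """Build a metric table from {(time, line, rep): length-20 values}."""
    rows = []
    for (t, line, rep), vals in values_by_sample.items():
        row = dict(zip(METRIC_NAMES, vals))
        row.update(sample_id=f"{line}_{t}_{rep}", cell_line=line, time_h=t, replicate=rep)
        rows.append(row)
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + METRIC_NAMES)


def _random_tensor(rng, shape=(6, 4, 5)):
    return FeatureTensor(
        rng.standard_normal(shape),
        [f"f{i}" for i in range(shape[0])],
        list(map(float, range(shape[1]))),
        [f"l{k}" for k in range(shape[2])],
    )


def test_assemble_shape_and_replicate_mean(rng):
    table = _table({
        (t, l, r): rng.standard_normal(20)
        for t in (10.0, 16.0) for l in ("a", "b", "c") for r in (1, 2)
    })
    tensor = assemble_tensor(table)
    assert tensor.shape == (20, 2, 3)
    assert tensor.time_points == [10.0, 16.0]
    assert tensor.cell_lines == ["a", "b", "c"]
    # replicate mean: rebuild one cell by hand
    sub = table[(table.time_h == 10.0) & (table.cell_line == "b")]
    assert np.allclose(tensor.entries[:, 0, 1], sub[METRIC_NAMES].mean().to_numpy())


def test_assemble_replicates_average_to_midpoint():
    v1, v3 = np.ones(20), 3 * np.ones(20)
    tensor = assemble_tensor(_table({
        (10.0, "a", 1): v1, (10.0, "a", 2): v3,
        (16.0, "a", 1): v1, (16.0, "a", 2): v1,
        (10.0, "b", 1): v1, (16.0, "b", 1): v3,
    }))
    assert np.allclose(tensor.entries[:, 0, 0], 2.0)


def test_assemble_missing_cell_reports_holes(rng):
    table = _table({
        (10.0, "a", 1): rng.standard_normal(20),
        (16.0, "a", 1): rng.standard_normal(20),
        (10.0, "b", 1): rng.standard_normal(20),
    })
    with pytest.raises(ValueError, match=r"missing.*16.*b"):
        assemble_tensor(table)


def test_normalize_constant_tensor_is_degenerate():
    t = FeatureTensor(np.full((3, 4, 5), 2.0), ["a", "b", "c"],
                      [0.0, 1.0, 2.0, 3.0], list("vwxyz"))
    with pytest.raises(ValueError, match="zero-variance"):
        normalize_tensor(t)


def test_normalize_step1_fiber_property_and_round_trip(rng):
    tensor = _random_tensor(rng)
    normalized, record = normalize_tensor(tensor)
    # reconstruct the step-1 intermediate from the record: every (i,k)
    # fibre mean over time must be zero there
    step1 = normalized.entries * record.feature_sds[:, None, None] + \
        record.line_means[:, :, None]
    assert np.allclose(step1.mean(axis=1), 0.0, atol=1e-12)
    # sequential centering: line-mode fibre means of step1 need not vanish
    back = denormalize_tensor(normalized, record)
    assert np.allclose(back.entries, tensor.entries, atol=1e-10)


def test_normalized_feature_slices_have_unit_variance(rng):
    normalized, _ = normalize_tensor(_random_tensor(rng))
    sds = normalized.entries.std(axis=(1, 2), ddof=1)
    assert np.allclose(sds, 1.0, atol=1e-12)


def test_select_components_rank1_and_full():
    a, b, c = np.arange(1, 5.0), np.array([2.0, -1.0, 3.0]), np.array([1.0, 4.0])
    rank1 = FeatureTensor(np.einsum("i,j,k->ijk", a, b, c),
                          list("wxyz"), [0.0, 1.0, 2.0], ["p", "q"])
    assert select_components(rank1, 0.95) == (1, 1, 1)
    rng = np.random.default_rng(0)
    noisy = _random_tensor(rng, (5, 4, 3))
    full = select_components(noisy, 1.0)
    assert full == tuple(
        np.linalg.matrix_rank(unfold(noisy.entries, m)) for m in range(3)
    )


def test_select_components_two_dominant_directions():
    """Mode-1 energy split 60/39/1 across orthogonal directions -> P = 2."""
    weights = np.sqrt([60.0, 39.0, 1.0])
    basis = np.linalg.qr(
        np.random.default_rng(1).standard_normal((20, 3))
    )[0].T  # 3 orthonormal rows of length 20
    mode1 = np.zeros((6, 20))
    mode1[:3] = weights[:, None] * basis
    t = FeatureTensor(mode1.reshape(6, 4, 5), [f"f{i}" for i in range(6)],
                      list(map(float, range(4))), list("abcde"))
    assert select_components(t, 0.95)[0] == 2


def test_tucker_full_rank_is_exact(rng):
    tensor = _random_tensor(rng)
    dims = tuple(np.linalg.matrix_rank(unfold(tensor.entries, m)) for m in range(3))
    model = fit_tucker3(tensor, dims)
    assert model.explained_variation_pct >= 99.99
    assert np.allclose(model.reconstruction() + model.residual, tensor.entries, atol=1e-8)


def test_tucker_rank111_exact_on_rank1():
    t = FeatureTensor(
        np.einsum("i,j,k->ijk", [1.0, 2, 3], [1.0, -1], [2.0, 0.5, 1]),
        list("abc"), [0.0, 1.0], list("xyz"),
    )
    model = fit_tucker3(t, (1, 1, 1))
    assert model.explained_variation_pct == pytest.approx(100.0, abs=1e-6)


def test_tucker_factors_orthonormal(rng):
    model = fit_tucker3(_random_tensor(rng), (3, 2, 2))
    for f in (model.A, model.B, model.C):
        assert np.allclose(f.T @ f, np.eye(f.shape[1]), atol=1e-10)


def test_tucker_explained_variation_monotone(rng):
    tensor = _random_tensor(rng, (5, 4, 4))
    fit = tucker_fit_grid(tensor)
    for d1 in fit:
        for d2 in fit:
            if all(a <= b for a, b in zip(d1, d2)):
                assert fit[d1] <= fit[d2] + 1e-6
    # the grid covers the full admissible lattice, exact at full dims
    assert fit[(5, 4, 4)] == pytest.approx(100.0, abs=1e-6)
    with pytest.raises(ValueError):
        fit_tucker3(tensor, (6, 1, 1))


def test_parafac_rank1_recovery():
    a, b, c = np.array([1.0, -2, 0.5]), np.array([3.0, 1, 2, -1]), np.array([1.0, 5])
    t = FeatureTensor(np.einsum("i,j,k->ijk", a, b, c), list("pqr"),
                      [0.0, 1, 2, 3], ["u", "v"])
    model = fit_parafac(t, 1, seed=0)
    assert model.explained_variation_pct > 99.999
    for truth, got in ((a, model.A), (b, model.B), (c, model.C)):
        assert abs(congruence(truth[:, None], got)[0, 0]) > 0.999


def test_parafac_rank3_factor_recovery(rng):
    shape, r = (8, 6, 5), 3
    truth = [rng.standard_normal((s, r)) for s in shape]
    t = FeatureTensor(np.einsum("ir,jr,kr->ijk", *truth),
                      [f"f{i}" for i in range(8)], list(map(float, range(6))),
                      list("abcde"))
    model = fit_parafac(t, r, n_starts=4, seed=1)
    assert model.explained_variation_pct > 99.9
    # align components by total congruence product, then check per mode
    prod = np.abs(
        congruence(truth[0], model.A)
        * congruence(truth[1], model.B)
        * congruence(truth[2], model.C)
    )
    perm = np.argmax(prod, axis=1)
    assert sorted(perm.tolist()) == list(range(r))
    for truth_f, got_f in zip(truth, (model.A, model.B, model.C)):
        cong = np.abs(congruence(truth_f, got_f))
        assert all(cong[i, perm[i]] > 0.99 for i in range(r))


def test_parafac_deterministic_per_seed(rng):
    t = _random_tensor(rng, (5, 4, 3))
    m1 = fit_parafac(t, 2, seed=42)
    m2 = fit_parafac(t, 2, seed=42)
    assert np.array_equal(m1.A, m2.A) and np.array_equal(m1.weights, m2.weights)


def test_parafac_nested_in_tucker(rng):
    t = _random_tensor(rng, (6, 5, 4))
    r = 3
    parafac = fit_parafac(t, r, seed=0)
    tucker = fit_tucker3(t, (r, r, r))
    assert parafac.explained_variation_pct <= tucker.explained_variation_pct + 1e-6


def test_influence_recovers_planted_features():
    hits = []
    for seed in range(5):
        t = plant_influence_tensor(seed=seed)
        normalized, _ = normalize_tensor(t)
        dims = select_dims_diffit(normalized)
        model = fit_tucker3(normalized, dims)
        scores = influence_scores(model, top_k=5)
        planted = {t.feature_names[i] for i in t.meta["planted_influential"]}
        hits.append(len(planted & set(scores.selected)))
    assert np.mean(hits) >= 4


def test_influence_equivariant_under_feature_permutation(rng):
    t = plant_influence_tensor(seed=3)
    perm = rng.permutation(t.shape[0])
    permuted = FeatureTensor(
        t.entries[perm], [t.feature_names[i] for i in perm],
        t.time_points, t.cell_lines,
    )
    def ranked(tensor):
        normalized, _ = normalize_tensor(tensor)
        model = fit_tucker3(normalized, (3, 2, 2))
        return influence_scores(model, top_k=5)
    assert set(ranked(t).selected) == set(ranked(permuted).selected)


def test_influence_ranksum_option_and_validation(rng):
    t = _random_tensor(rng, (6, 4, 5))
    model = fit_tucker3(t, (2, 2, 2))
    scores = influence_scores(model, top_k=3, combine="ranksum")
    assert len(scores.selected) == 3
    assert np.all(scores.hotelling_t2 >= 0) and np.all(scores.ssr >= 0)
    with pytest.raises(ValueError):
        influence_scores(model, combine="bogus")


def test_long_frame_round_trip(rng):
    t = _random_tensor(rng, (4, 3, 2))
    back = FeatureTensor.from_long_frame(t.to_long_frame())
    assert np.allclose(back.entries, t.entries)
    assert back.cell_lines == t.cell_lines
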
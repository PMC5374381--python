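import json

import numpy as np
import pytest

from pghm import ConfigurationError, build_pghm, nearest_group, select_groups, shade
from pghm.composition import FrequencyMatrix, build_matrix
from pghm.heatmap import PGHMConfig, PGHMModel
from pghm.sequence_io import ReadRecord, SampleSet
from pghm.synthetic import BiasModel, SyntheticConfig, make_templates, simulate_sample


def _sample_with_counts(label, counts):
    reads, groups = [], {}
    for g, n in counts.items():
        for i in range(n):
            rid = f"{label}:{g}:{i}"
            reads.append(ReadRecord(rid, "ACGTACGT", None))
            groups[rid] = g
    return SampleSet(label, reads, groups)


def test_select_groups_by_min_count():
    a = _sample_with_counts("A", {"a": 100, "b": 50, "c": 10, "d": 5, "e": 1})
    b = _sample_with_counts("B", {"a": 100, "b": 50, "c": 10, "d": 5, "e": 1})
    assert select_groups(a, b, n=4) == ["a", "b", "c", "d"]


def test_select_groups_requires_presence_in_both():
    a = _sample_with_counts("A", {"a": 100, "b": 50, "c": 10})
    b = _sample_with_counts("B", {"a": 100, "b": 50, "x": 99})
    assert select_groups(a, b, n=2) == ["a", "b"]
    with pytest.raises(ConfigurationError):
        select_groups(a, b, n=3)


def test_select_groups_ties_break_lexicographically():
    a = _sample_with_counts("A", {"z": 10, "y": 10, "x": 10})
    b = _sample_with_counts("B", {"z": 10, "y": 10, "x": 10})
    assert select_groups(a, b, n=2) == ["x", "y"]


def test_select_groups_rejects_n_of_one():
    a = _sample_with_counts("A", {"a": 5, "b": 5})
    with pytest.raises(ConfigurationError):
        select_groups(a, a, n=1)


@pytest.fixture(scope="module")
def three_group_sample(index336):
    """alpha and beta are 5% apart; gamma is 40% divergent from both."""
    near_cfg = SyntheticConfig(
        n_groups=2, template_gc=(0.55, 0.54),
        inter_group_divergence=0.05, reads_per_group=25,
        mutation_rate=0.01, seed=21)
    t0, t1 = make_templates(near_cfg)
    rng = np.random.default_rng(99)
    far_cfg = SyntheticConfig(
        n_groups=2, template_gc=(0.55, 0.45),
        inter_group_divergence=0.40, reads_per_group=25, seed=21)
    t2 = make_templates(far_cfg, rng)[1]
    sim_cfg = SyntheticConfig(
        n_groups=3, template_gc=(0.55, 0.54, 0.53),
        inter_group_divergence=0.05, reads_per_group=25,
        mutation_rate=0.01, seed=21)
    sample = simulate_sample([t0, t1, t2], sim_cfg, BiasModel(), "A")
    matrix = build_matrix(sample, index336)
    return sample, matrix


def test_nearest_group_agrees_across_methods(three_group_sample):
    sample, matrix = three_group_sample
    for method in ("mean_correlation", "pc_centroid"):
        assert nearest_group("alpha", sample, ["alpha", "beta", "gamma"],
                             matrix, method=method) == "beta"
        assert nearest_group("beta", sample, ["alpha", "beta", "gamma"],
                             matrix, method=method) == "alpha"


def test_nearest_group_two_candidate_case(three_group_sample):
    sample, matrix = three_group_sample
    assert nearest_group("alpha", sample, ["alpha", "gamma"], matrix) == "gamma"


def test_nearest_group_no_candidates(three_group_sample):
    sample, matrix = three_group_sample
    with pytest.raises(ConfigurationError):
        nearest_group("alpha", sample, ["alpha"], matrix)


def test_nearest_group_method_disagreement_warns(three_group_sample, caplog):
    sample, matrix = three_group_sample
    with caplog.at_level("WARNING"):
        nearest_group("alpha", sample, ["alpha", "beta", "gamma"], matrix,
                      check_agreement=True)
    # agreement here: no warning emitted, contract is warn-not-raise
    assert not any("disagree" in r.message for r in caplog.records)


def test_model_structure_and_counts(positive_model):
    model, _, _, _ = positive_model
    assert model.n_groups == 4
    assert len(model.inner_wedges) == 4
    assert len(model.outer_wedges) == 8
    assert len(model.significance) == 8
    for w in model.outer_wedges:
        assert w.nearest_group != w.group
        assert w.nearest_group in model.groups


def test_positive_control_pattern(positive_model):
    model, _, _, _ = positive_model
    assert model.pattern == "phylogenetic_clustering"
    inner = [w.summary.mean_R for w in model.inner_wedges]
    outer = [w.summary.mean_R for w in model.outer_wedges]
    assert min(inner) > max(outer)


def test_shades_monotone_with_mean_R(positive_model):
    model, _, _, _ = positive_model
    wedges = model.inner_wedges + model.outer_wedges
    order = sorted(wedges, key=lambda w: w.summary.mean_R)
    shades = [w.shade for w in order]
    assert all(a <= b + 1e-12 for a, b in zip(shades, shades[1:]))


def test_swapping_samples_preserves_inner_and_swaps_outer(positive_pair, index336):
    a, b, _ = positive_pair
    matrix = FrequencyMatrix.concat(
        [build_matrix(a, index336), build_matrix(b, index336)])
    m1 = build_pghm(a, b, matrix, n=4)
    m2 = build_pghm(b, a, matrix, n=4)
    assert m1.groups == m2.groups
    for w1, w2 in zip(m1.inner_wedges, m2.inner_wedges):
        assert w1.summary.mean_R == pytest.approx(w2.summary.mean_R, abs=1e-12)
    for g in m1.groups:
        r1 = sorted(w.summary.mean_R for w in m1.outer_pair(g))
        r2 = sorted(w.summary.mean_R for w in m2.outer_pair(g))
        assert r1 == pytest.approx(r2, abs=1e-12)
    assert m1.pattern == m2.pattern


def test_pattern_invariant_to_read_order_and_scaling(positive_pair, index336):
    a, b, _ = positive_pair
    ma, mb = build_matrix(a, index336), build_matrix(b, index336)
    matrix = FrequencyMatrix.concat([ma, mb])
    base = build_pghm(a, b, matrix, n=4)

    rng = np.random.default_rng(0)
    perm = rng.permutation(len(matrix.read_ids))
    shuffled = FrequencyMatrix(
        read_ids=[matrix.read_ids[i] for i in perm],
        features=matrix.features,
        values=5.0 * matrix.values[perm],
        lengths=matrix.lengths[perm],
    )
    a_shuf = SampleSet(a.sample_label, list(reversed(a.reads)), a.group_of)
    other = build_pghm(a_shuf, b, shuffled, n=4)
    assert other.pattern == base.pattern
    for w1, w2 in zip(base.inner_wedges, other.inner_wedges):
        assert w1.summary.mean_R == pytest.approx(w2.summary.mean_R, abs=1e-9)


@pytest.mark.parametrize("r,expected", [
    (1.0, 1.0), (0.0, 0.0), (-0.2, 0.0), (0.5, 0.5), (1.3, 1.0),
])
def test_shade_fixed_unit(r, expected):
    assert shade(r) == pytest.approx(expected)


def test_shade_data_range():
    assert shade(0.5, "data_range", data_min=0.0, data_max=1.0) == 0.5
    assert shade(0.11, "data_range", data_min=0.11, data_max=0.71) == 0.0
    assert shade(0.71, "data_range", data_min=0.11, data_max=0.71) == 1.0
    assert shade(0.4, "data_range", data_min=0.4, data_max=0.4) == 0.5


def test_model_json_roundtrip(positive_model, tmp_path):
    model, _, _, _ = positive_model
    p = tmp_path / "model.json"
    model.to_json(p)
    loaded = PGHMModel.from_json(p)
    assert loaded.pattern == model.pattern
    assert loaded.groups == model.groups
    assert [w.summary.mean_R for w in loaded.inner_wedges] == \
        [w.summary.mean_R for w in model.inner_wedges]
    # z samples are deliberately not serialized
    assert loaded.inner_wedges[0].summary.z_values is None
    with open(p) as fh:
        d = json.load(fh)
    assert set(d) == {"n_groups", "groups", "sample_labels", "inner_wedges",
                      "outer_wedges", "significance", "pattern", "shade_scale"}
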
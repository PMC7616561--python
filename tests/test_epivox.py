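"""Reconstruction network variants and their analytic cost accounting."""

import numpy as np
import pytest

from echo2vox import nn
from echo2vox.epivox import CapacityError, NetworkSpec, build_model, cost_report
from echo2vox.nn import autograd as ag

SMALL = dict(input_size_px=32, output_dim=16, base_width=8, seed=0)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


def test_tier_constraints_enforced():
    assert build_model(NetworkSpec(tier="fast", variant="parallel", **SMALL)).refiner is None
    assert build_model(NetworkSpec(tier="accurate", variant="parallel", **SMALL)).refiner is not None
    with pytest.raises(ValueError):
        NetworkSpec(tier="fast", use_refiner=True, **SMALL).resolved()
    with pytest.raises(ValueError):
        NetworkSpec(tier="accurate", backbone_depth=18, **SMALL).resolved()


def test_forward_shape_range_and_determinism(rng):
    model = build_model(NetworkSpec(tier="fast", variant="efficient", **SMALL))
    imgs = rng.random((2, 2, 32, 32))
    out1 = model(imgs).data
    out2 = model(imgs).data
    assert out1.shape == (2, 16, 16, 16)
    assert out1.min() >= 0.0 and out1.max() <= 1.0
    assert np.array_equal(out1, out2)
    assert out1.std() > 0  # non-degenerate


def test_efficient_variant_accepts_any_view_count_up_to_capacity(rng):
    model = build_model(NetworkSpec(tier="fast", variant="efficient", max_views=4, **SMALL))
    for v in (1, 2, 4):
        assert model(rng.random((1, v, 32, 32))).shape == (1, 16, 16, 16)
    with pytest.raises(CapacityError):
        model(rng.random((1, 5, 32, 32)))
    with pytest.raises(ValueError):
        model(rng.random((1, 2, 16, 16)))  # wrong image size


def test_parallel_fusion_identity_for_duplicated_views(rng):
    """Identical views get uniform softmax weights: fused == single-view coarse."""
    model = build_model(NetworkSpec(tier="fast", variant="parallel", **SMALL))
    img = rng.random((1, 1, 32, 32))
    single = model(img).data
    dup = model(np.concatenate([img, img], axis=1)).data
    assert np.allclose(single, dup, atol=1e-12)


def test_decoder_parameters_independent_of_view_count():
    spec = NetworkSpec(tier="fast", variant="efficient", **SMALL)
    model = build_model(spec)
    r1 = cost_report(spec, 1, model=model)
    r4 = cost_report(spec, 4, model=model)
    assert r1.components["decoder"]["parameter_count"] == r4.components["decoder"]["parameter_count"]
    assert r1.components["decoder"]["multiply_add_count"] == r4.components["decoder"]["multiply_add_count"]


def test_parallel_decoder_macs_linear_in_views():
    spec = NetworkSpec(tier="fast", variant="parallel", **SMALL)
    model = build_model(spec)
    d1 = cost_report(spec, 1, model=model).components["decoder"]["multiply_add_count"]
    d8 = cost_report(spec, 8, model=model).components["decoder"]["multiply_add_count"]
    assert d8 == 8 * d1


def _instrumented_total_macs(model, views, monkeypatch):
    """Independent oracle: accumulate multiply-adds from the runtime array
    shapes of every convolution actually executed in a forward pass."""
    from echo2vox.nn import autograd

    total = {"macs": 0}
    real_conv, real_convt = autograd.conv, autograd.conv_transpose

    def counting_conv(x, w, b, stride=1, pad=0):
        out = real_conv(x, w, b, stride, pad)
        batch = x.shape[0]
        per_sample = int(np.prod(out.shape[2:])) * w.shape[0] * w.shape[1] * int(np.prod(w.shape[2:]))
        total["macs"] += batch * per_sample
        return out

    def counting_convt(x, w, b, stride=1, pad=0, output_padding=0):
        out = real_convt(x, w, b, stride, pad, output_padding)
        batch = x.shape[0]
        per_sample = int(np.prod(x.shape[2:])) * w.shape[0] * w.shape[1] * int(np.prod(w.shape[2:]))
        total["macs"] += batch * per_sample
        return out

    monkeypatch.setattr(autograd, "conv", counting_conv)
    monkeypatch.setattr(autograd, "conv_transpose", counting_convt)
    rng = np.random.default_rng(1)
    model(rng.random((1, views, model.spec.input_size_px, model.spec.input_size_px)))
    monkeypatch.undo()
    return total["macs"]


@pytest.mark.parametrize("tier,variant", [("fast", "parallel"), ("fast", "efficient"), ("accurate", "efficient")])
def test_cost_report_matches_runtime_shape_walk(tier, variant, monkeypatch):
    spec = NetworkSpec(tier=tier, variant=variant, **SMALL)
    model = build_model(spec)
    views = 2
    report = cost_report(spec, views, model=model)
    measured = _instrumented_total_macs(model, views, monkeypatch)
    analytic = report.total_multiply_adds
    if variant == "parallel":
        # the report additionally books the per-voxel fusion weighted sum
        analytic -= views * spec.output_dim**3
    assert measured == analytic
    # parameter totals against the actual weight arrays
    assert report.total_parameters == sum(p.data.size for p in model.parameters())


@pytest.mark.parametrize("tier", ["fast", "accurate"])
def test_efficient_cheaper_with_nondecreasing_gap(tier):
    """At 64-cube output the single-decoder variant costs fewer multiply-adds
    for two or more views, and the saving grows with the view count."""
    sp = NetworkSpec(tier=tier, variant="parallel", output_dim=64)
    se = NetworkSpec(tier=tier, variant="efficient", output_dim=64)
    mp, me = build_model(sp), build_model(se)
    gaps = []
    for v in (1, 2, 4, 8):
        gap = cost_report(sp, v, model=mp).total_multiply_adds - cost_report(se, v, model=me).total_multiply_adds
        if v >= 2:
            assert gap > 0
        gaps.append(gap)
    assert all(b >= a for a, b in zip(gaps, gaps[1:]))
    assert cost_report(se, 1, model=me).total_parameters < cost_report(sp, 1, model=mp).total_parameters


@pytest.mark.parametrize(
    "tier,variant",
    [("fast", "parallel"), ("fast", "efficient"), ("accurate", "parallel"), ("accurate", "efficient")],
)
def test_single_step_decreases_loss(tier, variant, rng):
    """Gradient flow smoke test for all four variants at 16-cube output."""
    model = build_model(NetworkSpec(tier=tier, variant=variant, **SMALL))
    imgs = np.random.default_rng(2).random((1, 2, 32, 32))
    gt = (np.random.default_rng(3).random((1, 16, 16, 16)) > 0.5).astype(float)
    opt = nn.Adam(model.parameters(), lr=1e-3)
    loss0 = ag.binary_cross_entropy(model(imgs), gt)
    loss0.backward()
    opt.step()
    loss1 = ag.binary_cross_entropy(model(imgs), gt)
    assert loss1.data.item() < loss0.data.item()


def test_spec_yaml_roundtrip():
    spec = NetworkSpec(tier="accurate", variant="efficient", output_dim=32, max_views=4)
    again = NetworkSpec.from_yaml(spec.to_yaml())
    assert again == spec
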
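"""Synthetic data generation, demographic fixtures, splits and partitions."""

import numpy as np
import pytest

from fairseg.data import (
    DemographicTable,
    GenerationSpec,
    GroupAppearance,
    build_demographic_fixture,
    generate_dataset,
    load_dataset,
    partition_by_site,
    render_sample,
    save_dataset,
    stratified_split,
)
from fairseg.groups import GROUP_ORDER, SITES, GroupKey

WM = GroupKey("White", "Male")
BF = GroupKey("Black", "Female")


# ---------------------------------------------------------------------------
# Demographic fixtures: site tables and their cohort marginals
# ---------------------------------------------------------------------------

HIP_MARGINALS = {
    ("gender", "Male"): 324, ("gender", "Female"): 437,
    ("race", "White"): 443, ("race", "Black"): 318,
    ("group", "MB"): 94, ("group", "MW"): 230, ("group", "FB"): 224, ("group", "FW"): 213,
}
KNEE_MARGINALS = {
    ("gender", "Male"): 280, ("gender", "Female"): 427,
    ("race", "White"): 447, ("race", "Black"): 260,
    ("group", "MB"): 86, ("group", "MW"): 194, ("group", "FB"): 174, ("group", "FW"): 253,
}


@pytest.mark.parametrize(
    "name,total,marginals",
    [("hip", 761, HIP_MARGINALS), ("knee", 707, KNEE_MARGINALS)],
)
def test_fixture_marginals_match_cohort_tables(name, total, marginals):
    """Every site-table row summed over sites A-E equals the cohort-level
    demographic count, for all eight attribute rows of both datasets."""
    table = build_demographic_fixture(name)
    assert table.total() == total
    for (kind, key), expected in marginals.items():
        if kind == "gender":
            assert table.attribute_total(gender=key) == expected, key
        elif kind == "race":
            assert table.attribute_total(race=key) == expected, key
        else:
            assert table.group_total(GroupKey.from_code(key)) == expected, key


def test_hip_site_a_black_cells():
    """Site A of the hip cohort: 157 Black patients, 112 of them Female-Black."""
    hip = build_demographic_fixture("hip")
    assert hip.cell(GroupKey("Black", "Female"), "A") == 112
    black_a = sum(hip.cell(g, "A") for g in GROUP_ORDER if g.race == "Black")
    assert black_a == 157


def test_unknown_fixture_rejected():
    with pytest.raises(ValueError, match="unknown dataset"):
        build_demographic_fixture("elbow")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _spec(**kw):
    defaults = dict(n_samples=8, image_size=(32, 32), seed=3)
    defaults.update(kw)
    return GenerationSpec(**defaults)


def test_render_is_deterministic():
    a = render_sample(_spec(), WM, 5)
    b = render_sample(_spec(), WM, 5)
    assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)


def test_render_has_foreground_and_valid_range():
    rec = render_sample(_spec(), BF, 1)
    assert (rec.mask > 0).any()
    assert rec.mask.max() <= 6
    assert 0.0 <= rec.image.min() and rec.image.max() <= 1.0


def test_zero_noise_unit_contrast_is_exact_rendering():
    """With noise 0 and contrast 1 the image is exactly the noiseless
    structure rendering (same geometry rng stream)."""
    app = {g: GroupAppearance(noise_sd=0.0, contrast=1.0) for g in GROUP_ORDER}
    rec = render_sample(_spec(group_appearance=app), WM, 2)
    rec2 = render_sample(_spec(group_appearance=app), WM, 2)
    assert np.array_equal(rec.image, rec2.image)
    # every pixel is either background or one of the structure intensities
    assert set(np.round(np.unique(rec.image), 6)).issuperset({0.08})


def test_group_noise_gap_shows_in_residual_sd():
    """Monte-Carlo: residual SD (noisy minus noiseless render) tracks the
    group noise level."""
    quiet = {g: GroupAppearance(noise_sd=0.02, contrast=1.0) for g in GROUP_ORDER}
    loud = {g: GroupAppearance(noise_sd=0.20, contrast=1.0) for g in GROUP_ORDER}
    none = {g: GroupAppearance(noise_sd=0.0, contrast=1.0) for g in GROUP_ORDER}

    def residual_sd(app):
        sds = []
        for s in range(50):
            noisy = render_sample(_spec(group_appearance=app), WM, s).image
            clean = render_sample(_spec(group_appearance=none), WM, s).image
            sds.append((noisy - clean).std())
        return np.mean(sds)

    assert residual_sd(loud) > 5 * residual_sd(quiet) > 0


def test_too_small_image_rejected():
    with pytest.raises(ValueError, match="too small"):
        render_sample(_spec(image_size=(8, 8)), WM, 0)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def test_uniform_generation_balances_groups():
    samples = generate_dataset(_spec(n_samples=8))
    counts = {g: 0 for g in GROUP_ORDER}
    for rec in samples:
        counts[rec.group] += 1
    assert all(c == 2 for c in counts.values())
    assert len({r.sample_id for r in samples}) == 8


def test_fixture_generation_matches_table_exactly():
    spec = GenerationSpec(fixture="hip", image_size=(32, 32), seed=0)
    samples = generate_dataset(spec)
    assert len(samples) == 761
    male = sum(1 for r in samples if r.group.gender == "Male")
    white = sum(1 for r in samples if r.group.race == "White")
    assert male == 324 and white == 443
    table = build_demographic_fixture("hip")
    for g in GROUP_ORDER:
        for s in SITES:
            got = sum(1 for r in samples if r.group == g and r.site == s)
            assert got == table.cell(g, s)


def test_generation_reproducible():
    a = generate_dataset(_spec(n_samples=6))
    b = generate_dataset(_spec(n_samples=6))
    assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------


def test_split_single_group_exact_sizes():
    spec = GenerationSpec(group_counts={WM: 100}, image_size=(32, 32), seed=3)
    samples = generate_dataset(spec)
    assignment = stratified_split(samples, (0.7, 0.1, 0.2), seed=1)
    from collections import Counter

    c = Counter(assignment.values())
    assert (c["train"], c["val"], c["test"]) == (70, 10, 20)


def test_split_per_group_largest_remainder():
    """4 groups x 20 samples at 70/10/20 -> every group contributes 14/2/4."""
    samples = generate_dataset(_spec(n_samples=80))
    stratified_split(samples, (0.7, 0.1, 0.2), seed=2)
    from collections import Counter

    for g in GROUP_ORDER:
        c = Counter(r.split for r in samples if r.group == g)
        assert (c["train"], c["val"], c["test"]) == (14, 2, 4)


def test_split_degenerate_fraction_and_validation():
    samples = generate_dataset(_spec(n_samples=10))
    assignment = stratified_split(samples, (1.0, 0.0, 0.0), seed=0)
    assert set(assignment.values()) == {"train"}
    with pytest.raises(ValueError):
        stratified_split(samples, (0.5, 0.4, 0.2), seed=0)
    with pytest.raises(ValueError):
        stratified_split(samples, (1.5, -0.5, 0.0), seed=0)


def test_split_deterministic_given_seed():
    samples = generate_dataset(_spec(n_samples=40))
    a = stratified_split(samples, seed=9)
    b = stratified_split(samples, seed=9)
    assert a == b


# ---------------------------------------------------------------------------
# Site partition
# ---------------------------------------------------------------------------


def test_partition_matches_fixture_cells():
    spec = GenerationSpec(fixture="knee", image_size=(32, 32), seed=1)
    samples = generate_dataset(spec)
    table = build_demographic_fixture("knee")
    partition = partition_by_site(samples, table, seed=4)
    assert sum(len(v) for v in partition.values()) == 707
    by_id = {r.sample_id: r for r in samples}
    for s, ids in partition.items():
        for g in GROUP_ORDER:
            got = sum(1 for i in ids if by_id[i].group == g)
            assert got == table.cell(g, s)
    male = sum(1 for r in samples if r.group.gender == "Male")
    assert male == 280


def test_partition_single_site_table():
    samples = generate_dataset(_spec(n_samples=8))
    table = DemographicTable(
        name="one", counts={(g, "C"): 2 for g in GROUP_ORDER}
    )
    partition = partition_by_site(samples, table, seed=0)
    assert list(partition) == ["C"] and len(partition["C"]) == 8


def test_partition_infeasible_names_deficient_cell():
    samples = generate_dataset(_spec(n_samples=8))  # 2 per group
    table = DemographicTable(name="bad", counts={(WM, "A"): 5})
    with pytest.raises(ValueError, match="MW.*site=A|site=A"):
        partition_by_site(samples, table, seed=0)


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------


def test_png_csv_round_trip(tmp_path, tiny_dataset):
    save_dataset(tiny_dataset, tmp_path)
    loaded = load_dataset(tmp_path)
    assert len(loaded) == len(tiny_dataset)
    by_id = {r.sample_id: r for r in loaded}
    for rec in tiny_dataset:
        got = by_id[rec.sample_id]
        assert np.array_equal(got.mask, rec.mask)  # labels lossless
        assert np.abs(got.image - rec.image).max() <= 1 / 255 + 1e-9  # 8-bit quantized
        assert got.group == rec.group and got.split == rec.split


# ---------------------------------------------------------------------------
# Disparity induction (directional, brief training)
# ---------------------------------------------------------------------------


def test_group_noise_gap_induces_lower_iou_for_noisy_group():
    """With the default appearance gap, a briefly trained baseline scores the
    noisier (Black) groups below the cleaner (White) groups - checked as a
    majority vote over 3 seeds."""
    from fairseg.curriculum import order_shuffled
    from fairseg.metrics import group_mean_ious
    from fairseg.data import metadata_groups
    from fairseg.model import Adam, LossSpec, ModelDescriptor, OptimizerConfig, build_model, evaluate, train_epoch

    wins = 0
    for seed in (0, 1, 2):
        app = {
            g: GroupAppearance(noise_sd=0.05 if g.race == "White" else 0.35,
                               contrast=1.0 if g.race == "White" else 0.7)
            for g in GROUP_ORDER
        }
        spec = GenerationSpec(n_samples=40, image_size=(32, 32),
                              group_appearance=app, seed=seed)
        samples = generate_dataset(spec)
        ds = {r.sample_id: r for r in samples}
        model = build_model(ModelDescriptor(), seed=seed)
        opt = Adam(model, OptimizerConfig(lr=3e-3))
        for epoch in range(1, 7):
            order = order_shuffled(sorted(ds), seed * 100 + epoch)
            model, _, _ = train_epoch(model, ds, order, LossSpec("ce"), opt, epoch=epoch)
        scores = evaluate(model, samples)
        means = group_mean_ious(scores, metadata_groups(samples), "race")
        wins += means["White"] > means["Black"]
    assert wins >= 2
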
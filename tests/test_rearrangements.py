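"""32-class SV classification, breakend clustering, sample selection."""

import numpy as np
import pytest

from somacat.rearrangements import (
    REARRANGEMENT_LABELS,
    SIZE_BIN_LABELS,
    SvEvent,
    assign_size_bin,
    build_rearrangement_catalogue,
    classify_event,
    cluster_breakpoints,
    select_samples_for_signatures,
)


def test_class_alphabet_is_32():
    assert len(REARRANGEMENT_LABELS) == 32
    assert len(set(REARRANGEMENT_LABELS)) == 32
    assert sum(1 for lab in REARRANGEMENT_LABELS if "translocation" in lab) == 2


@pytest.mark.parametrize(
    "size,expected",
    [
        (500, "1-10kb"),          # sub-1 kb admitted into the smallest bin
        (5_000, "1-10kb"),
        (10_000, "10-100kb"),     # half-open boundary
        (99_999, "10-100kb"),
        (100_000, "100kb-1Mb"),
        (1_000_000, "1-10Mb"),
        (25_000_000, ">10Mb"),
    ],
)
def test_size_bins(size, expected):
    assert assign_size_bin(size) == expected


def test_size_bin_rejects_nonpositive():
    with pytest.raises(ValueError):
        assign_size_bin(0)


def test_event_normalisation_and_validation():
    ev = SvEvent("s1", "chr1", 5000, "chr1", 1000, "deletion")
    assert (ev.pos1, ev.pos2) == (1000, 5000)
    assert ev.size == 4000
    tr = SvEvent("s1", "chr1", 10, "chr2", 20, "translocation")
    assert tr.size is None
    with pytest.raises(ValueError):
        SvEvent("s1", "chr1", 10, "chr1", 20, "translocation")
    with pytest.raises(ValueError):
        SvEvent("s1", "chr1", 10, "chr2", 20, "inversion")
    with pytest.raises(ValueError):
        SvEvent("s1", "chr1", 10, "chr1", 20, "mystery")


def test_ten_breakends_in_small_span_all_clustered():
    events = [
        SvEvent("s1", "chr1", 1 + i * 10_000, "chr1", 95_000 + i * 1000, "dup")
        for i in range(5)
    ]  # 10 breakends all within ~100 kb on chr1
    flagged = cluster_breakpoints(events)
    assert all(ev.clustered for ev in flagged)


def test_nine_breakends_below_min_count():
    # 4 events + one breakend elsewhere: 9 breakends within 1 Mb
    events = [
        SvEvent("s1", "chr1", 1 + i * 10_000, "chr1", 60_000 + i * 1000, "del")
        for i in range(4)
    ] + [SvEvent("s1", "chr1", 70_000, "chr1", 40_000_000, "dup")]
    flagged = cluster_breakpoints(events)
    assert not any(ev.clustered for ev in flagged)


def test_linked_group_without_dense_window_not_clustered():
    """10 breakends spaced 0.9 Mb: single-linkage joins them but no 1 Mb
    span holds 10, so none are clustered."""
    events = [
        SvEvent("s1", "chr1", 1 + i * 1_800_000, "chr1", 901_000 + i * 1_800_000, "inv")
        for i in range(5)
    ]  # breakends at 0, 0.9, 1.8, 2.7 ... Mb (gaps 0.9 Mb)
    flagged = cluster_breakpoints(events)
    assert not any(ev.clustered for ev in flagged)


def test_clustering_is_order_independent():
    rng = np.random.default_rng(5)
    events = []
    for i in range(40):
        p1 = int(rng.integers(1, 40_000_000))
        events.append(SvEvent("s1", "chr1", p1, "chr1", p1 + int(rng.integers(2_000, 80_000)), "del"))
    flags = {(e.pos1, e.pos2): e.clustered for e in cluster_breakpoints(events)}
    perm = [events[i] for i in rng.permutation(len(events))]
    flags_perm = {(e.pos1, e.pos2): e.clustered for e in cluster_breakpoints(perm)}
    assert flags == flags_perm


def test_translocation_breakends_count_on_both_chromosomes():
    # 10 translocations focused on both ends: 10 breakends per chromosome
    events = [
        SvEvent("s1", "chr1", 100_000 + i * 5_000, "chr2", 200_000 + i * 5_000, "translocation")
        for i in range(10)
    ]
    flagged = cluster_breakpoints(events)
    assert all(ev.clustered for ev in flagged)


def test_catalogue_single_events():
    ev = cluster_breakpoints([SvEvent("s1", "chr1", 1000, "chr1", 6000, "deletion")])
    cat = build_rearrangement_catalogue(ev)
    assert cat.as_series()["non-clustered:del:1-10kb"] == 1
    assert cat.total == 1
    tr = cluster_breakpoints([SvEvent("s1", "chr1", 1, "chr2", 1, "translocation")])
    cat2 = build_rearrangement_catalogue(tr)
    assert cat2.as_series()["non-clustered:translocation"] == 1


def naive_classify(ev):
    """Independent per-event re-classification oracle."""
    prefix = "clustered" if ev.clustered else "non-clustered"
    if ev.chrom1 != ev.chrom2:
        return f"{prefix}:translocation"
    size = abs(ev.pos2 - ev.pos1)
    if size < 10_000:
        bin_ = "1-10kb"
    elif size < 100_000:
        bin_ = "10-100kb"
    elif size < 1_000_000:
        bin_ = "100kb-1Mb"
    elif size < 10_000_000:
        bin_ = "1-10Mb"
    else:
        bin_ = ">10Mb"
    return f"{prefix}:{ev.sv_type}:{bin_}"


def test_catalogue_matches_naive_oracle_on_random_sets():
    from somacat.synthetic import simulate_svs

    rng = np.random.default_rng(17)
    for trial in range(5):
        mixture = rng.dirichlet(np.ones(32))
        events, _truth = simulate_svs(200, mixture, rng=rng)
        events = cluster_breakpoints(events)
        cat = build_rearrangement_catalogue(events).as_series()
        expected = {lab: 0 for lab in REARRANGEMENT_LABELS}
        for ev in events:
            expected[naive_classify(ev)] += 1
        for lab in REARRANGEMENT_LABELS:
            assert cat[lab] == expected[lab]
        assert cat.sum() == 200


def test_every_event_in_exactly_one_class():
    assert classify_event(
        SvEvent("s", "chr1", 1, "chr1", 5_001, "inv", clustered=True)
    ) == "clustered:inv:1-10kb"


def make_cat(sample_id, n):
    events = [
        SvEvent(sample_id, "chr1", 1 + i * 2_000_000, "chr1", 5_001 + i * 2_000_000, "del")
        for i in range(n)
    ]
    return build_rearrangement_catalogue(cluster_breakpoints(events), sample_id)


def test_low_sv_samples_excluded_from_signature_analysis():
    cats = [make_cat("rich", 101), make_cat("ok", 15), make_cat("sparse", 2)]
    included, excluded = select_samples_for_signatures(cats, min_sv=10)
    assert [c.sample_id for c in included] == ["rich", "ok"]
    assert [c.sample_id for c in excluded] == ["sparse"]


def test_all_samples_below_threshold_raises():
    cats = [make_cat("a", 2), make_cat("b", 3)]
    with pytest.raises(ValueError):
        select_samples_for_signatures(cats, min_sv=10)


def test_rearrangement_signature_recovery_with_clustered_signature():
    """Two known SV signatures, one clustered-dominated, recovered >= 0.9."""
    from somacat.rearrangements import catalogue_matrix
    from somacat.signatures import cosine_similarity, extract_signatures
    from scipy.optimize import linear_sum_assignment

    rng = np.random.default_rng(23)
    sig_a = np.zeros(32)  # clustered-dominated
    sig_b = np.zeros(32)
    for i, lab in enumerate(REARRANGEMENT_LABELS):
        if lab.startswith("clustered"):
            sig_a[i] = rng.uniform(0.5, 1.0)
        else:
            sig_b[i] = rng.uniform(0.5, 1.0)
    sig_a /= sig_a.sum()
    sig_b /= sig_b.sum()
    S = np.column_stack([sig_a, sig_b])
    V = np.zeros((32, 16))
    for j in range(16):
        w = rng.dirichlet(np.ones(2))
        V[:, j] = rng.multinomial(400, S @ w)
    model = extract_signatures(V, k=2, n_restarts=30, seed=4)
    C = np.array([[cosine_similarity(S[:, i], model.signatures[:, j]) for j in range(2)]
                  for i in range(2)])
    ri, ci = linear_sum_assignment(-C)
    assert (C[ri, ci] >= 0.9).all()
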
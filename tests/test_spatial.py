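"""Spatial statistics: closed-form oracles, brute-force equivalence, envelopes."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuromosaic import (
    CSR_NND_CV,
    InsufficientDataError,
    InvalidSpecError,
    PointPattern,
    SimulationSpec,
    average_pcf,
    csr_envelope,
    csr_mean_nnd,
    cv_of_nnd,
    merge_double_positive,
    nnd,
    pcf,
    rectangle_window,
    simulate_csr,
    simulate_matern_ii,
    simulate_thomas,
    thomas_pcf,
)


@pytest.fixture(scope="module")
def win():
    return rectangle_window(1000.0, 1000.0)


# ===================================================================== NND
def test_nnd_two_points_and_cross_coincident(win):
    pat = PointPattern(np.array([[100.0, 100.0], [110.0, 100.0]]), win)
    res = nnd(pat)
    assert np.allclose(res.distances, 10.0)
    assert res.mean == pytest.approx(10.0)

    both = PointPattern(
        np.array([[100.0, 100.0], [200.0, 200.0], [100.0, 100.0], [200.0, 200.0]]),
        win,
        types=["A", "A", "B", "B"],
    )
    cross = nnd(both, "A", "B")
    assert np.allclose(cross.distances, 0.0)


def test_nnd_is_asymmetric(win):
    # one B point close to a cluster of A points
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [500.0, 500.0]])
    pat = PointPattern(pts, win, types=["A", "A", "A", "B"])
    ab = nnd(pat, "A", "B")
    ba = nnd(pat, "B", "A")
    assert ab.mean != ba.mean
    assert ab.n == 3 and ba.n == 1


def test_nnd_insufficient_data_errors(win):
    single = PointPattern(np.array([[1.0, 1.0]]), win)
    with pytest.raises(InsufficientDataError):
        nnd(single)
    typed = PointPattern(np.array([[1.0, 1.0]]), win, types=["A"])
    with pytest.raises(InsufficientDataError):
        nnd(typed, "A", "B")


def test_nnd_rigid_motion_invariance(win):
    rng = np.random.default_rng(8)
    pts = rng.uniform(200, 800, (40, 2))
    theta = 0.61
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + [3000.0, -500.0]
    big = rectangle_window(10000, 10000)
    d0 = nnd(PointPattern(pts, big, _skip_validation=True)).distances
    d1 = nnd(PointPattern(moved, big, _skip_validation=True)).distances
    assert np.allclose(np.sort(d0), np.sort(d1), atol=1e-9)


@pytest.mark.parametrize("lam", [50.0, 100.0, 400.0])
def test_nnd_closed_form_recovery(lam):
    """Poisson mean NND 1/(2√λ) and CV √((4−π)/π), reduced-sample estimator."""
    win2 = rectangle_window(2000.0, 2000.0)
    margin = 2.0 / np.sqrt(lam * 1e-6)
    means, cvs = [], []
    for s in range(60):
        pat = simulate_csr(SimulationSpec("csr", lam, win2, seed=4000 + s))
        res = nnd(pat, border_margin=margin)
        means.append(res.mean)
        cvs.append(res.cv)
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - csr_mean_nnd(lam)) < max(3 * se, 0.01 * csr_mean_nnd(lam))
    assert abs(np.mean(cvs) - CSR_NND_CV) < 0.03 * CSR_NND_CV


def test_cv_zero_on_square_lattice(win):
    xs = np.arange(100.0, 901.0, 100.0)
    pts = np.array([[x, y] for x in xs for y in xs])
    res = nnd(PointPattern(pts, win))
    assert cv_of_nnd(res) == pytest.approx(0.0, abs=1e-12)


def test_cv_insufficient(win):
    res = nnd(PointPattern(np.array([[0.0, 0.0], [5.0, 0.0]]), win))
    assert res.n == 2
    one = res.__class__("cell", "cell", np.array([5.0]))
    with pytest.raises(InsufficientDataError):
        cv_of_nnd(one)


def test_cv_regularity_ordering():
    """lattice < Matérn II < CSR < Thomas, at matched intensity (~100/mm²)."""
    win = rectangle_window(1000.0, 1000.0)
    reps, ok = 100, 0
    for s in range(reps):
        mat = simulate_matern_ii(
            SimulationSpec("matern_ii", 117.5, win, seed=300 + s, inhibition_radius=30.0)
        )
        csr = simulate_csr(SimulationSpec("csr", 100.0, win, seed=200 + s))
        tho = simulate_thomas(
            SimulationSpec("thomas", 20.0, win, seed=400 + s, offspring_mean=5.0,
                           cluster_sd=8.0)
        )
        if 0.0 < nnd(mat).cv < nnd(csr).cv < nnd(tho).cv:
            ok += 1
    assert ok >= 0.95 * reps


# ===================================================================== merging
def test_merge_basic_rules(win):
    a = PointPattern(np.array([[0.0, 0.0]]), win)
    b = PointPattern(np.array([[2.0, 0.0]]), win)
    merged = merge_double_positive(a, b, soma_radius=5.0)
    assert merged.n == 1 and list(merged.types) == ["AB"]
    assert np.allclose(merged.points[0], [0.0, 0.0])  # A-member coordinates

    far = PointPattern(np.array([[10.0, 0.0]]), win)
    kept = merge_double_positive(a, far, soma_radius=5.0)
    assert kept.n == 2 and sorted(kept.types) == ["A", "B"]


def test_merge_chain_greedy_once_each(win):
    a = PointPattern(np.array([[0.0, 0.0], [6.0, 0.0]]), win)
    b = PointPattern(np.array([[3.0, 0.0]]), win)
    merged = merge_double_positive(a, b, soma_radius=5.0)
    assert merged.n == 2
    assert sorted(merged.types) == ["A", "AB"]


def _greedy_merge_oracle(a_pts, b_pts, radius):
    """Definition transcription: repeatedly merge the closest unused pair."""
    used_a, used_b, merges = set(), set(), []
    while True:
        best = None
        for i, pa in enumerate(a_pts):
            if i in used_a:
                continue
            for j, pb in enumerate(b_pts):
                if j in used_b:
                    continue
                d = float(np.hypot(pa[0] - pb[0], pa[1] - pb[1]))
                if d < radius and (best is None or (d, i, j) < best):
                    best = (d, i, j)
        if best is None:
            return merges
        _, i, j = best
        used_a.add(i)
        used_b.add(j)
        merges.append((i, j))


@given(st.integers(0, 2**31 - 1))
def test_merge_matches_exhaustive_oracle(seed):
    """Greedy merge equals the definitional nearest-first oracle (≤8 points)."""
    rng = np.random.default_rng(seed)
    win = rectangle_window(100.0, 100.0)
    na, nb = rng.integers(0, 5), rng.integers(0, 5)
    a_pts = rng.uniform(0, 100, (na, 2))
    b_pts = rng.uniform(0, 100, (nb, 2))
    radius = float(rng.uniform(5, 40))
    a = PointPattern(a_pts, win, _skip_validation=True)
    b = PointPattern(b_pts, win, _skip_validation=True)
    merged = merge_double_positive(a, b, soma_radius=radius)
    oracle = _greedy_merge_oracle(a_pts, b_pts, radius)
    assert merged.n == na + nb - len(oracle)
    n_ab = int((merged.types == "AB").sum())
    assert n_ab == len(oracle)
    for i, _ in oracle:
        assert np.any(np.all(np.isclose(merged.points, a_pts[i]), axis=1))


# ===================================================================== PCF
def _pcf_bruteforce(pattern, type_a, type_b, r, bandwidth):
    """Direct O(n²) transcription of the translation-corrected estimator."""
    pts_a = pattern.coords_of(type_a)
    pts_b = pattern.coords_of(type_b)
    same = type_a == type_b or (type_a is None and type_b is None)
    x0, y0, x1, y1 = pattern.window.bounds
    w_ext, h_ext = x1 - x0, y1 - y0
    area = pattern.area
    lam_a = len(pts_a) / area
    lam_b = len(pts_b) / area
    rows = []
    for i in range(len(pts_a)):
        for j in range(len(pts_b)):
            if same and i == j:
                continue
            dx = pts_b[j, 0] - pts_a[i, 0]
            dy = pts_b[j, 1] - pts_a[i, 1]
            d = np.sqrt(dx**2 + dy**2)
            ox = w_ext - np.abs(dx)
            oy = h_ext - np.abs(dy)
            w = area / (max(ox, 0.0) * max(oy, 0.0))
            u = r - d
            k = 0.75 * (1.0 - (u / bandwidth) ** 2) / bandwidth
            rows.append(np.where(np.abs(u) <= bandwidth, k, 0.0) * w)
    acc = np.zeros(len(r)) if not rows else np.zeros(len(r)) + np.vstack(rows).sum(axis=0)
    return acc / (2.0 * np.pi * r * lam_a * lam_b * area)


@pytest.mark.parametrize("typed", [False, True])
def test_pcf_streaming_equals_bruteforce_bitwise(typed, win):
    rng = np.random.default_rng(12)
    r = np.arange(5.0, 200.0, 5.0)
    pts = rng.uniform(0, 1000, (46, 2))
    types = rng.choice(["A", "B"], 46) if typed else None
    pat = PointPattern(pts, win, types=types)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if typed:
            est = pcf(pat, "A", "B", r=r, bandwidth=20.0)
            oracle = _pcf_bruteforce(pat, "A", "B", r, 20.0)
        else:
            est = pcf(pat, r=r, bandwidth=20.0)
            oracle = _pcf_bruteforce(pat, None, None, r, 20.0)
    assert np.array_equal(est.g, oracle)


def test_pcf_csr_long_range_calibration(win):
    """ĝ → 1 for CSR: mean over r∈[20,100] within 1 ± 0.05 over 100 reps."""
    r = np.arange(2.0, 130.0, 2.0)
    vals = [
        pcf(simulate_csr(SimulationSpec("csr", 100.0, win, seed=1000 + s)), r=r).mean_over(
            20.0, 100.0
        )
        for s in range(100)
    ]
    assert abs(np.mean(vals) - 1.0) < 0.05


def test_pcf_hard_core_support(win):
    """Matérn II h=30: smoothed ĝ < 0.2 below 0.8h, averaged over reps."""
    r = np.arange(2.0, 101.0, 2.0)
    gs = [
        pcf(
            simulate_matern_ii(
                SimulationSpec("matern_ii", 200.0, win, seed=5000 + s,
                               inhibition_radius=30.0)
            ),
            r=r,
        ).g
        for s in range(50)
    ]
    mean_g = np.mean(gs, axis=0)
    assert np.all(mean_g[r < 24.0] < 0.2)
    assert abs(np.mean(mean_g[r > 60]) - 1.0) < 0.1


def test_pcf_thomas_matches_closed_form(win):
    """Clustered ĝ matches 1 + exp(−r²/4σ²)/(4πκσ²) within 10% at r = σ."""
    kappa, sd = 10.0, 10.0
    r = np.arange(2.0, 61.0, 2.0)
    gs = []
    for s in range(150):
        pat = simulate_thomas(
            SimulationSpec("thomas", kappa, win, seed=100 + s, offspring_mean=10.0,
                           cluster_sd=sd)
        )
        if pat.n >= 10:
            gs.append(pcf(pat, r=r, bandwidth=3.0).g)
    mean_g = np.mean(gs, axis=0)
    i = int(np.argmin(np.abs(r - sd)))
    theory = thomas_pcf(r[i], kappa, sd)
    assert mean_g[i] == pytest.approx(theory, rel=0.10)
    assert np.all(mean_g[r <= 2 * sd] > 1.0)


def test_pcf_errors_and_warnings(win):
    pat = PointPattern(np.array([[1.0, 1.0], [5.0, 5.0]]), win, types=["A", "A"])
    with pytest.raises(InsufficientDataError):
        pcf(pat, "A", "B")
    with pytest.warns(UserWarning):
        est = pcf(pat, "A", "A", r=np.arange(1.0, 50.0), bandwidth=10.0)
    assert not est.stable
    with pytest.warns(UserWarning):
        trimmed = pcf(pat, "A", "A", r=np.arange(10.0, 900.0, 10.0), bandwidth=10.0)
    assert trimmed.r.max() <= 500.0


def test_pcf_isotropic_correction_close_to_translation(win):
    pat = simulate_csr(SimulationSpec("csr", 60.0, win, seed=77))
    r = np.arange(10.0, 101.0, 10.0)
    t = pcf(pat, r=r, bandwidth=15.0, correction="translation")
    i = pcf(pat, r=r, bandwidth=15.0, correction="isotropic")
    assert np.allclose(t.g, i.g, rtol=0.05, atol=0.05)


def test_pcf_edge_offset_axis():
    est_r = np.arange(5.0, 50.0, 5.0)
    win = rectangle_window(1000, 1000)
    pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=3))
    est = pcf(pat, r=est_r, bandwidth=10.0)
    shifted = est.with_edge_offset(6.0)
    assert np.allclose(shifted.r, est.r - 6.0)
    assert np.array_equal(shifted.g, est.g)


# ===================================================================== envelopes
def test_envelope_requires_enough_sims(win):
    pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=0))
    with pytest.raises(InvalidSpecError):
        csr_envelope(pat, n_sim=0)
    with pytest.raises(InvalidSpecError):
        csr_envelope(pat, n_sim=20)


def test_envelope_pointwise_coverage_for_csr(win):
    """Null coverage: ~95% of grid points inside the bands on average."""
    r = np.arange(2.0, 101.0, 2.0)
    fracs = []
    for s in range(20):
        pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=500 + s))
        est = csr_envelope(pat, n_sim=99, seed=s, r=r)
        fracs.append(np.mean((est.g >= est.envelope_lo) & (est.g <= est.envelope_hi)))
    assert 0.88 <= np.mean(fracs) <= 1.0


def test_global_envelope_simultaneous_coverage(win):
    """Global bands contain a null curve everywhere in ≥90% of reps."""
    r = np.arange(2.0, 101.0, 2.0)
    inside = 0
    reps = 20
    for s in range(reps):
        pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=800 + s))
        est = csr_envelope(pat, n_sim=99, seed=s, r=r, scope="global")
        inside += np.all((est.g >= est.envelope_lo) & (est.g <= est.envelope_hi))
    assert inside >= 0.9 * reps


def test_matern_below_lower_envelope(win):
    """Inhibited pattern dips below the CSR band at r < h."""
    r = np.arange(2.0, 61.0, 2.0)
    below = 0
    reps = 20
    for s in range(reps):
        pat = simulate_matern_ii(
            SimulationSpec("matern_ii", 200.0, win, seed=5000 + s, inhibition_radius=30.0)
        )
        est = csr_envelope(pat, n_sim=99, seed=s, r=r)
        mask = r < 30.0
        below += np.all(est.g[mask] < est.envelope_lo[mask])
    assert below >= 0.95 * reps


def test_envelope_relabel_mode_runs(win):
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 1000, (60, 2))
    pat = PointPattern(pts, win, types=rng.choice(["A", "B"], 60))
    est = csr_envelope(pat, "A", "B", n_sim=39, seed=1,
                       r=np.arange(5.0, 101.0, 5.0), mode="relabel")
    assert est.envelope_lo is not None and (est.envelope_hi >= est.envelope_lo).all()


# ===================================================================== averaging
def test_average_pcf_identity_and_mean(win):
    pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=2))
    r = np.arange(5.0, 101.0, 5.0)
    est = pcf(pat, r=r, bandwidth=12.0)
    single = average_pcf([est])
    assert np.array_equal(single.g, est.g)

    from dataclasses import replace

    lo = replace(est, g=np.full_like(est.g, 0.8))
    hi = replace(est, g=np.full_like(est.g, 1.2))
    avg = average_pcf([lo, hi])
    assert np.allclose(avg.g, 1.0)


def test_average_pcf_two_level_vs_pooled(win):
    """3 ROIs for mouse A, 1 for mouse B: mouse-first averaging reweights."""
    from dataclasses import replace

    pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=2))
    r = np.arange(5.0, 101.0, 5.0)
    base = pcf(pat, r=r, bandwidth=12.0)
    roi_a = [replace(base, g=np.full_like(base.g, v)) for v in (0.9, 1.0, 1.1)]
    roi_b = [replace(base, g=np.full_like(base.g, 2.0))]
    mouse_means = [average_pcf(roi_a), average_pcf(roi_b)]
    group = average_pcf(mouse_means)
    assert np.allclose(group.g, (1.0 + 2.0) / 2)
    pooled = average_pcf(roi_a + roi_b)
    assert np.allclose(pooled.g, (0.9 + 1.0 + 1.1 + 2.0) / 4)
    assert not np.allclose(group.g, pooled.g)


def test_average_pcf_mismatched_bandwidth_rejected(win):
    pat = simulate_csr(SimulationSpec("csr", 100.0, win, seed=2))
    r = np.arange(5.0, 101.0, 5.0)
    with pytest.raises(InvalidSpecError):
        average_pcf([pcf(pat, r=r, bandwidth=10.0), pcf(pat, r=r, bandwidth=20.0)])
    with pytest.raises(InsufficientDataError):
        average_pcf([])
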
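import math

import numpy as np
import pytest

from cnvscale import (
    DetectorParams,
    MedianFilterParams,
    ReadCoverage,
    ScaleParams,
    build_fingerprint_map,
    build_scale_space,
    candidate_intervals,
    detect_cnvs,
    effective_stats,
    eligible_layers,
    median_filter,
)
from cnvscale.fingerprint import FingerPrintMap
from cnvscale.segmentation import LayerBaselines


# ---------------------------------------------------------------------------
# Effective (trimmed) layer statistics
# ---------------------------------------------------------------------------

def test_effective_stats_constant():
    assert effective_stats(np.full(10, 4.0)) == (4.0, 0.0, 4.0, 0.0)


def test_effective_stats_outlier_excluded():
    # hand computation: m=10, delta=30; only the 100 is outside m +/- 2*delta
    layer = np.array([0.0] * 9 + [100.0])
    m, d, m_eff, d_eff = effective_stats(layer)
    assert m == pytest.approx(10.0)
    assert d == pytest.approx(30.0)
    assert m_eff == pytest.approx(0.0)
    assert d_eff == pytest.approx(0.0)


def test_effective_stats_truncated_normal_sd(rng):
    """Trimming a normal sample at +/-2 sigma shrinks the SD by the
    closed-form truncated-normal factor ~0.8796."""
    from scipy.stats import norm

    x = rng.normal(size=100_000)
    m, d, m_eff, d_eff = effective_stats(x)
    phi2, mass = norm.pdf(2.0), norm.cdf(2.0) - norm.cdf(-2.0)
    expected = math.sqrt(1.0 - 4.0 * phi2 / mass)
    assert abs(m_eff) < 0.01
    assert d_eff / d == pytest.approx(expected, abs=0.01)


def test_effective_stats_validation():
    with pytest.raises(ValueError):
        effective_stats(np.array([1.0]))


def test_baselines_ordering(rng):
    bl = LayerBaselines.from_layer(0, rng.normal(5, 1, 5000), d=3.0)
    assert bl.sd_all >= bl.sd_eff >= 0
    assert bl.lower <= bl.mean_eff <= bl.upper


# ---------------------------------------------------------------------------
# Layer eligibility and interval search (dense API)
# ---------------------------------------------------------------------------

def _map_with_crossings(n, layers, crossings):
    z = np.zeros((n, layers), dtype=np.int8)
    for k, pos, sign in crossings:
        z[pos, k] = sign
    return FingerPrintMap(z=z, sigmas=1000.0 * 1.1 ** np.arange(layers))


def test_eligible_layers_ordering():
    empty = _map_with_crossings(50, 4, [])
    assert eligible_layers(empty) == []
    fp = _map_with_crossings(50, 6, [(3, 10, 1), (3, 20, -1), (5, 30, 1), (5, 40, -1)])
    assert eligible_layers(fp) == [5, 3]


def test_candidate_intervals_flat_layer():
    cov = ReadCoverage("c", np.full(800, 3.0) + 0.0)
    params = ScaleParams(sigma0=10.0, ratio=1.3, layers=3)
    img = build_scale_space(cov, params)
    fp = build_fingerprint_map(img)
    bl = LayerBaselines.from_layer(0, img.layer(0))
    assert candidate_intervals(fp, 0, img, bl) == []


def _bump_coverage(n=6000, lo=2500, hi=3100, level=3.0, height=5.0):
    vals = np.full(n, level)
    vals[lo:hi] += height
    return ReadCoverage("c", vals)


def test_candidate_interval_detects_gain_and_respects_exclusion():
    cov = _bump_coverage()
    params = ScaleParams(sigma0=60.0, ratio=1.25, layers=4, convolution_mode="direct")
    img = build_scale_space(cov, params)
    fp = build_fingerprint_map(img)
    k = 3
    bl = LayerBaselines.from_layer(k, img.layer(k))
    found = candidate_intervals(fp, k, img, bl, exclusions=[])
    assert len(found) == 1
    iv = found[0]
    assert iv.direction == "gain"
    assert iv.left < 2800 < iv.right
    assert iv.traced_left < 2800 < iv.traced_right
    # same candidate fully inside an already-declared region is discarded
    assert candidate_intervals(fp, k, img, bl, exclusions=[(0, 5999)]) == []


# ---------------------------------------------------------------------------
# End-to-end detection behaviour
# ---------------------------------------------------------------------------

def _small_params(layers=10, sigma0=100.0, median_w=30, min_len=100):
    return DetectorParams(
        median=MedianFilterParams(w=median_w),
        scale=ScaleParams(sigma0=sigma0, ratio=1.2, layers=layers),
        min_call_length=min_len,
    )


def test_no_cnvs_on_pure_noise(rng):
    cov = ReadCoverage("c", rng.poisson(3.0, 50_000))
    calls = detect_cnvs(cov, _small_params())
    called = sum(c.length for c in calls)
    assert called <= 0.03 * cov.n  # at most a few percent false-called bases


def test_single_gain_recovered(rng):
    lam = np.full(100_000, 3.0)
    lam[40_000:60_000] *= 1.5
    cov = ReadCoverage("c", rng.poisson(lam))
    calls = detect_cnvs(cov, _small_params(layers=20))
    gains = [c for c in calls if c.cnv_type == "gain"]
    assert gains
    best = max(gains, key=lambda c: min(c.end, 60_000) - max(c.start, 40_000))
    overlap = (min(best.end, 60_000) - max(best.start, 40_000)) / 20_000
    assert overlap >= 0.9


def test_large_and_small_cnv_found_at_different_scales(rng):
    """Multi-scale behaviour: a 70 kb loss is declared at a coarser layer
    than a 2 kb gain."""
    lam = np.full(600_000, 3.0)
    lam[150_000:220_000] = 0.05  # 70 kb deep loss
    lam[400_000:402_000] *= 2.0  # 2 kb gain
    cov = ReadCoverage("c", rng.poisson(lam))
    calls = detect_cnvs(cov)  # production defaults: sigma0=1 kb, 60 layers
    losses = [c for c in calls if c.cnv_type == "loss"
              and min(c.end, 220_000) > max(c.start, 150_000)]
    gains = [c for c in calls if c.cnv_type == "gain"
             and min(c.end, 402_000) > max(c.start, 400_000)]
    assert losses and gains
    assert max(l.detection_layer for l in losses) > max(g.detection_layer for g in gains)


def test_calls_disjoint_sorted_and_band_consistent(noisy_step):
    calls = detect_cnvs(noisy_step, _small_params())
    for a, b in zip(calls, calls[1:]):
        assert a.end <= b.start
    for c in calls:
        assert c.end - c.start >= 100
        assert c.score >= 3.0
        if c.cnv_type == "gain":
            assert c.mean_value > c.baseline_mean
        else:
            assert c.mean_value < c.baseline_mean


def test_detector_param_validation():
    with pytest.raises(ValueError):
        DetectorParams(engine="gpu")


# ---------------------------------------------------------------------------
# Brute-force reference: literal three-condition enumeration
# ---------------------------------------------------------------------------

def brute_force_calls(cov, params):
    """Independent re-derivation of the call set from the dense image.

    Enumerates every adjacent opposite-sign crossing pair at every eligible
    layer (top down), applies the baseline-band condition with its own
    trimmed statistics, traces boundaries by exhaustive nearest-same-sign
    search, and enforces the region-exclusion rule.
    """
    filtered = median_filter(cov, params.median)
    img = build_scale_space(filtered, params.scale)
    fp = build_fingerprint_map(img)
    sigmas = fp.sigmas
    n, L = fp.n, fp.layers

    def trimmed(x):
        m, d = x.mean(), x.std()
        keep = np.abs(x - m) <= 2 * d
        if not keep.any():
            return m, d
        return x[keep].mean(), x[keep].std()

    def trace(pos, layer, sign):
        cur = pos
        for k in range(layer, 0, -1):
            radius = math.ceil(3 * sigmas[k])
            cands = [p for p in range(n) if fp.z[p, k - 1] == sign
                     and abs(p - cur) <= radius]
            if cands:
                cur = min(cands, key=lambda p: (abs(p - cur), p))
        return cur

    declared = []
    calls = []
    for k in range(L - 1, -1, -1):
        pos = np.flatnonzero(fp.z[:, k])
        if pos.size < 2:
            continue
        m_eff, d_eff = trimmed(img.layer(k))
        for a, b in zip(pos, pos[1:]):
            if fp.z[a, k] * fp.z[b, k] >= 0:
                continue
            mean = img.layer(k)[a : b + 1].mean()
            if mean > m_eff + params.d * d_eff:
                typ = "gain"
            elif mean < m_eff - params.d * d_eff:
                typ = "loss"
            else:
                continue
            l0 = trace(int(a), k, int(fp.z[a, k]))
            u0 = trace(int(b), k, int(fp.z[b, k]))
            if l0 >= u0:
                continue
            if any(l0 <= e and s <= u0 for s, e in declared):
                continue
            declared.append((l0, u0))
            calls.append((l0, u0 + 1, typ, k))
    calls = [c for c in calls if c[1] - c[0] >= params.min_call_length]
    return sorted(calls)


@pytest.mark.parametrize("seed", [11, 47])
def test_detect_matches_bruteforce_enumeration(seed):
    rng = np.random.default_rng(seed)
    lam = np.full(6000, 3.0)
    lam[1500:2300] *= 2.0
    lam[4000:4600] = 0.1
    cov = ReadCoverage("c", rng.poisson(lam))
    params = DetectorParams(
        median=MedianFilterParams(w=20),
        scale=ScaleParams(sigma0=40.0, ratio=1.25, layers=8),
        min_call_length=100, engine="dense")
    got = sorted((c.start, c.end, c.cnv_type, c.detection_layer)
                 for c in detect_cnvs(cov, params))
    assert got == brute_force_calls(cov, params)


def test_recovery_monotone_in_coverage():
    """Holding the planted CNV fixed, recovery improves with coverage."""
    from dataclasses import replace

    from cnvscale.evaluation import score_calls
    from cnvscale.simulator import GroundTruth, SimulationConfig, simulate_coverage

    truth = GroundTruth(regions=[(150_000, 170_000, "gain")])
    base = SimulationConfig(genome_length=400_000, error_rate=0.02)
    rates = []
    for C in (0.5, 1.0, 2.0, 3.0):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            cov = simulate_coverage(replace(base, coverage=C), truth, rng)
            calls = detect_cnvs(cov)
            res = score_calls(calls, truth, base.genome_length)
            hits += res.fnr <= 50.0  # majority of the event recovered
        rates.append(hits / 20)
    # non-decreasing up to binomial sampling error (2 * SE at p=0.5, n=20)
    slack = 2 * (0.25 / 20) ** 0.5
    for lo, hi in zip(rates, rates[1:]):
        assert hi >= lo - slack, rates
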
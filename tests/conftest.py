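import numpy as np
import pytest

from vqfunc import Hotspot, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def hotspot_phantom():
    """One seeded phantom with three airway-clumping hotspots (~0.5% of lung)."""
    spec = PhantomSpec(
        hotspots=(
            Hotspot(center=(20.0, 32.0, 40.0), radius_mm=8.0, intensity_multiple=30.0),
            Hotspot(center=(44.0, 30.0, 26.0), radius_mm=7.0, intensity_multiple=15.0),
            Hotspot(center=(20.0, 36.0, 24.0), radius_mm=6.0, intensity_multiple=45.0),
        ),
        shine_through_fraction=0.3,
        seed=7,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Hotspot-free phantom: uptake never exceeds mean + 4 SD materially."""
    spec = PhantomSpec(seed=11)
    return spec, generate_phantom(spec)


def naive_candidate_loop(values, sigma_multiplier=4.0, cutoff=0.99, max_iter=100):
    """Independent from-scratch reference for the convergence iteration.

    Each pass re-filters the ORIGINAL value array by the previous candidate
    (rather than carrying a retained subset forward) and recomputes mean and
    population SD from scratch. Returns (candidates, z_list, reduced, peak).
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    orig_max = vals.max()
    m, s = vals.mean(), vals.std()
    c = m + sigma_multiplier * s
    candidates, zs = [c], []
    if c >= orig_max or c >= cutoff * orig_max:
        return candidates, zs, False, float(orig_max)
    for _ in range(max_iter):
        retained = vals[vals <= c]
        m, s = retained.mean(), retained.std()
        c_new = m + sigma_multiplier * s
        z = c_new / c
        candidates.append(c_new)
        zs.append(z)
        if z > cutoff:
            return candidates, zs, True, float(c_new)
        c = c_new
    raise AssertionError("reference loop did not converge")


def random_uptake_sample(rng, n=None, outlier_fraction=None, outlier_scale=None):
    """Lognormal background with a controllable admixture of hotspot outliers."""
    if n is None:
        n = int(rng.integers(500, 10_001))
    if outlier_fraction is None:
        outlier_fraction = float(rng.uniform(0.0, 0.05))
    if outlier_scale is None:
        outlier_scale = float(rng.uniform(5.0, 100.0))
    sigma = float(rng.uniform(0.1, 0.6))
    vals = rng.lognormal(0.0, sigma, n)
    k = int(round(outlier_fraction * n))
    if k:
        idx = rng.choice(n, size=k, replace=False)
        vals[idx] = outlier_scale * vals.mean() * rng.uniform(0.8, 1.2, k)
    return vals
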
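import numpy as np
import pytest

from metasmd import effects_from_collection, load_gdf15_fixture


@pytest.fixture(scope="session")
def mrna_late():
    return load_gdf15_fixture("mRNA", "late")


@pytest.fixture(scope="session")
def mrna_middle():
    return load_gdf15_fixture("mRNA", "middle")


@pytest.fixture(scope="session")
def protein_late():
    return load_gdf15_fixture("protein", "late")


@pytest.fixture(scope="session")
def protein_middle():
    return load_gdf15_fixture("protein", "middle")


@pytest.fixture(scope="session")
def mrna_late_effects(mrna_late):
    return effects_from_collection(mrna_late)


@pytest.fixture(scope="session")
def protein_late_effects(protein_late):
    return effects_from_collection(protein_late)


@pytest.fixture(scope="session")
def protein_middle_effects(protein_middle):
    return effects_from_collection(protein_middle)


def dl_reference(theta, var):
    """Independent DerSimonian-Laird reference: statsmodels estimates Q and
    the moment tau^2 (clamped at 0 here), then plain inverse-variance
    combination on the random-effects weights."""
    import warnings

    from statsmodels.stats.meta_analysis import combine_effects

    theta = np.asarray(theta, dtype=float)
    var = np.asarray(var, dtype=float)
    with warnings.catch_warnings():
        # statsmodels leaves tau^2 unclamped; negative values raise sqrt warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        res = combine_effects(theta, var, method_re="dl")
    tau2 = max(0.0, float(res.tau2))
    w = 1.0 / (var + tau2)
    return {
        "pooled": float((w * theta).sum() / w.sum()),
        "se": float(1.0 / np.sqrt(w.sum())),
        "q_stat": float(res.q),
        "tau_squared": tau2,
        "pooled_fe": float(res.mean_effect_fe),
        "se_fe": float(res.sd_eff_w_fe),
    }


def random_effect_instances(seed, count, k_range=(2, 20)):
    """Random (theta, var) meta-analysis instances for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        theta = rng.normal(0.0, 1.0, size=k)
        var = rng.uniform(0.01, 0.5, size=k)
        out.append((theta, var))
    return out
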
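import numpy as np
import pytest

from pfce.trial_data import average_years, load_fixture_table


@pytest.fixture(scope="session")
def table_2023():
    return load_fixture_table("2023")


@pytest.fixture(scope="session")
def table_2024():
    return load_fixture_table("2024")


@pytest.fixture(scope="session")
def table_avg(table_2023, table_2024):
    return average_years([table_2023, table_2024])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_reciprocal_matrix(rng, n):
    """Random Saaty-scale reciprocal judgment matrix of order n."""
    scale = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = rng.choice(scale)
            if rng.random() < 0.5:
                v = 1.0 / v
            a[i, j] = v
            a[j, i] = 1.0 / v
    return a


def perturbed_consistent_matrix(rng, n, noise=0.25):
    """Random reciprocal matrix near consistency: b_ij = (w_i/w_j)·exp(ε)
    with antisymmetric lognormal perturbation.  This is the population the
    CR < 0.1 gate admits in practice."""
    w = rng.dirichlet(np.ones(n)) + 0.05
    w = w / w.sum()
    eps = rng.normal(0, noise, size=(n, n))
    eps = (eps - eps.T) / 2
    a = np.outer(w, 1.0 / w) * np.exp(eps)
    np.fill_diagonal(a, 1.0)
    return a


def power_iteration(a, iters=10_000, tol=1e-14):
    """Dominant eigenpair of a positive matrix (Perron–Frobenius)."""
    v = np.ones(a.shape[0]) / a.shape[0]
    lam = 0.0
    for _ in range(iters):
        w = a @ v
        lam_new = np.linalg.norm(w)
        w = w / lam_new
        if np.linalg.norm(w - v) < tol:
            v = w
            lam = lam_new
            break
        v, lam = w, lam_new
    v = v / v.sum()
    rayleigh = float((v @ a @ v) / (v @ v))
    return rayleigh, v
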
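import numpy as np
import pytest

from somacat.synthetic import simulate_catalogues, synthetic_signature_matrix


@pytest.fixture(scope="session")
def bundled_signatures():
    """The five bundled well-separated synthetic signatures (96 x 5)."""
    return synthetic_signature_matrix(k=5, seed=12345)


@pytest.fixture(scope="session")
def synthetic_cohort(bundled_signatures):
    """30 samples, Dirichlet(1) exposures, 2000 mutations each, fixed seed."""
    catalogues, truth = simulate_catalogues(
        bundled_signatures,
        n_samples=30,
        mutations_per_sample=2000,
        dirichlet_alpha=1.0,
        rng=np.random.default_rng(2024),
    )
    return catalogues, truth


def grid_search_simplex(b, S, final_step=0.001):
    """Independent nested grid-search oracle for the simplex QP.

    Enumerates mixing weights on a coarse simplex lattice, then refines
    locally around the incumbent until the lattice step reaches
    ``final_step``.  Derivative-free and independent of the QP route.
    """
    import itertools

    b = np.asarray(b, dtype=float)
    S = np.asarray(S, dtype=float)
    k = S.shape[1]

    def objective(w):
        r = S @ w - b
        return float(r @ r)

    def lattice(center, step, radius_steps):
        lo = np.maximum(center - step * radius_steps, 0.0)
        axes = [np.arange(0, 2 * radius_steps + 1) for _ in range(k - 1)]
        pts = []
        for combo in itertools.product(*axes):
            w = lo[:-1] + step * np.asarray(combo, dtype=float)
            s = w.sum()
            if s <= 1.0 + 1e-12:
                pts.append(np.append(w, max(1.0 - s, 0.0)))
        return pts

    # coarse global sweep over the whole simplex
    coarse = 0.05
    n_steps = int(round(1.0 / coarse))
    best_w, best_f = None, np.inf
    for combo in itertools.product(range(n_steps + 1), repeat=k - 1):
        if sum(combo) > n_steps:
            continue
        w = coarse * np.asarray(combo, dtype=float)
        w = np.append(w, 1.0 - w.sum())
        f = objective(w)
        if f < best_f:
            best_w, best_f = w, f
    step = coarse
    while step > final_step:
        step = max(step / 5.0, final_step)
        for w in lattice(best_w, step, 6):
            f = objective(w)
            if f < best_f:
                best_w, best_f = w, f
    return best_w, best_f
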
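import numpy as np
import pytest

from impact.screen import PhenotypeScreen


def build_screen(profiles: dict[str, list], parameter_names=None) -> PhenotypeScreen:
    """Assemble a screen from {gene: [profile values, ...]}."""
    values, genes, oligos = [], [], []
    for g, rows in profiles.items():
        for j, row in enumerate(rows):
            values.append(np.asarray(row, dtype=float))
            genes.append(g)
            oligos.append(f"{g}:{j}")
    values = np.asarray(values)
    names = parameter_names or [f"p{j}" for j in range(values.shape[1])]
    return PhenotypeScreen(values, genes, oligos, names)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def noisy_copies(base, n, sd, rng):
    base = np.asarray(base, dtype=float)
    return [base + rng.normal(0, sd, base.size) for _ in range(n)]


@pytest.fixture
def small_screen(rng):
    """6 genes x 40 params: A,B,C share a profile shape, D,E,F are noise."""
    shape = rng.normal(size=40)
    data = {}
    for g in "ABC":
        data[g] = noisy_copies(shape, 3, 0.1, rng)
    for g in "DEF":
        data[g] = [rng.normal(size=40) for _ in range(3)]
    return build_screen(data)
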
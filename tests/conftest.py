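import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cablehh.morphology import Section
from cablehh.solver import HinesSystem

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_parent_vector(rng, n, branch_max=4):
    """A random Hines-ordered tree: p[i] < i, at most branch_max children."""
    p = np.full(n, -1, dtype=np.int64)
    child_count = np.zeros(n, dtype=int)
    for i in range(1, n):
        candidates = np.flatnonzero(child_count[:i] < branch_max)
        j = int(rng.choice(candidates))
        p[i] = j
        child_count[j] += 1
    return p


def random_hines_system(rng, n, branch_max=4):
    """A diagonally dominant symmetric tree system on a random topology."""
    p = random_parent_vector(rng, n, branch_max)
    U = np.zeros(n)
    U[1:] = -rng.uniform(0.1, 10.0, size=n - 1)
    incident = np.zeros(n)
    for i in range(1, n):
        incident[i] += abs(U[i])
        incident[p[i]] += abs(U[i])
    D = incident + rng.uniform(0.05, 5.0, size=n)
    B = rng.normal(0.0, 1.0, size=n)
    return HinesSystem(p=p, D=D, U=U, B=B)


def random_section_tree(rng, max_sections=8, max_nseg=16):
    """A random valid tree of sections with positive geometry."""
    n_sections = int(rng.integers(1, max_sections + 1))
    sections = []
    for k in range(n_sections):
        parent = None
        if k > 0:
            j = int(rng.integers(0, k))
            parent = (f"sec{j}", "distal" if rng.random() < 0.5 else "proximal")
        sections.append(Section(
            name=f"sec{k}",
            length=float(rng.uniform(10.0, 400.0)),
            diameter=float(rng.uniform(0.5, 12.0)),
            nseg=int(rng.integers(1, max_nseg + 1)),
            Ra=float(rng.uniform(50.0, 300.0)),
            Cm=float(rng.uniform(0.5, 2.0)),
            channel_densities={"pas": 1e-4},
            parent=parent,
        ))
    return sections
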
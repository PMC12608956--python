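"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written directly from the verbal definitions of the
statistics, without importing the implementation under test, so the two
code paths share nothing but the boundary conventions they are both
specified to follow.
"""

from __future__ import annotations

import numpy as np


def clause_weight(a: float, b: float) -> float:
    """Banded agreement weight, transcribed clause by clause.

    Boundary conventions: "below t" means < t, "above 0.8" means > 0.8,
    "above 0.5" includes 0.5, "between x and y" includes x, and includes
    y only at 0.8 (so that 0.8 counts as between 0.2 and 0.8).
    """
    for x, y in ((a, b), (b, a)):
        if x > 0.8 and y < 0.2:
            return 0.0
        if 0.5 <= x <= 0.8 and y < 0.2:
            return 0.5
        if 0.2 <= x < 0.5 and y > 0.8:
            return 0.5
    if 0.2 <= a <= 0.8 and 0.2 <= b <= 0.8:
        return 1.0
    for x, y in ((a, b), (b, a)):
        if x > 0.8 and y >= 0.5:
            return 1.0
        if x < 0.2 and y < 0.5:
            return 1.0
    raise AssertionError(f"no clause matched ({a}, {b})")


def brute_agreement_rate(pairs) -> float:
    """Plain-loop average of clause weights."""
    total = 0.0
    n = 0
    for p in pairs:
        total += clause_weight(p.ratio_a, p.ratio_b)
        n += 1
    return total / n


def balanced_anova_components(values: np.ndarray, n_groups: int,
                              per_group: int) -> tuple[float, float]:
    """Textbook one-way ANOVA variance components for balanced data.

    ``values`` must be ordered group-major.  Returns (sigma_cond^2,
    sigma_res^2) with the between component truncated at zero.
    """
    y = np.asarray(values, dtype=float).reshape(n_groups, per_group)
    group_means = y.mean(axis=1)
    grand = y.mean()
    msb = per_group * ((group_means - grand) ** 2).sum() / (n_groups - 1)
    msw = ((y - group_means[:, None]) ** 2).sum() / (n_groups * (per_group - 1))
    return max(0.0, (msb - msw) / per_group), msw


def random_ratios(rng: np.random.Generator, n: int) -> np.ndarray:
    """Ratios spanning all bands, including exact band edges (k/20 grid)."""
    kind = rng.integers(0, 3, size=n)
    cont = rng.uniform(0, 1.6, size=n)
    grid = rng.integers(0, 32, size=n) / 20.0
    edges = rng.choice([0.0, 0.2, 0.5, 0.8, 1.0], size=n)
    return np.where(kind == 0, cont, np.where(kind == 1, grid, edges))
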
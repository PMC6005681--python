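"""Bootstrap group-difference test and Holm-Bonferroni correction.

The bootstrap controls for unequal per-animal unit counts: each iteration
samples a fixed number of values (default 30) without replacement from
every animal, averages within hearing-status group, and records the group
difference. The empirical two-tailed 98.75% CI of the resulting
distribution decides significance at p < 0.05 (zero outside the CI).
Standard tests (ANOVA, rank-sum, KS, t) are delegated to scipy/statsmodels
and not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroupComparison", "bootstrap_group_diff", "holm_bonferroni"]

CI_LEVEL = 0.9875


@dataclass
class GroupComparison:
    metric: str
    group_means: dict
    mean_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    per_animal: int
    significant: bool
    seed: int
    small_animals: list = field(default_factory=list)
    distribution: np.ndarray | None = field(default=None, repr=False)


def bootstrap_group_diff(
    values_by_animal: dict,
    groups: dict,
    n_boot: int = 10_000,
    per_animal: int = 30,
    seed: int = 0,
    metric: str = "",
    keep_distribution: bool = True,
) -> GroupComparison:
    """Bootstrap difference of group means over per-animal subsamples.

    Parameters
    ----------
    values_by_animal
        Mapping animal id -> 1-D array of the metric's per-unit values.
    groups
        Mapping animal id -> group label; exactly two labels expected.
        The difference is reported as first group minus second group, in
        sorted label order.
    per_animal
        Units drawn (without replacement) from each animal per iteration;
        animals with fewer values contribute all of them (recorded in
        ``small_animals``).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    by_group = {g: [a for a in values_by_animal if groups[a] == g] for g in labels}
    for g, animals in by_group.items():
        if not animals:
            raise ValueError(f"group {g!r} has no animals")
    arrays = {a: np.asarray(v, float) for a, v in values_by_animal.items()}
    small = [a for a, v in arrays.items() if v.size < per_animal]
    rng = np.random.default_rng(seed)

    # Pre-draw subsample means: (n_boot,) per animal
    animal_means = {}
    for a, v in arrays.items():
        k = min(per_animal, v.size)
        if k == v.size:
            animal_means[a] = np.full(n_boot, v.mean())
        else:
            keys = rng.random((n_boot, v.size))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            animal_means[a] = v[idx].mean(axis=1)
    g0 = np.mean([animal_means[a] for a in by_group[labels[0]]], axis=0)
    g1 = np.mean([animal_means[a] for a in by_group[labels[1]]], axis=0)
    diffs = g0 - g1
    alpha = 1.0 - CI_LEVEL
    ci_low, ci_high = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    significant = not (ci_low <= 0.0 <= ci_high)
    group_means = {
        labels[0]: float(np.mean([arrays[a].mean() for a in by_group[labels[0]]])),
        labels[1]: float(np.mean([arrays[a].mean() for a in by_group[labels[1]]])),
    }
    return GroupComparison(
        metric=metric, group_means=group_means, mean_diff=float(diffs.mean()),
        ci_low=float(ci_low), ci_high=float(ci_high), n_boot=n_boot,
        per_animal=per_animal, significant=bool(significant), seed=seed,
        small_animals=small,
        distribution=diffs if keep_distribution else None,
    )


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni rejection flags, in the input order.

    Sorts ascending and rejects p_(i) while p_(i) < alpha / (m - i + 1),
    stopping at the first failure.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] < alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject
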
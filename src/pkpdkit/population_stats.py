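"""Metabolizer-subpopulation detection and breed half-life statistics.

Subjects are split into extensive (EM) and poor (PM) metabolizers by an
exact two-means clustering of log half-lives; subgroup parameters are
compared with Welch's unpaired t-test; breed summaries use a one-way
fixed-effect ANOVA with Tukey HSD compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import InputError

__all__ = [
    "MetabolizerAssignment",
    "ClassificationResult",
    "SubgroupComparison",
    "BreedSummary",
    "classify_metabolizers",
    "compare_subgroups",
    "breed_anova",
    "fold_ratio",
]


@dataclass(frozen=True)
class MetabolizerAssignment:
    subject_id: str
    label: str  # "EM" | "PM"
    basis_halflife: float


@dataclass(frozen=True)
class ClassificationResult:
    assignments: tuple[MetabolizerAssignment, ...]
    bimodal: bool
    cluster_means: tuple[float, float]  # (EM, PM) half-life scale
    separation_ratio: float  # cluster gap / pooled within-cluster SD


@dataclass(frozen=True)
class SubgroupComparison:
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    p_value: float
    fold_ratio: float
    significant: bool
    parameter_name: str = ""


@dataclass(frozen=True)
class BreedSummary:
    breed: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv: float  # %
    letter_group: str


def fold_ratio(a: float, b: float) -> float:
    """Larger mean over smaller mean (dimensionless, >= 1)."""
    if a <= 0 or b <= 0:
        raise InputError("fold ratio requires positive values")
    return max(a, b) / min(a, b)


def _two_means_1d(x: np.ndarray) -> np.ndarray:
    """Exact 1-D two-means: best split point of the sorted values."""
    order = np.argsort(x)
    xs = x[order]
    best_cost, best_k = np.inf, 1
    for k in range(1, len(xs)):
        lo, hi = xs[:k], xs[k:]
        cost = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        if cost < best_cost:
            best_cost, best_k = cost, k
    labels = np.zeros(len(x), dtype=int)
    labels[order[best_k:]] = 1  # 1 = upper cluster
    return labels


def classify_metabolizers(
    halflives: Mapping[str, float],
) -> ClassificationResult:
    """Two-cluster split of log half-lives into EM (fast) and PM (slow).

    Subjects whose log half-life exceeds the midpoint of the two cluster
    centers are PM.  The split is flagged bimodal only when the center
    separation is at least twice the pooled within-cluster SD; otherwise
    all subjects keep their nearest-cluster label but the flag is False.
    """
    if len(halflives) < 4:
        raise InputError("need >= 4 subjects to classify")
    ids = list(halflives)
    hl = np.array([halflives[i] for i in ids], dtype=float)
    if np.any(hl <= 0):
        raise InputError("half-lives must be positive")
    logs = np.log(hl)

    if np.allclose(logs, logs[0]):
        assignments = tuple(
            MetabolizerAssignment(i, "EM", h) for i, h in zip(ids, hl)
        )
        m = float(np.exp(logs[0]))
        return ClassificationResult(assignments, False, (m, m), 0.0)

    labels = _two_means_1d(logs)
    c_lo, c_hi = logs[labels == 0].mean(), logs[labels == 1].mean()
    midpoint = 0.5 * (c_lo + c_hi)
    pm = logs > midpoint

    within = np.concatenate(
        [logs[labels == 0] - c_lo, logs[labels == 1] - c_hi]
    )
    dof = len(logs) - 2
    pooled_sd = float(np.sqrt(np.sum(within**2) / dof)) if dof > 0 else 0.0
    gap = c_hi - c_lo
    sep = gap / pooled_sd if pooled_sd > 0 else np.inf
    assignments = tuple(
        MetabolizerAssignment(i, "PM" if is_pm else "EM", h)
        for i, h, is_pm in zip(ids, hl, pm)
    )
    return ClassificationResult(
        assignments=assignments,
        bimodal=bool(sep >= 2.0),
        cluster_means=(float(np.exp(c_lo)), float(np.exp(c_hi))),
        separation_ratio=float(sep),
    )


def compare_subgroups(
    values_by_label: Mapping[str, Sequence[float]], parameter_name: str = ""
) -> SubgroupComparison:
    """Welch unpaired t-test between exactly two labeled groups."""
    if len(values_by_label) != 2:
        raise InputError("exactly two groups are required")
    (la, va), (lb, vb) = sorted(values_by_label.items())
    a = np.asarray(va, dtype=float)
    b = np.asarray(vb, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs n >= 2")
    means = (float(a.mean()), float(b.mean()))
    sds = (float(a.std(ddof=1)), float(b.std(ddof=1)))
    if sds[0] == 0.0 and sds[1] == 0.0:
        p = 1.0 if means[0] == means[1] else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    fr = fold_ratio(means[0], means[1]) if min(means) > 0 else float("nan")
    return SubgroupComparison(
        group_means=means,
        group_sds=sds,
        p_value=p,
        fold_ratio=fr,
        significant=bool(p < 0.05),
        parameter_name=parameter_name or f"{la}_vs_{lb}",
    )


def _compact_letters(groups: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Greedy insert-and-absorb over groups sorted as given."""
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) in nonsig_pairs for other in s):
                s.add(g)
                placed = True
        if not placed:
            # new letter: g plus every group not separated from it that fits mutually
            s = {g}
            for other in groups:
                if other != g and frozenset((g, other)) in nonsig_pairs:
                    if all(frozenset((other, m)) in nonsig_pairs for m in s):
                        s.add(other)
            letter_sets.append(s)
    # drop sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < other for j, other in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def breed_anova(
    halflives_by_breed: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    posthoc: bool = True,
) -> tuple[tuple[BreedSummary, ...], float]:
    """Per-breed descriptive summaries and one-way fixed-effect ANOVA.

    Returns the summaries (with CV in % and Tukey-HSD letter groups at
    ``alpha``) and the ANOVA p-value.
    """
    if len(halflives_by_breed) < 2:
        raise InputError("need >= 2 breeds")
    arrays = {b: np.asarray(v, dtype=float) for b, v in halflives_by_breed.items()}
    for b, v in arrays.items():
        if len(v) < 2:
            raise InputError(f"breed {b!r} needs n >= 2")

    p_value = float(stats.f_oneway(*arrays.values()).pvalue)

    breeds = list(arrays)
    letters = {b: "a" for b in breeds}
    if posthoc and len(breeds) > 1:
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[b] * len(arrays[b]) for b in breeds])
        if np.all(values == values[0]):
            nonsig = {frozenset(p) for p in zip(*np.triu_indices(len(breeds), 1))}
            letters = {b: "a" for b in breeds}
        else:
            tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
            nonsig = set()
            for row in tk.summary().data[1:]:
                g1, g2, reject = str(row[0]), str(row[1]), row[-1]
                if not reject:
                    nonsig.add(frozenset((g1, g2)))
            order = sorted(breeds, key=lambda b: arrays[b].mean())
            letters = _compact_letters(order, nonsig)

    summaries = []
    for b in breeds:
        v = arrays[b]
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        summaries.append(
            BreedSummary(
                breed=b,
                n=len(v),
                min=float(v.min()),
                max=float(v.max()),
                mean=mean,
                sd=sd,
                cv=float(sd / mean * 100.0) if mean != 0 else float("nan"),
                letter_group=letters.get(b, "a"),
            )
        )
    return tuple(summaries), p_value
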
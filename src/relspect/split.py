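"""Age-balanced stratified train/validation/test splitting.

Cases are stratified into the four sex-by-label subgroups; within each
subgroup the stated fractions are applied (largest-remainder rounding keeps
every subgroup's proportion within one case of its target in every set,
while the global set sizes hit the exact targets).  Many candidate splits
are drawn and the one minimizing an age-balance objective — the sum over
subgroups of the range (max - min) of mean ages across the three sets — is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["SplitAssignment", "stratified_split", "split_dataset", "StratificationError"]

SET_NAMES = ("train", "validation", "test")
#: train = 2/3 of all cases; the remaining third splits 1:2 into
#: validation and test.
DEFAULT_FRACTIONS = (2.0 / 3.0, 1.0 / 9.0, 2.0 / 9.0)


class StratificationError(ValueError):
    """A subgroup is too small to stratify."""


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive index sets plus the balance diagnostics."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    balance_report: dict = field(default_factory=dict)
    objective: float = np.nan
    candidate_index: int = 0

    @property
    def sizes(self):
        return (len(self.train_idx), len(self.val_idx), len(self.test_idx))

    def as_dict(self):
        return {
            "train": self.train_idx.tolist(),
            "validation": self.val_idx.tolist(),
            "test": self.test_idx.tolist(),
        }


def _largest_remainder(ideals: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(ideals).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(ideals - base))
        base[order[:short]] += 1
    return base


def _allocate(subgroup_sizes, set_targets, n):
    """Per-(subgroup, set) counts: rows sum to subgroup sizes, columns to
    the exact global set targets, each cell within ~1 of its ideal."""
    g, s = len(subgroup_sizes), len(set_targets)
    ideal = np.outer(subgroup_sizes, set_targets).astype(float) / n
    counts = np.floor(ideal).astype(int)
    row_need = np.asarray(subgroup_sizes) - counts.sum(axis=1)
    col_need = np.asarray(set_targets) - counts.sum(axis=0)
    frac = ideal - np.floor(ideal)
    order = np.dstack(np.unravel_index(np.argsort(-frac, axis=None), frac.shape))[0]
    for gi, si in order:
        if row_need[gi] > 0 and col_need[si] > 0:
            counts[gi, si] += 1
            row_need[gi] -= 1
            col_need[si] -= 1
    # any leftovers (rare): pair remaining row/column needs arbitrarily
    while row_need.sum() > 0:
        gi = int(np.argmax(row_need))
        si = int(np.argmax(col_need))
        counts[gi, si] += 1
        row_need[gi] -= 1
        col_need[si] -= 1
    return counts


def stratified_split(
    labels: Sequence,
    sexes: Sequence,
    ages: Sequence,
    fractions=DEFAULT_FRACTIONS,
    n_candidates: int = 100,
    seed: int = 0,
) -> SplitAssignment:
    """Draw ``n_candidates`` stratified splits and keep the age-balanced one.

    Stratification subgroups are the four sex-by-label combinations; the
    objective is the summed per-subgroup range of mean ages across the
    three sets.  Deterministic given ``seed``; with ``n_candidates=1`` the
    single candidate is returned regardless of balance.

    Raises
    ------
    StratificationError
        If any subgroup holds fewer than 3 cases.
    """
    labels = np.asarray(labels)
    sexes = np.asarray(sexes)
    ages = np.asarray(ages, dtype=float)
    n = len(labels)
    if not (len(sexes) == len(ages) == n):
        raise ValueError("labels, sexes, ages must have equal length")
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be three numbers summing to 1")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")

    keys = [f"{s}|{l}" for s, l in zip(sexes, labels)]
    subgroup_names = sorted(set(keys))
    subgroup_idx = {
        name: np.flatnonzero([k == name for k in keys]) for name in subgroup_names
    }
    for name, idx in subgroup_idx.items():
        if len(idx) < 3:
            raise StratificationError(
                f"subgroup '{name}' has only {len(idx)} cases (need >= 3)"
            )

    set_targets = _largest_remainder(fractions * n, n)
    sizes = [len(subgroup_idx[name]) for name in subgroup_names]
    counts = _allocate(sizes, set_targets, n)

    rng = np.random.default_rng(seed)
    best = None
    for cand in range(n_candidates):
        sets = {s: [] for s in SET_NAMES}
        for gi, name in enumerate(subgroup_names):
            perm = rng.permutation(subgroup_idx[name])
            off = 0
            for si, sname in enumerate(SET_NAMES):
                sets[sname].append(perm[off : off + counts[gi, si]])
                off += counts[gi, si]
        assignment = {s: np.sort(np.concatenate(v)) for s, v in sets.items()}
        objective = 0.0
        for name in subgroup_names:
            means = []
            for sname in SET_NAMES:
                members = np.intersect1d(assignment[sname], subgroup_idx[name])
                if len(members):
                    means.append(ages[members].mean())
            if len(means) >= 2:
                objective += max(means) - min(means)
        if best is None or objective < best[0]:
            best = (objective, cand, assignment)

    objective, cand, assignment = best
    report = {}
    for gi, name in enumerate(subgroup_names):
        report[name] = {}
        for sname in SET_NAMES:
            members = np.intersect1d(assignment[sname], subgroup_idx[name])
            report[name][sname] = {
                "n": int(len(members)),
                "mean_age": float(ages[members].mean()) if len(members) else None,
            }
    return SplitAssignment(
        train_idx=assignment["train"],
        val_idx=assignment["validation"],
        test_idx=assignment["test"],
        balance_report=report,
        objective=float(objective),
        candidate_index=int(cand),
    )


def split_dataset(dataset, fractions=DEFAULT_FRACTIONS, n_candidates=100, seed=0):
    """:func:`stratified_split` on a phantom :class:`LabeledDataset`."""
    return stratified_split(
        dataset.labels, dataset.sexes, dataset.ages, fractions, n_candidates, seed
    )
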
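"""Agreement, permutation tests, and consistency statistics.

Two categorizations of the same rhythms are compared by a raw
similarity score: the number of rhythms given the same category by
both.  Significance comes from a randomized permutation test — category
labels are reassigned uniformly at random and the score recomputed,
10,000 times by default — with the add-one convention
p = (1 + #{permuted >= observed}) / (1 + n) so p is never exactly zero.
Two-tailed p-values double the smaller tail (capped at 1); an
extreme-count variant measures two-sidedness as distance from the
permutation mean.

Consistency of a categorical response distribution is its relative
entropy: Shannon entropy divided by the maximum attainable, log k over
the k available categories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .categorize import Categorization, CategoryLabel, EXCLUDED
from .errors import UndefinedCorrelationError, ValidationError

__all__ = [
    "AgreementResult", "PermutationResult",
    "agreement", "permutation_test", "relative_entropy",
    "snr_entropy_correlation", "load_behavioral_labels",
    "load_behavioral_entropy", "write_permutation_json",
]


@dataclass(frozen=True)
class AgreementResult:
    """Raw agreement after exclusions."""
    n_compared: int
    n_agree: int

    @property
    def fraction(self) -> float:
        return self.n_agree / self.n_compared

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    n_permutations: int
    p_value: float
    tail: str
    seed: int
    n_compared: int


def _paired_labels(a: Categorization, b: Categorization,
                   exclusions: Iterable[str] = ()) -> tuple[list, list]:
    ids_a, ids_b = set(a.ids), set(b.ids)
    if ids_a != ids_b:
        raise ValidationError("categorizations cover different rhythm id sets")
    excluded = set(exclusions)
    la, lb = [], []
    for rid in a.ids:
        xa, xb = a.label_of(rid), b.label_of(rid)
        if rid in excluded or xa == EXCLUDED or xb == EXCLUDED:
            continue
        la.append(xa)
        lb.append(xb)
    if not la:
        raise ValidationError("no rhythms left after exclusions")
    return la, lb


def agreement(a: Categorization, b: Categorization,
              exclusions: Iterable[str] = ()) -> AgreementResult:
    """Count rhythms assigned the same category by both, dropping any in
    ``exclusions`` or marked excluded in either input.  Symmetric."""
    la, lb = _paired_labels(a, b, exclusions)
    return AgreementResult(len(la), sum(x == y for x, y in zip(la, lb)))


def permutation_test(a: Categorization, b: Categorization,
                     n: int = 10_000, tail: str = "two", seed: int = 0,
                     exclusions: Iterable[str] = (),
                     tail_method: str = "double") -> PermutationResult:
    """Randomized permutation test of label agreement.

    The labels of ``b`` are reassigned uniformly at random ``n`` times
    (by symmetry it does not matter which side is permuted) and the
    agreement score recomputed each time.  One-tailed
    p = (1 + #{score >= observed}) / (1 + n); two-tailed either doubles
    the smaller tail capped at 1 (``tail_method="double"``) or counts
    permutations at least as far from the permutation mean
    (``"extreme_count"``).  Fully determined by ``seed``.
    """
    if n < 1:
        raise ValidationError("need at least one permutation")
    la, lb = _paired_labels(a, b, exclusions)
    if len(la) <= 1:
        raise ValidationError("degenerate input: need more than one rhythm")
    # integer-encode so the permutation loop is pure numpy
    uniq = {lab: i for i, lab in enumerate(dict.fromkeys(la + lb))}
    xa = np.array([uniq[l] for l in la])
    xb = np.array([uniq[l] for l in lb])
    observed = int((xa == xb).sum())

    rng = np.random.default_rng(seed)
    m = xa.size
    scores = np.empty(n, dtype=np.int64)
    for i in range(n):
        scores[i] = int((xa == xb[rng.permutation(m)]).sum())

    upper = (1 + int((scores >= observed).sum())) / (1 + n)
    if tail == "one":
        p = upper
    elif tail == "two":
        if tail_method == "double":
            lower = (1 + int((scores <= observed).sum())) / (1 + n)
            p = min(1.0, 2 * min(upper, lower))
        elif tail_method == "extreme_count":
            center = scores.mean()
            dev = abs(observed - center)
            p = (1 + int((np.abs(scores - center) >= dev - 1e-12).sum())) / (1 + n)
        else:
            raise ValidationError("tail_method must be double|extreme_count")
    else:
        raise ValidationError("tail must be one|two")
    return PermutationResult(observed, n, float(p), tail, seed, m)


def relative_entropy(counts: Sequence[float], k: int | None = None) -> float:
    """Shannon entropy of the empirical distribution over categories,
    divided by log k, the maximum attainable with k available
    categories (k defaults to len(counts)); 0 log 0 := 0."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 0):
        raise ValidationError("counts must be nonnegative and nonempty")
    total = c.sum()
    if total <= 0:
        raise ValidationError("counts sum to zero")
    k = k if k is not None else c.size
    if k < 2:
        raise ValidationError("need at least two available categories")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log(k)


def snr_entropy_correlation(snr_table: pd.DataFrame,
                            entropy_table: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) between model SNR and externally
    supplied behavioral relative-entropy values, paired on rhythm grid
    coordinates.  Exists for replication against behavioral maps; the
    predicted sign is negative (distinct states -> consistent choices).
    """
    merged = snr_table.merge(entropy_table, on=["k1", "k2", "k3"])
    if len(merged) < 3:
        raise ValidationError("need at least 3 paired values")
    x = merged["snr"].to_numpy(dtype=float)
    y = merged["rel_entropy"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one variable")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def load_behavioral_labels(path: str | Path,
                           condition_name: str = "none") -> Categorization:
    """Load a human category map CSV with columns k1, k2, k3, label;
    an empty/missing label marks the rhythm excluded (its modal human
    choice was not one of the prototype categories)."""
    from .stimuli import meter_condition
    df = pd.read_csv(path)
    assignments: dict[str, CategoryLabel | str] = {}
    for row in df.itertuples():
        rid = f"{int(row.k1)}-{int(row.k2)}-{int(row.k3)}"
        lab = getattr(row, "label", None)
        if lab is None or (isinstance(lab, float) and np.isnan(lab)) or str(lab) == "":
            assignments[rid] = EXCLUDED
        else:
            assignments[rid] = CategoryLabel(tuple(int(x) for x in str(lab).split("-")))
    return Categorization(assignments, meter_condition(condition_name))


def load_behavioral_entropy(path: str | Path) -> pd.DataFrame:
    """Load a consistency map CSV with columns k1, k2, k3, rel_entropy."""
    df = pd.read_csv(path)
    missing = {"k1", "k2", "k3", "rel_entropy"} - set(df.columns)
    if missing:
        raise ValidationError(f"entropy CSV missing columns {sorted(missing)}")
    return df


def write_permutation_json(result: PermutationResult, path: str | Path,
                           exclusions: Iterable[str] = ()) -> None:
    payload = asdict(result)
    payload["exclusions"] = sorted(exclusions)
    Path(path).write_text(json.dumps(payload, indent=2))
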
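"""Prototype-based categorization of rhythms.

Each named category is an integer-ratio rhythm (1-2-1 -> IOIs 0.25,
0.5, 0.25 s).  Running a category's exact rhythm through the no-meter
pipeline yields its *prototype activation pattern*; an arbitrary rhythm
is then assigned the category whose prototype pattern is nearest in
Euclidean state space (one dimension per oscillator).  Patterns are not
normalized before the distance — Euclidean distance here is
deliberately scale-sensitive.

The default 12-category list ships as a data file
(``data/prototypes.csv``): the identities of the most common human
transcription categories are an empirical input, so they live in data
rather than code.  Entries whose membership in the original
twelve could not be confirmed are flagged ``verified=no`` in the file;
the classifier is agnostic to the list's content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activation import ActivationPattern
from .config import ModelConfig
from .errors import ValidationError
from .stimuli import MeterCondition, NO_METER, RhythmSequence

__all__ = [
    "CategoryLabel", "PrototypeSet", "Categorization", "EXCLUDED",
    "default_category_labels", "load_prototype_labels", "prototype_rhythm",
    "build_prototypes", "classify", "categorize_condition",
    "convexity_report", "write_category_csv", "read_category_csv",
]

EXCLUDED = "excluded"


@dataclass(frozen=True, order=True)
class CategoryLabel:
    """An integer-ratio rhythm category, canonicalized by the gcd of its
    ratio entries (2-2-2 and 1-1-1 are the same category)."""
    ratio: tuple[int, int, int]
    display: str = field(default="", compare=False)

    def __post_init__(self):
        if len(self.ratio) != 3 or any(r < 1 for r in self.ratio):
            raise ValidationError("category ratio needs three integers >= 1")
        g = math.gcd(math.gcd(self.ratio[0], self.ratio[1]), self.ratio[2])
        canon = tuple(r // g for r in self.ratio)
        object.__setattr__(self, "ratio", canon)
        if not self.display:
            object.__setattr__(self, "display", "-".join(map(str, canon)))


@dataclass(frozen=True)
class PrototypeSet:
    """Ordered category -> activation-pattern anchors; order is the
    deterministic tie-break for classification."""
    labels: tuple[CategoryLabel, ...]
    patterns: np.ndarray                 # (n_categories, n_oscillators)
    frequencies: np.ndarray
    source_condition: MeterCondition = NO_METER

    def __post_init__(self):
        p = np.asarray(self.patterns, dtype=float)
        if p.shape[0] != len(self.labels):
            raise ValidationError("one pattern per label required")
        object.__setattr__(self, "patterns", p)

    @property
    def n(self) -> int:
        return len(self.labels)

    def pattern_for(self, label: CategoryLabel) -> np.ndarray:
        return self.patterns[self.labels.index(label)]


@dataclass(frozen=True)
class Categorization:
    """Rhythm id -> category label (or the excluded marker) under one
    meter condition."""
    assignments: Mapping[str, CategoryLabel | str]
    condition: MeterCondition

    def label_of(self, rhythm_id: str) -> CategoryLabel | str:
        return self.assignments[rhythm_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def modal_label(self) -> CategoryLabel:
        """Most frequent non-excluded label; ties -> smallest ratio."""
        counts: dict[CategoryLabel, int] = {}
        for lab in self.assignments.values():
            if lab != EXCLUDED:
                counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            raise ValidationError("no non-excluded assignments")
        return min(counts, key=lambda lab: (-counts[lab], lab.ratio))


def default_category_labels() -> list[CategoryLabel]:
    """The shipped 12-category list (see module docstring)."""
    with resources.files("rhythmcat.data").joinpath("prototypes.csv").open() as fh:
        return _labels_from_frame(pd.read_csv(fh))


def load_prototype_labels(path: str | Path) -> list[CategoryLabel]:
    """Load a prototype list CSV with columns r1, r2, r3, display."""
    return _labels_from_frame(pd.read_csv(path))


def _labels_from_frame(df: pd.DataFrame) -> list[CategoryLabel]:
    return [CategoryLabel((int(r.r1), int(r.r2), int(r.r3)), str(r.display))
            for r in df.itertuples()]


def prototype_rhythm(label: CategoryLabel, total: float = 1.0) -> RhythmSequence:
    """Exact integer-ratio rhythm for a category: IOI_j = total r_j / sum r."""
    s = sum(label.ratio)
    return RhythmSequence(tuple(total * r / s for r in label.ratio),
                          label=f"proto:{label.display}")


def build_prototypes(labels: Sequence[CategoryLabel] | None = None,
                     config: ModelConfig | None = None) -> PrototypeSet:
    """Run each category's exact rhythm through the no-meter pipeline.

    Prototypes are always generated without metric priming, matching how
    the category anchors were defined; deterministic.
    """
    from .pipeline import condition_activation_matrix
    config = config or ModelConfig()
    labels = tuple(labels if labels is not None else default_category_labels())
    rhythms = [prototype_rhythm(lab, config.trial.bar_s) for lab in labels]
    mat = condition_activation_matrix(rhythms, NO_METER, config)
    return PrototypeSet(labels, mat.values, mat.frequencies, NO_METER)


def _distances(values: np.ndarray, prototypes: PrototypeSet,
               metric: str) -> np.ndarray:
    diffs = prototypes.patterns - values[np.newaxis, :]
    if metric == "euclidean":
        return np.sqrt((diffs**2).sum(axis=1))
    if metric == "cosine":
        num = prototypes.patterns @ values
        den = (np.linalg.norm(prototypes.patterns, axis=1)
               * np.linalg.norm(values))
        return 1 - num / den
    raise ValidationError(f"unknown metric {metric!r}")


def classify(pattern: ActivationPattern, prototypes: PrototypeSet,
             metric: str = "euclidean") -> CategoryLabel:
    """Nearest-prototype label; ties break to the earliest listed."""
    if pattern.n != prototypes.patterns.shape[1]:
        raise ValidationError("pattern and prototype dimensionality differ")
    d = _distances(pattern.values, prototypes, metric)
    return prototypes.labels[int(np.argmin(d))]  # argmin takes first on ties


def categorize_condition(rhythms: Sequence[RhythmSequence],
                         condition: MeterCondition,
                         prototypes: PrototypeSet,
                         config: ModelConfig | None = None) -> Categorization:
    """Classify every rhythm of a condition against the (no-meter)
    prototype set.  The meter condition changes only the trial
    construction; the model always produces a nearest prototype, so no
    rhythm is excluded on the model side."""
    from .pipeline import condition_activation_matrix
    config = config or ModelConfig()
    mat = condition_activation_matrix(rhythms, condition, config)
    metric = config.distance.metric
    assignments = {}
    for r, values in zip(rhythms, mat.values):
        d = _distances(values, prototypes, metric)
        assignments[r.id] = prototypes.labels[int(np.argmin(d))]
    return Categorization(assignments, condition)


def _barycentric_xy(units: np.ndarray) -> np.ndarray:
    """Project (k1,k2,k3) simplex points to the plane of the triangle."""
    total = units.sum(axis=1, keepdims=True)
    p = units / total
    x = p[:, 1] + 0.5 * p[:, 2]
    y = (np.sqrt(3) / 2) * p[:, 2]
    return np.column_stack([x, y])


def convexity_report(categorization: Categorization,
                     rhythms: Sequence[RhythmSequence],
                     n_segment_samples: int = 64) -> pd.DataFrame:
    """Per-category convexity fraction over the triangular grid.

    For every pair of same-label grid points, sample the straight
    segment between them in the 2-simplex, snap each sample to the
    nearest grid point, and check the path never leaves the label's
    region.  The fraction of fully inside pairs is a soft diagnostic of
    how convex the category region is (1.0 for filled-convex regions,
    < 1.0 for disconnected islands).
    """
    units = np.array([r.grid_units for r in rhythms], dtype=float)
    if np.any(units == None):  # noqa: E711 - grid rhythms only
        raise ValidationError("convexity_report needs grid rhythms with units")
    xy = _barycentric_xy(units)
    labels = [categorization.label_of(r.id) for r in rhythms]
    uniq = sorted({lab for lab in labels if lab != EXCLUDED})
    t = np.linspace(0, 1, n_segment_samples)[:, np.newaxis]
    rows = []
    for lab in uniq:
        idx = [i for i, l in enumerate(labels) if l == lab]
        pairs = inside = 0
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                a, b = idx[a_pos], idx[b_pos]
                seg = xy[a] + t * (xy[b] - xy[a])          # (S, 2)
                d2 = ((seg[:, np.newaxis, :] - xy[np.newaxis, :, :])**2).sum(-1)
                nearest = d2.argmin(axis=1)
                pairs += 1
                inside += all(labels[j] == lab for j in nearest)
        rows.append({"label": lab.display, "n_points": len(idx),
                     "n_pairs": pairs,
                     "convex_fraction": inside / pairs if pairs else 1.0})
    return pd.DataFrame(rows)


def write_category_csv(categorization: Categorization,
                       rhythms: Sequence[RhythmSequence],
                       path: str | Path) -> None:
    """Category map CSV: id, k1, k2, k3, label, excluded."""
    rows = []
    for r in rhythms:
        lab = categorization.label_of(r.id)
        k = r.grid_units or (np.nan, np.nan, np.nan)
        rows.append({"id": r.id, "k1": k[0], "k2": k[1], "k3": k[2],
                     "label": "" if lab == EXCLUDED else lab.display,
                     "excluded": lab == EXCLUDED})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_category_csv(path: str | Path,
                      condition: MeterCondition = NO_METER) -> Categorization:
    df = pd.read_csv(path)
    assignments: dict[str, CategoryLabel | str] = {}
    for row in df.itertuples():
        if bool(row.excluded) or (isinstance(row.label, float) and np.isnan(row.label)):
            assignments[str(row.id)] = EXCLUDED
        else:
            ratio = tuple(int(x) for x in str(row.label).split("-"))
            assignments[str(row.id)] = CategoryLabel(ratio)
    return Categorization(assignments, condition)
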
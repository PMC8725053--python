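"""Core data containers for survey screening.

All detection indices and the boosted-tree classifier operate on a
:class:`ResponseMatrix` (respondent x item integer categories), optionally
paired with a :class:`RTMatrix` of item-level response times, under a
:class:`ScaleDesign` describing the questionnaire layout (construct
membership, reversed wording, page size).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScaleDesign",
    "ResponseMatrix",
    "RTMatrix",
    "LabeledDataset",
    "StudyConfig",
    "ValidationError",
    "recode_reversed",
]


class ValidationError(ValueError):
    """Raised when survey data violates the scale design contract."""


@dataclass(frozen=True)
class ScaleDesign:
    """Questionnaire layout: items, categories, constructs, reversed wording.

    Parameters
    ----------
    n_items : int
        Number of items J.
    n_categories : int
        Number of ordered response options K (categories are 1..K).
    constructs : ndarray of int, shape (n_items,)
        Construct (subscale) id of each item.
    reversed_items : ndarray of bool, shape (n_items,)
        True where the item is negatively worded and must be recoded
        (x -> K+1-x) before consistency or distance analyses.
    page_size : int
        Items per survey page; response-time parcels aggregate over pages.
    """

    n_items: int
    n_categories: int
    constructs: np.ndarray
    reversed_items: np.ndarray
    page_size: int = 10

    def __post_init__(self) -> None:
        constructs = np.asarray(self.constructs)
        rev = np.asarray(self.reversed_items, dtype=bool)
        object.__setattr__(self, "constructs", constructs)
        object.__setattr__(self, "reversed_items", rev)
        if constructs.shape != (self.n_items,):
            raise ValidationError(
                f"constructs has shape {constructs.shape}, expected ({self.n_items},)"
            )
        if rev.shape != (self.n_items,):
            raise ValidationError(
                f"reversed_items has shape {rev.shape}, expected ({self.n_items},)"
            )
        if self.n_categories <= 1:
            raise ValidationError("n_categories must exceed 1")
        if self.page_size <= 0:
            raise ValidationError("page_size must be positive")

    @classmethod
    def hexaco_like(
        cls,
        n_constructs: int = 6,
        items_per_construct: int = 10,
        n_categories: int = 5,
        reversed_fraction: float = 0.5,
        page_size: int = 10,
    ) -> "ScaleDesign":
        """Six-construct, 60-item layout mirroring a HEXACO-60-style inventory.

        Within each construct, every second item is flagged as reversed until
        ``reversed_fraction`` of its items is reached.
        """
        n_items = n_constructs * items_per_construct
        constructs = np.repeat(np.arange(n_constructs), items_per_construct)
        n_rev = int(round(reversed_fraction * items_per_construct))
        rev_within = np.zeros(items_per_construct, dtype=bool)
        rev_within[1 : 2 * n_rev : 2] = True
        reversed_items = np.tile(rev_within, n_constructs)
        return cls(n_items, n_categories, constructs, reversed_items, page_size)

    @property
    def construct_ids(self) -> np.ndarray:
        return np.unique(self.constructs)

    def items_of(self, construct) -> np.ndarray:
        """Column indices of the items belonging to one construct."""
        return np.flatnonzero(self.constructs == construct)

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "n_categories": self.n_categories,
            "constructs": self.constructs.tolist(),
            "reversed": self.reversed_items.astype(int).tolist(),
            "page_size": self.page_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleDesign":
        return cls(
            n_items=int(d["n_items"]),
            n_categories=int(d["n_categories"]),
            constructs=np.asarray(d["constructs"], dtype=int),
            reversed_items=np.asarray(d["reversed"], dtype=bool),
            page_size=int(d.get("page_size", 10)),
        )


@dataclass(frozen=True)
class ResponseMatrix:
    """n x J grid of integer Likert responses in 1..K; no missing entries."""

    values: np.ndarray
    respondent_ids: np.ndarray | None = None
    item_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("response values must be 2-D (respondents x items)")
        if not np.issubdtype(values.dtype, np.integer):
            flt = np.asarray(values, dtype=float)
            if np.isnan(flt).any():
                i, j = np.argwhere(np.isnan(flt))[0]
                raise ValidationError(f"missing response at row {i}, column {j}")
            if not np.allclose(flt, np.round(flt)):
                raise ValidationError("responses must be integer categories")
            values = flt.astype(np.int64)
        object.__setattr__(self, "values", values)
        if self.respondent_ids is None:
            object.__setattr__(self, "respondent_ids", np.arange(values.shape[0]))
        else:
            object.__setattr__(self, "respondent_ids", np.asarray(self.respondent_ids))
        if self.item_ids is None:
            object.__setattr__(
                self, "item_ids", np.array([f"item{j+1}" for j in range(values.shape[1])])
            )
        else:
            object.__setattr__(self, "item_ids", np.asarray(self.item_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def validate(self, design: ScaleDesign) -> "ResponseMatrix":
        """Check shape and category range against a design; return self."""
        if self.n_items != design.n_items:
            raise ValidationError(
                f"matrix has {self.n_items} item columns, design expects {design.n_items}"
            )
        bad = (self.values < 1) | (self.values > design.n_categories)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"response {self.values[i, j]} outside 1..{design.n_categories} "
                f"at row {i} (id {self.respondent_ids[i]}), column {j} "
                f"(item {self.item_ids[j]})"
            )
        return self


@dataclass(frozen=True)
class RTMatrix:
    """n x J item-level response times in seconds; strictly positive."""

    values: np.ndarray
    respondent_ids: np.ndarray | None = None
    item_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("RT values must be 2-D (respondents x items)")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(f"missing response time at row {i}, column {j}")
        if (values <= 0).any():
            i, j = np.argwhere(values <= 0)[0]
            raise ValidationError(f"non-positive response time at row {i}, column {j}")
        object.__setattr__(self, "values", values)
        if self.respondent_ids is None:
            object.__setattr__(self, "respondent_ids", np.arange(values.shape[0]))
        else:
            object.__setattr__(self, "respondent_ids", np.asarray(self.respondent_ids))
        if self.item_ids is None:
            object.__setattr__(
                self, "item_ids", np.array([f"item{j+1}" for j in range(values.shape[1])])
            )
        else:
            object.__setattr__(self, "item_ids", np.asarray(self.item_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabeledDataset:
    """Responses (+ optional response times) with careless/regular labels.

    ``labels`` is 1 for careless (the positive class throughout) and 0 for
    regular respondents; ``styles`` tags each careless respondent with the
    generating style ('random', 'midpoint', 'pattern', 'empirical') and is
    the empty string for regular respondents.
    """

    responses: ResponseMatrix
    labels: np.ndarray
    rt: RTMatrix | None = None
    styles: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.responses.n,):
            raise ValidationError("labels length must equal number of respondents")
        if not np.isin(labels, [0, 1]).all():
            raise ValidationError("labels must be binary 0/1")
        if self.rt is not None and self.rt.values.shape != self.responses.values.shape:
            raise ValidationError("RT matrix shape must match response matrix")
        if self.styles is None:
            styles = np.where(labels == 1, "unknown", "")
            object.__setattr__(self, "styles", np.asarray(styles, dtype=object))
        else:
            styles = np.asarray(self.styles, dtype=object)
            object.__setattr__(self, "styles", styles)
            if styles.shape != (self.responses.n,):
                raise ValidationError("styles length must equal number of respondents")
            tagged = np.array([bool(s) for s in styles])
            if (tagged & (labels == 0)).any():
                raise ValidationError("style tags are only allowed on careless rows")

    @property
    def n(self) -> int:
        return self.responses.n


_KNOWN_STYLES = ("random", "midpoint", "pattern", "empirical")

_CONFIG_DEFAULTS = dict(
    prevalence=0.10,
    style="random",
    n_train=425,
    n_test=180,
    test_fraction=0.30,
    test_ratio=9.0,
    replications=100,
    seed=1234,
    zh_cutoff=-1.96,
    antonym_r_crit=-0.20,
    longstring_cutoff=6,
    irv_percentiles=(5.0, 95.0),
    evenodd_cutoff=0.30,
    mahalanobis_alpha=0.05,
)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulated or emulated detection study.

    Defaults reproduce the benchmark condition: 10% careless prevalence,
    random style, test samples of 180 respondents and training samples of
    425 respondents.
    """

    prevalence: float = _CONFIG_DEFAULTS["prevalence"]
    style: str = _CONFIG_DEFAULTS["style"]
    n_train: int = _CONFIG_DEFAULTS["n_train"]
    n_test: int = _CONFIG_DEFAULTS["n_test"]
    test_fraction: float = _CONFIG_DEFAULTS["test_fraction"]
    test_ratio: float = _CONFIG_DEFAULTS["test_ratio"]
    replications: int = _CONFIG_DEFAULTS["replications"]
    seed: int = _CONFIG_DEFAULTS["seed"]
    zh_cutoff: float = _CONFIG_DEFAULTS["zh_cutoff"]
    antonym_r_crit: float = _CONFIG_DEFAULTS["antonym_r_crit"]
    longstring_cutoff: int = _CONFIG_DEFAULTS["longstring_cutoff"]
    irv_percentiles: tuple = _CONFIG_DEFAULTS["irv_percentiles"]
    evenodd_cutoff: float = _CONFIG_DEFAULTS["evenodd_cutoff"]
    mahalanobis_alpha: float = _CONFIG_DEFAULTS["mahalanobis_alpha"]
    tuning_grid: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(f"prevalence {self.prevalence} outside (0, 1)")
        if self.style not in _KNOWN_STYLES:
            raise ValidationError(
                f"unknown style {self.style!r}; expected one of {_KNOWN_STYLES}"
            )
        if self.replications < 1:
            raise ValidationError("replications must be >= 1")
        if not 0.0 < self.mahalanobis_alpha < 1.0:
            raise ValidationError("mahalanobis_alpha outside (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = set(_CONFIG_DEFAULTS) | {"tuning_grid"}
        unknown = set(d) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in d.items() if k in known}
        if "irv_percentiles" in kwargs:
            kwargs["irv_percentiles"] = tuple(kwargs["irv_percentiles"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _CONFIG_DEFAULTS}
        d["irv_percentiles"] = list(self.irv_percentiles)
        d["tuning_grid"] = self.tuning_grid
        return d

    def replace(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)

    def digest(self) -> str:
        """Stable hash of the configuration, for run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def recode_reversed(X: ResponseMatrix, design: ScaleDesign) -> ResponseMatrix:
    """Reflect negatively worded items: x -> K+1-x on reversed columns.

    Apply exactly once before Mahalanobis and even-odd analyses; applying
    the same flag set twice restores the original matrix.
    """
    X.validate(design)
    values = X.values.copy()
    rev = design.reversed_items
    values[:, rev] = design.n_categories + 1 - values[:, rev]
    return ResponseMatrix(values, X.respondent_ids, X.item_ids)
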
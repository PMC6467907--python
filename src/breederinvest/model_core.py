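"""Core equations of the maternal risk-management model of breeder investment.

The model scores every species on two axes measured per breeding event:
offspring quantity ``N`` and relative offspring quality ``S = m/M`` (mass of
one offspring at dispersal over the mass of the breeding female).  Quantity
maps onto the probability of offspring mortality by predation,

    P = 1 - w/N,

where ``w`` is replacement fitness — the survival of at least two fertile
offspring (one daughter, one outbreeding son), treated as a constant ``w = 2``
across species.  ``S`` doubles as the modelled probability of offspring
mortality by spatiotemporal resource scarcity.  User-chosen set points on
``S`` and ``N`` partition the investment plane into four natural-selection
categories:

===========  ===========  ==========
 category     S            N
===========  ===========  ==========
 predation    <= s_set     >  n_set
 scarcity     >  s_set     <= n_set
 weak         <= s_set     <= n_set
 convergent   >  s_set     >  n_set
===========  ===========  ==========

For species whose broods carry per-offspring masses, a bias-corrected
rank-form Gini coefficient ``G`` quantifies inequality of maternal investment
within the brood (0 = equal shares, 1 = one offspring holds all mass), and the
convergent-selection index is the joint mortality product ``C = P * S``.

Species breeding one offspring per event would make ``P`` negative; for them
``N`` is replaced by a substitute value just above ``w`` (default 2.1) before
``P`` is computed, and the substitution is flagged, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidInputError",
    "DomainError",
    "DegenerateBroodError",
    "ConfigError",
    "Category",
    "ModelParams",
    "SpeciesRecord",
    "BroodProfile",
    "ClassificationResult",
    "predation_mortality",
    "relative_quality",
    "gini",
    "gini_rank_form",
    "brood_profile",
    "convergent_index",
    "apply_singleton_rule",
    "category_for",
    "classify",
    "map_to_legacy",
    "summarize_by_taxon",
]


class InvalidInputError(ValueError):
    """An argument violates a precondition of the model."""


class DomainError(InvalidInputError):
    """An argument is outside the mathematical domain of an equation."""


class DegenerateBroodError(InvalidInputError):
    """A brood whose total mass is zero; inequality is undefined."""


class ConfigError(ValueError):
    """A configuration document or generator setting is inconsistent."""


class Category(str, Enum):
    """The four natural-selection categories of the investment plane."""

    PREDATION = "predation"
    SCARCITY = "scarcity"
    WEAK = "weak"
    CONVERGENT = "convergent"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Mapping from each category to its closest counterpart in r/K selection and
#: in Grime's CSR scheme.  ``None`` means the legacy theory has no analogue.
_LEGACY_MAP: dict[Category, tuple[Optional[str], Optional[str]]] = {
    Category.SCARCITY: ("r-selection", "S-selection"),
    Category.WEAK: ("K-selection", "C-selection"),
    Category.PREDATION: (None, "R-selection"),
    Category.CONVERGENT: (None, None),
}


@dataclass(frozen=True)
class ModelParams:
    """Model constants and classification set points.

    Parameters
    ----------
    w
        Replacement fitness: the number of fertile offspring that must survive
        to the next generation for the breeder line to persist.  Dimensionless
        count, default 2 (one daughter, one outbreeding son).
    s_setpoint
        Threshold on relative offspring quality ``S`` separating small from
        large per-offspring investment.  Default 0.1.
    n_setpoint
        Threshold on offspring quantity ``N`` separating small from large
        broods.  Default 10.
    n_substitute
        Effective ``N`` used for broods smaller than ``w`` so that the
        predation-mortality probability stays positive.  Must exceed ``w``;
        default 2.1.
    """

    w: float = 2.0
    s_setpoint: float = 0.1
    n_setpoint: float = 10.0
    n_substitute: float = 2.1

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise InvalidInputError(f"replacement fitness w must be > 0, got {self.w}")
        if not self.n_substitute > self.w:
            raise InvalidInputError(
                f"n_substitute ({self.n_substitute}) must exceed w ({self.w}) "
                "so that substituted broods have positive predation mortality"
            )
        if not self.s_setpoint > 0:
            raise InvalidInputError(f"s_setpoint must be > 0, got {self.s_setpoint}")
        if not self.n_setpoint >= 1:
            raise InvalidInputError(f"n_setpoint must be >= 1, got {self.n_setpoint}")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' breeder-investment observations.

    ``n_offspring`` may be fractional: heterogeneous sources and printed
    ranges are averaged upstream.  ``offspring_mass`` and ``breeder_mass``
    must share units within the record; only their ratio enters the model.
    ``brood_masses`` are optional per-offspring masses at dispersal used for
    the inequality index.
    """

    name: str
    taxon_group: str
    n_offspring: float
    offspring_mass: float
    breeder_mass: float
    brood_masses: Optional[tuple[float, ...]] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.breeder_mass > 0:
            raise InvalidInputError(
                f"{self.name}: breeder_mass must be > 0, got {self.breeder_mass}"
            )
        if self.offspring_mass < 0:
            raise InvalidInputError(
                f"{self.name}: offspring_mass must be >= 0, got {self.offspring_mass}"
            )
        if not self.n_offspring > 0:
            raise InvalidInputError(
                f"{self.name}: n_offspring must be > 0, got {self.n_offspring}"
            )
        if self.brood_masses is not None:
            masses = tuple(float(m) for m in self.brood_masses)
            if len(masses) < 2:
                raise InvalidInputError(
                    f"{self.name}: brood_masses needs >= 2 entries, got {len(masses)}"
                )
            if any(m < 0 for m in masses):
                raise InvalidInputError(f"{self.name}: brood_masses must be >= 0")
            object.__setattr__(self, "brood_masses", masses)


@dataclass(frozen=True)
class BroodProfile:
    """Per-offspring masses with descending-order ranks, mean, and Gini.

    Ranks follow the convention that the largest offspring at dispersal
    receives rank 1 and the smallest rank ``N``.
    """

    masses: tuple[float, ...]
    ranks: tuple[int, ...]
    mu: float
    gini: float

    @property
    def n(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class ClassificationResult:
    """Computed axes, indices, and assigned category for one species."""

    record: SpeciesRecord
    s_value: float
    p_value: float
    c_value: Optional[float]
    g_value: Optional[float]
    category: Category
    singleton_rule_applied: bool
    effective_n: float

    @property
    def species(self) -> str:
        return self.record.name

    @property
    def taxon_group(self) -> str:
        return self.record.taxon_group


def predation_mortality(n_offspring: float, w: float = 2.0) -> float:
    """Probability of offspring mortality by predation, ``P = 1 - w/N``.

    With replacement fitness fixed at ``w``, a brood of ``N`` offspring can
    afford to lose a fraction ``1 - w/N`` of them to consumers and still
    replace the breeder and her mate.  Callers must apply the singleton
    substitution first: ``N < w`` is a domain error here, never clamped.

    >>> predation_mortality(20, 2)
    0.9
    """
    if not n_offspring > 0:
        raise InvalidInputError(f"n_offspring must be > 0, got {n_offspring}")
    if not w > 0:
        raise InvalidInputError(f"w must be > 0, got {w}")
    if n_offspring < w:
        raise DomainError(
            f"n_offspring ({n_offspring}) < w ({w}) would give negative "
            "predation mortality; apply_singleton_rule first"
        )
    return 1.0 - w / n_offspring


def relative_quality(offspring_mass: float, breeder_mass: float) -> float:
    """Relative offspring quality ``S = m/M``.

    ``m`` is the mass of one offspring at dispersal — the moment it leaves
    maternal provisioning — and ``M`` the mass of the breeding female.  ``S``
    doubles as the modelled probability of offspring mortality by scarcity.
    Values above 1 (offspring outweighing the breeder) are permitted but
    logged, since they usually indicate an averaging artefact in the data.
    """
    if not breeder_mass > 0:
        raise InvalidInputError(f"breeder_mass must be > 0, got {breeder_mass}")
    if offspring_mass < 0:
        raise InvalidInputError(f"offspring_mass must be >= 0, got {offspring_mass}")
    s = offspring_mass / breeder_mass
    if s > 1:
        logger.warning(
            "relative quality S = %.4g exceeds 1 (offspring heavier than breeder)", s
        )
    return s


def _validated_masses(masses: Sequence[float]) -> np.ndarray:
    arr = np.asarray(masses, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidInputError(f"need a 1-d brood of >= 2 masses, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("brood masses must be finite numbers")
    if np.any(arr < 0):
        raise InvalidInputError("brood masses must be >= 0")
    if arr.sum() == 0:
        raise DegenerateBroodError("all-zero brood: inequality is undefined (mu = 0)")
    return arr


def gini(masses: Sequence[float]) -> float:
    """Bias-corrected Gini coefficient of brood inequality.

    Computed through the tie-invariant mean-absolute-difference form

        G = sum_{i,j} |m_i - m_j| / (2 N (N-1) mu),

    which is algebraically identical to the rank form
    :func:`gini_rank_form` whenever all masses are distinct, but does not
    depend on how rank ties are broken.  ``G`` is 0 for a perfectly equal
    brood, exactly 1 when a single offspring holds all mass, and invariant
    under permutation and positive rescaling of the masses.
    """
    arr = _validated_masses(masses)
    n = arr.size
    mu = arr.mean()
    s = np.sort(arr)
    # sum over ordered pairs |m_i - m_j| = 2 * sum_i (2i - n - 1) * s_(i), i = 1..n;
    # the coefficients sum to 0, so shifting by s[0] changes nothing analytically
    # but makes the equal-brood case cancel exactly in floating point
    coef = 2.0 * np.arange(1, n + 1) - n - 1
    return float(np.dot(coef, s - s[0]) / (n * (n - 1) * mu))


def gini_rank_form(masses: Sequence[float]) -> float:
    """Rank-form bias-corrected Gini,
    ``G = (N+1)/(N-1) - 2/(N (N-1) mu) * sum_i R_i m_i``,
    with descending ranks (largest offspring gets rank 1).

    Equivalent to :func:`gini` for distinct masses; with ties the value
    depends on the (stable) tie-break, which is why :func:`gini` is the
    canonical implementation.
    """
    arr = _validated_masses(masses)
    n = arr.size
    mu = arr.mean()
    ranks = _descending_ranks(arr)
    return float((n + 1) / (n - 1) - 2.0 * np.dot(ranks, arr) / (n * (n - 1) * mu))


def _descending_ranks(arr: np.ndarray) -> np.ndarray:
    """Ranks 1..N in descending mass order; ties broken by input position."""
    order = np.argsort(-arr, kind="stable")
    ranks = np.empty(arr.size, dtype=int)
    ranks[order] = np.arange(1, arr.size + 1)
    return ranks


def brood_profile(masses: Sequence[float]) -> BroodProfile:
    """Bundle a brood's masses with their ranks, mean, and Gini index."""
    arr = _validated_masses(masses)
    return BroodProfile(
        masses=tuple(arr.tolist()),
        ranks=tuple(_descending_ranks(arr).tolist()),
        mu=float(arr.mean()),
        gini=gini(arr),
    )


def convergent_index(p_value: float, s_value: float) -> float:
    """Convergent-selection index ``C = P * S``.

    The product of the probabilities of offspring mortality by predation and
    by scarcity; high ``C`` marks environments lethal on both axes at once,
    hypothesised to favour unequal (high-Gini) maternal investment and the
    evolution of permanent societies.
    """
    if not 0 <= p_value <= 1:
        raise InvalidInputError(f"p_value must be in [0, 1], got {p_value}")
    if not 0 <= s_value <= 1:
        raise InvalidInputError(f"s_value must be in [0, 1], got {s_value}")
    return p_value * s_value


def apply_singleton_rule(
    n_offspring: float, params: ModelParams = ModelParams()
) -> tuple[float, bool]:
    """Substitute ``N`` for broods smaller than replacement fitness.

    A brood of fewer than ``w`` offspring would give negative predation
    mortality; such broods (one offspring per breeding season under the
    default ``w = 2``) have ``N`` replaced by ``params.n_substitute``.
    Returns ``(effective_n, applied)`` so the substitution is always visible.
    """
    if not n_offspring > 0:
        raise InvalidInputError(f"n_offspring must be > 0, got {n_offspring}")
    if n_offspring < params.w:
        return params.n_substitute, True
    return float(n_offspring), False


def category_for(s_value: float, n_value: float, params: ModelParams = ModelParams()) -> Category:
    """Assign the selection category for a point on the (S, N) plane.

    The comparisons are ``<=`` on the low side of each set point and strictly
    ``>`` on the high side, so the four regions partition the plane.
    """
    if not s_value >= 0:
        raise InvalidInputError(f"s_value must be >= 0, got {s_value}")
    if not n_value > 0:
        raise InvalidInputError(f"n_value must be > 0, got {n_value}")
    low_s = s_value <= params.s_setpoint
    low_n = n_value <= params.n_setpoint
    if low_s and not low_n:
        return Category.PREDATION
    if not low_s and low_n:
        return Category.SCARCITY
    if low_s and low_n:
        return Category.WEAK
    return Category.CONVERGENT


def classify(record: SpeciesRecord, params: ModelParams = ModelParams()) -> ClassificationResult:
    """Classify one species into its natural-selection category.

    Computes ``S = m/M``, applies the singleton substitution to ``N``,
    computes ``P = 1 - w/N_eff``, assigns the category from ``(S, N_eff)``
    against the set points, and attaches ``C = P * S`` (and ``G`` when
    per-offspring brood masses are available).  When ``S > 1`` the product
    ``P * S`` is still reported but no longer interpretable as a joint
    mortality probability; a warning is logged.
    """
    s = relative_quality(record.offspring_mass, record.breeder_mass)
    effective_n, applied = apply_singleton_rule(record.n_offspring, params)
    p = predation_mortality(effective_n, params.w)
    if s <= 1:
        c: Optional[float] = convergent_index(p, s)
    else:
        logger.warning(
            "%s: S = %.4g > 1; C = P*S reported but not a probability", record.name, s
        )
        c = p * s
    g = gini(record.brood_masses) if record.brood_masses is not None else None
    return ClassificationResult(
        record=record,
        s_value=s,
        p_value=p,
        c_value=c,
        g_value=g,
        category=category_for(s, effective_n, params),
        singleton_rule_applied=applied,
        effective_n=effective_n,
    )


def map_to_legacy(category: Category) -> tuple[Optional[str], Optional[str]]:
    """Map a selection category to its r/K and CSR counterparts.

    Returns ``(r/K counterpart, CSR counterpart)``; ``None`` where the legacy
    theory has no matching category (neither addresses convergent selection).
    """
    try:
        return _LEGACY_MAP[Category(category)]
    except (KeyError, ValueError) as exc:
        raise InvalidInputError(f"unknown category: {category!r}") from exc


def summarize_by_taxon(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Contingency table of taxon group x selection category counts.

    Rows are taxon groups, columns the four categories (always all four, in
    model order); row sums equal the per-taxon record counts.
    """
    if len(results) == 0:
        raise InvalidInputError("no classification results to summarize")
    taxa = [r.taxon_group for r in results]
    cats = [r.category.value for r in results]
    table = pd.crosstab(
        pd.Series(taxa, name="taxon_group"), pd.Series(cats, name="category")
    )
    return table.reindex(columns=[c.value for c in Category], fill_value=0)
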
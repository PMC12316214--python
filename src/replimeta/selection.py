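"""Exhaustive information-criterion model selection, in two stages.

Stage 1 enumerates every admissible subset of the candidate covariates
for the location (each united with the forced covariates, typically the
original standard error) and ranks the location-only fits by AIC (or
BIC).  Stage 2 keeps the stage-1 winner's covariates as the joint pool
and enumerates (location subset, scale subset) combinations of that
pool, each fitted as a location-scale model, re-ranking by the same
criterion.

Admissibility: a covariate with a ``requires`` declaration may only
enter a set together with its companion — e.g. the share of male
authors only together with the author count.  Each such pair therefore
contributes a factor 3 (neither / companion only / both) instead of 4
to the search-space size, each free covariate a factor 2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .datamodel import CovariateMeta, InvalidInputError, ReplicationDataset
from .location import MetaRegressionFit, fit_location_additive, fit_location_multiplicative
from .locscale import LocationScaleFit, fit_ls_additive, fit_ls_multiplicative

logger = logging.getLogger("replimeta")

__all__ = [
    "ModelSpec",
    "RankedModel",
    "SelectionResult",
    "enumerate_location_models",
    "information_criterion",
    "select_two_stage",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate covariate configuration."""

    location_set: tuple[str, ...]
    scale_set: tuple[str, ...] = ()
    forced_location: tuple[str, ...] = ()


@dataclass(frozen=True)
class RankedModel:
    spec: ModelSpec
    criterion_value: float
    fit: MetaRegressionFit | None = None


@dataclass(frozen=True)
class SelectionResult:
    ranked: tuple[RankedModel, ...]
    best: ModelSpec
    criterion: str
    n_models_evaluated: int


def _check_constraints(candidates: Sequence[CovariateMeta], extra_known: set[str]) -> None:
    known = {m.name for m in candidates} | extra_known
    graph = {}
    for m in candidates:
        if m.requires is not None:
            if m.requires not in known:
                raise InvalidInputError(
                    f"covariate {m.name!r} requires unknown covariate {m.requires!r}"
                )
            graph[m.name] = m.requires
    # the requires relation must be acyclic
    for start in graph:
        seen = {start}
        node = start
        while node in graph:
            node = graph[node]
            if node in seen:
                raise InvalidInputError(f"cyclic 'requires' constraint involving {node!r}")
            seen.add(node)


def _admissible(subset: set[str], candidates: Sequence[CovariateMeta],
                always_present: set[str]) -> bool:
    for m in candidates:
        if m.name in subset and m.requires is not None:
            if m.requires not in subset and m.requires not in always_present:
                return False
    return True


def enumerate_location_models(
    candidates: Sequence[CovariateMeta],
    forced: Sequence[str] = (),
) -> list[ModelSpec]:
    """All admissible candidate subsets, each united with ``forced``.

    Deterministic order: subsets are enumerated by increasing bitmask
    over the candidate order given.
    """
    forced = tuple(forced)
    _check_constraints(candidates, set(forced))
    names = [m.name for m in candidates]
    specs = []
    for mask in range(1 << len(names)):
        subset = {names[i] for i in range(len(names)) if mask >> i & 1}
        if not _admissible(subset, candidates, set(forced)):
            continue
        location = forced + tuple(n for n in names if n in subset and n not in forced)
        specs.append(ModelSpec(location_set=location, forced_location=forced))
    return specs


def information_criterion(fit: MetaRegressionFit, which: str = "aic") -> float:
    """AIC = -2 l + 2 k, or BIC = -2 l + k ln(n)."""
    if which == "aic":
        return -2.0 * fit.loglik + 2.0 * fit.k
    if which == "bic":
        return -2.0 * fit.loglik + fit.k * math.log(fit.n_used)
    raise InvalidInputError(f"unknown criterion {which!r}")


def _sort_key(rm: RankedModel):
    k = rm.fit.k if rm.fit is not None else float("inf")
    return (rm.criterion_value, k, tuple(sorted(rm.spec.location_set)),
            tuple(sorted(rm.spec.scale_set)))


def _rank(entries: list[RankedModel], criterion: str) -> SelectionResult:
    ranked = tuple(sorted(entries, key=_sort_key))
    return SelectionResult(
        ranked=ranked,
        best=ranked[0].spec,
        criterion=criterion,
        n_models_evaluated=len(entries),
    )


def select_two_stage(
    dataset: ReplicationDataset,
    candidates: Sequence[CovariateMeta],
    flavor: str = "multiplicative",
    criterion: str = "aic",
    forced: Sequence[str] = (),
) -> tuple[SelectionResult, SelectionResult]:
    """Two-stage exhaustive selection: location first, then location-scale.

    Models that fail to fit are kept in the ranking with an infinite
    criterion value and a warning.  Returns the stage-1 and stage-2
    rankings.
    """
    if flavor not in ("multiplicative", "additive"):
        raise InvalidInputError(f"unknown flavor {flavor!r}")
    fit_location = (
        fit_location_multiplicative if flavor == "multiplicative" else fit_location_additive
    )
    fit_ls = fit_ls_multiplicative if flavor == "multiplicative" else fit_ls_additive

    # stage 1: location-only exhaustive search
    stage1_entries = []
    for spec in enumerate_location_models(candidates, forced):
        try:
            fit = fit_location(dataset, spec.location_set)
            stage1_entries.append(RankedModel(spec, information_criterion(fit, criterion), fit))
        except Exception as err:  # noqa: BLE001 - any failed fit is recorded, not fatal
            warnings.warn(f"location model {spec.location_set} failed: {err}")
            stage1_entries.append(RankedModel(spec, float("inf"), None))
    stage1 = _rank(stage1_entries, criterion)

    # stage 2: joint re-enumeration within the stage-1 winner's pool
    pool_names = stage1.best.location_set
    by_name = {m.name: m for m in candidates}
    pool = [by_name.get(n, CovariateMeta(n, "continuous")) for n in pool_names]
    forced_set = set(forced)
    loc_candidates = [m for m in pool if m.name not in forced_set]
    loc_specs = enumerate_location_models(loc_candidates, tuple(forced))
    scale_subsets = [s.location_set for s in enumerate_location_models(pool, ())]
    logger.info(
        "stage-2 search space: %d location subsets x %d scale subsets",
        len(loc_specs), len(scale_subsets),
    )

    stage2_entries = []
    for loc_spec in loc_specs:
        for scale_set in scale_subsets:
            spec = ModelSpec(loc_spec.location_set, tuple(scale_set), tuple(forced))
            try:
                fit = fit_ls(dataset, spec.location_set, spec.scale_set)
                stage2_entries.append(
                    RankedModel(spec, information_criterion(fit, criterion), fit)
                )
            except Exception as err:  # noqa: BLE001
                warnings.warn(
                    f"location-scale model {spec.location_set}/{spec.scale_set} failed: {err}"
                )
                stage2_entries.append(RankedModel(spec, float("inf"), None))
    stage2 = _rank(stage2_entries, criterion)
    return stage1, stage2
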
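"""Design matrices for meta-regression: reference-coded covariate expansion.

Categorical covariates are expanded with reference-cell coding: the first
declared level is the reference and produces no column; every other level
contributes an indicator column named ``covariate[level]``.  Pairs missing
a covariate that is actually in the model are dropped (complete-case per
fitted model) with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .datamodel import CovariateMeta, InvalidInputError, ReplicationDataset, StudyPair
from .differences import pair_difference

logger = logging.getLogger("replimeta")

__all__ = ["DesignMatrixSpec", "ModelData", "build_design", "prepare_model_data"]


@dataclass(frozen=True)
class DesignMatrixSpec:
    """Post-expansion layout of a covariate set."""

    covariates: tuple[str, ...]
    column_names: tuple[str, ...]  # excluding the intercept

    @property
    def p(self) -> int:
        return len(self.column_names)


@dataclass(frozen=True)
class ModelData:
    """Numerical ingredients of one meta-regression fit."""

    pair_ids: tuple[str, ...]
    y: np.ndarray          # estimated differences Delta_hat_i
    v: np.ndarray          # squared SE of the difference, se_o^2 + se_r^2
    X: np.ndarray          # location design incl. leading intercept column
    location: DesignMatrixSpec
    Z: np.ndarray | None = None   # scale design incl. intercept, or None
    scale: DesignMatrixSpec | None = None
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.y.shape[0]


def _meta_map(dataset: ReplicationDataset) -> dict[str, CovariateMeta]:
    return {m.name: m for m in dataset.covariate_meta}


def _expand(pairs: Sequence[StudyPair], covariates: Sequence[str],
            metas: dict[str, CovariateMeta]) -> tuple[np.ndarray, DesignMatrixSpec]:
    columns: list[np.ndarray] = [np.ones(len(pairs))]
    names: list[str] = []
    for name in covariates:
        meta = metas.get(name, CovariateMeta(name, "continuous"))
        if meta.kind == "continuous":
            col = np.array([float(p.covariate(name)) for p in pairs])
            columns.append(col)
            names.append(name)
        else:
            values = [str(p.covariate(name)) for p in pairs]
            unknown = sorted(set(values) - set(meta.levels))
            if unknown:
                raise InvalidInputError(
                    f"covariate {name!r}: values {unknown} not among declared levels"
                )
            for level in meta.levels[1:]:
                columns.append(np.array([1.0 if v == level else 0.0 for v in values]))
                names.append(f"{name}[{level}]")
    X = np.column_stack(columns)
    return X, DesignMatrixSpec(tuple(covariates), tuple(names))


def _check_rank(X: np.ndarray, names: Sequence[str], what: str) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [i for i, d in enumerate(diag) if d <= tol]
    if bad:
        all_names = ["intercept", *names]
        cols = [all_names[piv[i]] for i in bad]
        raise InvalidInputError(f"{what} design matrix is rank deficient; collinear columns: {cols}")


def build_design(dataset: ReplicationDataset, covariates: Sequence[str]):
    """Expand covariates for all pairs of a dataset (no completeness filter)."""
    return _expand(dataset.pairs, covariates, _meta_map(dataset))


def prepare_model_data(
    dataset: ReplicationDataset,
    location_covariates: Sequence[str] = (),
    scale_covariates: Sequence[str] | None = None,
) -> ModelData:
    """Assemble response, variances and design matrices for one model.

    Complete-case per model: only pairs with values for every covariate
    appearing in this particular model are used.
    """
    metas = _meta_map(dataset)
    needed = list(dict.fromkeys([*location_covariates, *(scale_covariates or ())]))
    for name in needed:
        if name not in metas and not all(p.covariate(name) is not None for p in dataset.pairs):
            raise InvalidInputError(f"unknown covariate {name!r}")

    used = [p for p in dataset.pairs if all(p.covariate(c) is not None for c in needed)]
    n_dropped = len(dataset.pairs) - len(used)
    if n_dropped:
        logger.warning(
            "dropping %d pair(s) with missing values for covariates %s", n_dropped, needed
        )
    if not used:
        raise InvalidInputError("no study pair has complete covariate information")

    diffs = [pair_difference(p) for p in used]
    y = np.array([d.delta_hat for d in diffs])
    v = np.array([d.se_delta**2 for d in diffs])

    X, loc_spec = _expand(used, location_covariates, metas)
    _check_rank(X, loc_spec.column_names, "location")

    Z = None
    scale_spec = None
    if scale_covariates is not None:
        Z, scale_spec = _expand(used, scale_covariates, metas)
        _check_rank(Z, scale_spec.column_names, "scale")

    return ModelData(
        pair_ids=tuple(p.pair_id for p in used),
        y=y, v=v, X=X,
        location=loc_spec, Z=Z, scale=scale_spec,
        n_dropped=n_dropped,
    )
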
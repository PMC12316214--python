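"""Study-pair data model, Fisher-z transform, and tabular I/O.

The unit of analysis throughout the package is the original–replication
*study pair*.  Effect estimates of both studies must live on a common,
approximately normal scale; for correlations the conventional choice is
the Fisher z-transform, ``z = atanh(r)`` with standard error
``1/sqrt(n - 3)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectEstimate",
    "StudyPair",
    "CovariateMeta",
    "ReplicationDataset",
    "fisher_z",
    "orient_positive",
    "load_dataset",
    "write_dataset",
    "DEFAULT_COLUMNS",
]

logger = logging.getLogger("replimeta")

#: Default column names understood by :func:`load_dataset`.
DEFAULT_COLUMNS = {
    "pair_id": "pair_id",
    "project": "project",
    "effect_o": "effect_o",
    "se_o": "se_o",
    "n_o": "n_o",
    "effect_r": "effect_r",
    "se_r": "se_r",
    "n_r": "n_r",
}


class InvalidInputError(ValueError):
    """Raised when user input violates a documented precondition."""


@dataclass(frozen=True)
class EffectEstimate:
    """An effect size and its standard error on the analysis scale.

    Parameters
    ----------
    estimate:
        Effect size on the analysis scale (Fisher-z by convention).
    standard_error:
        Standard error on the same scale; must be strictly positive.
    sample_size:
        Optional study sample size.  For Fisher-z effects it must be
        consistent with ``standard_error = 1/sqrt(n - 3)``.
    scale_tag:
        Either ``"fisher_z"`` or ``"raw"``.
    """

    estimate: float
    standard_error: float
    sample_size: int | None = None
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise InvalidInputError("estimate must be finite")
        if not (self.standard_error > 0):
            raise InvalidInputError(
                f"standard_error must be > 0, got {self.standard_error!r}"
            )
        if self.scale_tag not in ("fisher_z", "raw"):
            raise InvalidInputError(f"unknown scale_tag {self.scale_tag!r}")
        if (
            self.scale_tag == "fisher_z"
            and self.sample_size is not None
            and abs(self.standard_error - 1.0 / math.sqrt(self.sample_size - 3)) > 1e-10
        ):
            raise InvalidInputError(
                "standard_error inconsistent with 1/sqrt(n-3) for fisher_z scale"
            )


@dataclass(frozen=True)
class StudyPair:
    """One original–replication study pair with optional covariates."""

    pair_id: str
    original: EffectEstimate
    replication: EffectEstimate
    project: str = ""
    covariates: Mapping[str, object] = field(default_factory=dict)
    oriented: bool = False
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.original.scale_tag != self.replication.scale_tag:
            raise InvalidInputError(
                f"pair {self.pair_id!r}: original and replication must share scale_tag"
            )

    def covariate(self, name: str):
        """Return a covariate value or ``None`` when missing.

        The standard errors are always available as covariates under the
        names ``se_o`` and ``se_r`` (the original SE is the canonical
        shrinkage covariate), even when not stored explicitly.
        """
        value = self.covariates.get(name)
        if value is None and name == "se_o":
            return self.original.standard_error
        if value is None and name == "se_r":
            return self.replication.standard_error
        if value is None:
            return None
        if isinstance(value, float) and math.isnan(value):
            return None
        return value


@dataclass(frozen=True)
class CovariateMeta:
    """Declaration of a covariate: its kind, levels and pairing constraint.

    ``requires`` names a companion covariate that must be present in any
    model that contains this one (e.g. a share-of-male-authors covariate
    that is only interpretable together with the author count).
    """

    name: str
    kind: str = "continuous"
    levels: tuple[str, ...] = ()
    requires: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise InvalidInputError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise InvalidInputError(
                f"categorical covariate {self.name!r} needs >= 2 levels"
            )
        if self.kind == "continuous" and self.levels:
            raise InvalidInputError(
                f"continuous covariate {self.name!r} must not declare levels"
            )


@dataclass(frozen=True)
class ReplicationDataset:
    """A collection of study pairs plus covariate metadata."""

    pairs: tuple[StudyPair, ...]
    covariate_meta: tuple[CovariateMeta, ...] = ()

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate pair_ids: {dupes}")
        known = {m.name for m in self.covariate_meta}
        for m in self.covariate_meta:
            if m.requires is not None and m.requires not in known:
                raise InvalidInputError(
                    f"covariate {m.name!r} requires unknown covariate {m.requires!r}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def meta(self, name: str) -> CovariateMeta:
        for m in self.covariate_meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def subset(self, pairs: Iterable[StudyPair]) -> "ReplicationDataset":
        return ReplicationDataset(tuple(pairs), self.covariate_meta)


def fisher_z(r: float, n: int) -> EffectEstimate:
    """Fisher z-transform a correlation: ``atanh(r)`` with se ``1/sqrt(n-3)``.

    Parameters
    ----------
    r:
        Correlation coefficient, ``|r| < 1``.
    n:
        Sample size of the study, ``n > 3``.
    """
    if not abs(r) < 1:
        raise InvalidInputError(f"r must satisfy |r| < 1, got r={r!r}")
    if not n > 3:
        raise InvalidInputError(f"n must be > 3, got n={n!r}")
    return EffectEstimate(
        estimate=math.atanh(r),
        standard_error=1.0 / math.sqrt(n - 3),
        sample_size=int(n),
        scale_tag="fisher_z",
    )


def orient_positive(pair: StudyPair) -> StudyPair:
    """Orient a pair so the original effect is non-negative.

    When the original estimate is negative both estimates are sign-flipped
    (standard errors are unaffected) and the ``oriented`` flag records the
    flip.  Zero originals count as already positive.  Idempotent.
    """
    if pair.original.estimate >= 0:
        return pair
    return replace(
        pair,
        original=replace(pair.original, estimate=-pair.original.estimate),
        replication=replace(pair.replication, estimate=-pair.replication.estimate),
        oriented=True,
    )


def _effect_from_row(row, eff_col, se_col, n_col, pair_id, scale_tag):
    se = row[se_col]
    if not (float(se) > 0):
        raise InvalidInputError(
            f"pair {pair_id!r}: non-positive standard error in column {se_col!r}"
        )
    n = None
    if n_col in row.index and pd.notna(row[n_col]):
        n = int(row[n_col])
    if (
        n is not None
        and scale_tag == "fisher_z"
        and abs(float(se) - 1.0 / math.sqrt(n - 3)) > 1e-10
    ):
        # rounded published SEs rarely satisfy the identity exactly; keep
        # the SE (which drives every analysis) and discard the sample size
        logger.warning(
            "pair %s: se %s inconsistent with 1/sqrt(n-3) for n=%d; dropping n",
            pair_id, se, n,
        )
        n = None
    return EffectEstimate(float(row[eff_col]), float(se), n, scale_tag)


def load_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    covariate_meta: Sequence[CovariateMeta] | None = None,
    scale_tag: str = "fisher_z",
    sep: str | None = None,
) -> ReplicationDataset:
    """Read a replication dataset from a CSV/TSV file.

    Every column not claimed by the effect/SE schema is treated as a
    covariate.  Rows with a missing effect or standard error are dropped
    (with a logged count); rows with missing covariate values are kept and
    flagged ``incomplete``.  Without an explicit ``covariate_meta``,
    numeric columns become continuous covariates and string columns
    categorical ones with levels in order of first appearance.
    """
    cols = dict(DEFAULT_COLUMNS)
    if schema:
        cols.update(schema)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)

    for key in ("effect_o", "se_o", "effect_r", "se_r"):
        if cols[key] not in df.columns:
            raise InvalidInputError(f"required column {cols[key]!r} missing from {path}")

    essential = [cols["effect_o"], cols["se_o"], cols["effect_r"], cols["se_r"]]
    complete = df[essential].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d row(s) with missing effect or SE", n_dropped)
    df = df[complete]

    reserved = set(cols.values())
    cov_names = [c for c in df.columns if c not in reserved]

    pairs = []
    for idx, row in df.iterrows():
        pair_id = (
            str(row[cols["pair_id"]]) if cols["pair_id"] in df.columns else str(idx)
        )
        covs = {}
        incomplete = False
        for c in cov_names:
            v = row[c]
            if pd.isna(v):
                covs[c] = None
                incomplete = True
            else:
                covs[c] = v.item() if hasattr(v, "item") else v
        pairs.append(
            StudyPair(
                pair_id=pair_id,
                project=str(row[cols["project"]]) if cols["project"] in df.columns else "",
                original=_effect_from_row(
                    row, cols["effect_o"], cols["se_o"], cols["n_o"], pair_id, scale_tag
                ),
                replication=_effect_from_row(
                    row, cols["effect_r"], cols["se_r"], cols["n_r"], pair_id, scale_tag
                ),
                covariates=covs,
                incomplete=incomplete,
            )
        )

    if covariate_meta is None:
        covariate_meta = _infer_covariate_meta(df, cov_names)
    logger.info("loaded %d pair(s) (%d dropped for missing effect/SE)", len(pairs), n_dropped)
    return ReplicationDataset(tuple(pairs), tuple(covariate_meta))


def _infer_covariate_meta(df: pd.DataFrame, cov_names: list[str]) -> list[CovariateMeta]:
    meta = []
    for c in cov_names:
        col = df[c].dropna()
        if pd.api.types.is_numeric_dtype(col):
            meta.append(CovariateMeta(c, "continuous"))
        else:
            levels = tuple(dict.fromkeys(str(v) for v in col))
            if len(levels) < 2:
                # constant string column carries no information but must
                # stay declarable; treat as continuous-unusable is worse,
                # so pad with a phantom reference-only declaration
                levels = levels + ("<other>",)
            meta.append(CovariateMeta(c, "categorical", levels))
    return meta


def write_dataset(dataset: ReplicationDataset, path, sep: str = ",") -> None:
    """Write a dataset back to CSV with the default column layout."""
    cov_names = [m.name for m in dataset.covariate_meta]
    rows = []
    for p in dataset.pairs:
        row = {
            "pair_id": p.pair_id,
            "project": p.project,
            "effect_o": p.original.estimate,
            "se_o": p.original.standard_error,
            "n_o": p.original.sample_size,
            "effect_r": p.replication.estimate,
            "se_r": p.replication.standard_error,
            "n_r": p.replication.sample_size,
        }
        for c in cov_names:
            row[c] = p.covariate(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
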
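"""Recovery, enrichment and depletion accounting across separation fractions.

A fractionation stage (size-exclusion chromatography or a density gradient)
splits an input sample into an ordered series of fractions.  For every analyte
(particles, bulk protein, or a named marker such as CD9 or APOA1) the
quantities of interest are

* the *recovery* of the analyte in a chosen set of fractions — the summed
  amount in those fractions divided by the whole-input total, and
* the *enrichment factor* of one analyte relative to another — the ratio of
  their recoveries over the same fraction set, algebraically identical to
  comparing the analyte ratio in the selected fractions to the same ratio in
  the unfractionated input.

Factors are computed at full precision; rounding to the nearest integer (as
headline "n-fold" values are usually quoted) is left to the presentation
layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedRecoveryError",
    "FractionationRun",
    "EnrichmentReport",
    "recovery_fraction",
    "enrichment_factor",
    "depletion_factor",
    "elution_profile",
    "compute_enrichment",
    "write_run",
    "read_run",
]

#: canonical column names of the per-fraction measurement table
_BASE_COLUMNS = ("fraction_id", "volume_ml", "density_g_ml", "particle_count", "protein_mass")

#: analyte aliases mapping user-facing names onto table columns
_ANALYTE_COLUMNS = {"particles": "particle_count", "protein": "protein_mass"}


class UndefinedRecoveryError(ValueError):
    """Raised when a recovery is requested against a zero reference total."""


@dataclass
class FractionationRun:
    """Ordered per-fraction measurements for one separation stage.

    Parameters
    ----------
    stage:
        Label of the separation stage, e.g. ``"SEC"`` or ``"ODG"``.
    reference:
        Whole-input totals keyed by analyte name (``"particles"``,
        ``"protein"`` and marker names).  Recoveries are computed against
        these totals.
    fractions:
        Table with one row per fraction.  Required columns:
        ``fraction_id`` (1-based, consecutive), ``volume_ml``,
        ``particle_count``, ``protein_mass``; optional ``density_g_ml``;
        any further column is treated as a marker amount.
    """

    stage: str
    reference: dict[str, float]
    fractions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = {"fraction_id", "volume_ml", "particle_count", "protein_mass"} - set(
            self.fractions.columns
        )
        if missing:
            raise ValueError(f"fraction table lacks columns: {sorted(missing)}")
        ids = self.fractions["fraction_id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("fraction ids must be consecutive and 1-based")
        for name, total in self.reference.items():
            if total < 0:
                raise ValueError(f"negative reference total for {name!r}")

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    @property
    def markers(self) -> list[str]:
        return [c for c in self.fractions.columns if c not in _BASE_COLUMNS]

    @property
    def analytes(self) -> list[str]:
        return ["particles", "protein", *self.markers]

    def amounts(self, analyte: str) -> pd.Series:
        """Per-fraction amounts of *analyte*, indexed by fraction id."""
        column = _ANALYTE_COLUMNS.get(analyte, analyte)
        if column not in self.fractions.columns:
            raise KeyError(f"unknown analyte {analyte!r}; have {self.analytes}")
        return pd.Series(
            self.fractions[column].to_numpy(dtype=float),
            index=pd.Index(self.fractions["fraction_id"], name="fraction_id"),
            name=analyte,
        )


@dataclass
class EnrichmentReport:
    """Enrichment of one analyte relative to another over selected fractions."""

    numerator: str
    denominator: str
    fractions: tuple[int, ...]
    recovery_numerator: float
    recovery_denominator: float
    factor: float

    def rounded_factor(self) -> int:
        """Presentation-layer integer factor (quoted as "n-fold")."""
        return int(round(self.factor))

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "fractions": list(self.fractions),
            "recovery_numerator": self.recovery_numerator,
            "recovery_denominator": self.recovery_denominator,
            "factor": self.factor,
            "factor_rounded": self.rounded_factor(),
        }


def recovery_fraction(run: FractionationRun, fractions: Iterable[int], analyte: str) -> float:
    """Proportion of the input *analyte* recovered in the selected fractions.

    Raises
    ------
    UndefinedRecoveryError
        If the whole-input reference total of the analyte is zero.
    KeyError / ValueError
        For unknown analytes or fraction ids.
    """
    amounts = run.amounts(analyte)
    wanted = sorted(set(int(f) for f in fractions))
    unknown = [f for f in wanted if f not in amounts.index]
    if unknown:
        raise ValueError(f"fraction ids {unknown} not in run (1..{run.n_fractions})")
    if analyte not in run.reference:
        raise KeyError(f"analyte {analyte!r} has no reference total")
    total = float(run.reference[analyte])
    if total == 0.0:
        raise UndefinedRecoveryError(
            f"recovery of {analyte!r} is undefined: reference total is zero"
        )
    recovery = float(amounts.loc[wanted].sum()) / total
    if recovery > 1.0:
        # measurement noise can push a recovery slightly past unity
        warnings.warn(
            f"recovery of {analyte!r} is {recovery:.4f} > 1; clamping for reporting",
            stacklevel=2,
        )
        recovery = 1.0
    return recovery


def enrichment_factor(recovery_numerator: float, recovery_denominator: float) -> float:
    """Ratio of two recoveries over the same fraction set.

    Equals (numerator/denominator ratio in the selected fractions) divided by
    the same ratio in the whole input, since the selected-fraction volumes
    cancel.
    """
    if recovery_numerator <= 0:
        raise ValueError("numerator recovery must be > 0")
    if recovery_denominator <= 0:
        raise ValueError("denominator recovery must be > 0; refusing to return infinity")
    return recovery_numerator / recovery_denominator


def depletion_factor(recovery_particles: float, recovery_marker: float) -> float:
    """Relative depletion of a marker with respect to particle recovery.

    Alias of :func:`enrichment_factor` with the marker in the denominator;
    a factor of 2000 means the marker was depleted 2000-fold relative to
    particles.
    """
    return enrichment_factor(recovery_particles, recovery_marker)


def elution_profile(run: FractionationRun, analyte: str) -> pd.Series:
    """Per-fraction proportion series for *analyte* relative to the input total.

    The series sums to the analyte's overall recovery (1.0 for a lossless,
    noise-free run).
    """
    amounts = run.amounts(analyte)
    if analyte not in run.reference:
        raise KeyError(f"analyte {analyte!r} has no reference total")
    total = float(run.reference[analyte])
    if total == 0.0:
        raise UndefinedRecoveryError(
            f"elution profile of {analyte!r} is undefined: reference total is zero"
        )
    return amounts / total


def compute_enrichment(
    run: FractionationRun,
    fractions: Iterable[int],
    numerator: str,
    denominator: str,
) -> EnrichmentReport:
    """Recoveries of two analytes over one fraction set and their ratio."""
    fracs = tuple(sorted(set(int(f) for f in fractions)))
    rn = recovery_fraction(run, fracs, numerator)
    rd = recovery_fraction(run, fracs, denominator)
    return EnrichmentReport(
        numerator=numerator,
        denominator=denominator,
        fractions=fracs,
        recovery_numerator=rn,
        recovery_denominator=rd,
        factor=enrichment_factor(rn, rd),
    )


def write_run(run: FractionationRun, tsv_path: str | Path, meta: Mapping | None = None) -> None:
    """Write the fraction table as TSV plus a JSON sidecar with reference totals."""
    tsv_path = Path(tsv_path)
    run.fractions.to_csv(tsv_path, sep="\t", index=False)
    sidecar = {
        "stage": run.stage,
        "reference": {k: float(v) for k, v in run.reference.items()},
        "meta": dict(meta) if meta else {},
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_run(tsv_path: str | Path) -> FractionationRun:
    """Read a run written by :func:`write_run`."""
    tsv_path = Path(tsv_path)
    table = pd.read_csv(tsv_path, sep="\t")
    sidecar = json.loads(tsv_path.with_suffix(".json").read_text())
    return FractionationRun(
        stage=sidecar["stage"], reference=sidecar["reference"], fractions=table
    )
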
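"""Core tabular containers for amplicon count data.

An :class:`OtuTable` is a samples × OTUs matrix of non-negative integer read
counts, backed by a pandas DataFrame whose index holds sample identifiers and
whose columns hold OTU identifiers.  A :class:`RelativeAbundanceTable` holds
the per-sample closed (sum-to-one) compositions derived from it, optionally
after a variance-stabilising fourth-root transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSTRATE_BINS = (
    "background",
    "PUR",
    "carbonate",
    "silica",
    "mixed",
    "steel",
    "organic",
    "control",
)


class ValidationError(ValueError):
    """Raised when a container or operation pre-condition is violated."""


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample experimental annotations.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier, matching a row of the count table.
    substrate_bin : str
        One of :data:`SUBSTRATE_BINS` — the colonization substrate category
        (water "background", polyurethane foam, carbonate/silica/mixed/steel
        solids, organic sponge) or "control" for sequencing controls.
    incubation : int or None
        Deployment number (1–5), or None for samples outside the timetable
        (e.g. sequencing controls).
    is_control : bool
        True for extraction / no-template / un-incubated mineral controls.
    """

    sample_id: str
    substrate_bin: str
    incubation: int | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.substrate_bin not in SUBSTRATE_BINS:
            raise ValidationError(
                f"unknown substrate_bin {self.substrate_bin!r}; "
                f"must be one of {sorted(SUBSTRATE_BINS)}"
            )
        if self.incubation is not None and self.incubation not in range(1, 6):
            raise ValidationError(
                f"incubation must be in 1..5 or None, got {self.incubation!r}"
            )
        if self.is_control and self.substrate_bin != "control":
            raise ValidationError(
                "is_control samples must use substrate_bin 'control', "
                f"got {self.substrate_bin!r}"
            )


@dataclass
class OtuTable:
    """Samples × OTUs count matrix with identifiers and optional taxonomy."""

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate OTU id {dup!r}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if arr.size and (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = counts
        if self.taxonomy is not None and not self.taxonomy.index.equals(counts.columns):
            raise ValidationError("taxonomy index must match OTU ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_otus(self, keep: list[str]) -> "OtuTable":
        tax = self.taxonomy.loc[keep] if self.taxonomy is not None else None
        return OtuTable(self.counts.loc[:, keep].copy(), taxonomy=tax)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class RelativeAbundanceTable:
    """Samples × OTUs fractional abundances; ``transformed`` marks x**(1/4)."""

    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr < 0).any() or arr.size and (arr > 1 + 1e-12).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        if not self.transformed and arr.size:
            sums = arr.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0))
            if bad.any():
                raise ValidationError(
                    f"untransformed rows must sum to 1 (sample "
                    f"{self.values.index[np.flatnonzero(bad)[0]]!r})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


def to_relative_abundance(table: OtuTable) -> RelativeAbundanceTable:
    """Close each sample's counts to fractions summing to one.

    Samples whose total count is zero become all-zero rows and trigger a
    :class:`UserWarning` naming them.
    """
    totals = table.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            "zero-total samples left as all-zero rows: "
            f"{list(table.counts.index[zero])}",
            UserWarning,
            stacklevel=2,
        )
    safe = totals.replace(0, 1)
    values = table.counts.div(safe, axis=0).astype(float)
    return RelativeAbundanceTable(values, transformed=False)
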
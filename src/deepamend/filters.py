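"""OTU-table filtering and transformation steps.

The processing chain mirrors standard amplicon practice for low-biomass
subsurface samples: drop dataset-wide singletons, drop OTUs below a
dataset-wide relative-abundance threshold (default 0.01%), remove OTUs that
reach ≥0.05% relative abundance in any negative-control sample, close the
counts to relative abundances, and fourth-root transform before ordination.

Each step is an sklearn-style transformer (``fit`` records the OTUs to drop
in ``removed_otu_ids_``; ``transform`` applies the membership change without
altering surviving counts).  The module-level functions are thin wrappers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .otu import (
    OtuTable,
    RelativeAbundanceTable,
    ValidationError,
    to_relative_abundance,
)


class SingletonFilter(BaseEstimator, TransformerMixin):
    """Remove OTUs whose total count across all samples is exactly one."""

    def fit(self, X: OtuTable, y=None) -> "SingletonFilter":
        totals = X.counts.sum(axis=0)
        self.removed_otu_ids_ = list(totals.index[totals == 1])
        return self

    def transform(self, X: OtuTable) -> OtuTable:
        keep = [o for o in X.otu_ids if o not in set(self.removed_otu_ids_)]
        return X.subset_otus(keep)


class AbundanceThresholdFilter(BaseEstimator, TransformerMixin):
    """Retain an OTU iff its share of the grand total count is ≥ ``threshold``.

    Parameters
    ----------
    threshold : float, default 1e-4
        Dataset-wide relative-abundance cutoff (0.01%).  Retention uses ≥,
        so an OTU sitting exactly on the boundary is kept.
    mode : {"dataset", "per_sample_max"}
        "dataset" compares each OTU's grand-total fraction; "per_sample_max"
        instead keeps an OTU if it reaches the threshold within at least one
        sample.
    """

    def __init__(self, threshold: float = 1e-4, mode: str = "dataset") -> None:
        self.threshold = threshold
        self.mode = mode

    def fit(self, X: OtuTable, y=None) -> "AbundanceThresholdFilter":
        if not (0 <= self.threshold < 1):
            raise ValidationError(
                f"threshold must lie in [0, 1), got {self.threshold}"
            )
        if self.mode not in ("dataset", "per_sample_max"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        counts = X.counts
        if self.mode == "dataset":
            grand = counts.to_numpy().sum()
            frac = counts.sum(axis=0) / max(grand, 1)
        else:
            totals = counts.sum(axis=1).replace(0, 1)
            frac = counts.div(totals, axis=0).max(axis=0)
        self.removed_otu_ids_ = list(frac.index[frac < self.threshold])
        return self

    def transform(self, X: OtuTable) -> OtuTable:
        keep = [o for o in X.otu_ids if o not in set(self.removed_otu_ids_)]
        return X.subset_otus(keep)


class ContaminantFilter(BaseEstimator, TransformerMixin):
    """Remove OTUs that are abundant in negative-control samples.

    An OTU is flagged as a contaminant when its relative abundance within a
    control sample reaches ``cutoff`` (default 0.05%).  ``mode="max"`` flags
    on any single control (the stricter reading); ``mode="mean"`` flags on
    the mean relative abundance over all controls.
    """

    def __init__(
        self, controls: OtuTable | None = None, cutoff: float = 5e-4, mode: str = "max"
    ) -> None:
        self.controls = controls
        self.cutoff = cutoff
        self.mode = mode

    def fit(self, X: OtuTable, y=None) -> "ContaminantFilter":
        if self.controls is None:
            raise ValidationError("ContaminantFilter requires control samples")
        if self.mode not in ("max", "mean"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        missing = set(X.otu_ids) - set(self.controls.otu_ids)
        if missing:
            raise ValidationError(
                "control samples must share the OTU universe of the table; "
                f"missing from controls: {sorted(missing)[:5]}"
            )
        # Relative abundance is judged against each control's full composition,
        # even when the main table was already reduced by earlier filters.
        ctl = self.controls.counts
        totals = ctl.sum(axis=1).replace(0, 1)
        rel = ctl.div(totals, axis=0)
        stat = rel.max(axis=0) if self.mode == "max" else rel.mean(axis=0)
        flagged = set(stat.index[stat >= self.cutoff])
        self.removed_otu_ids_ = [o for o in X.otu_ids if o in flagged]
        return self

    def transform(self, X: OtuTable) -> OtuTable:
        keep = [o for o in X.otu_ids if o not in set(self.removed_otu_ids_)]
        return X.subset_otus(keep)


class FourthRootTransform(BaseEstimator, TransformerMixin):
    """Elementwise x**(1/4) on a relative-abundance table.

    Compresses the dynamic range so that ordination is not dominated by the
    handful of most abundant OTUs.  Refuses to run twice (the ``transformed``
    flag on the table guards against accidental double application).
    """

    def fit(self, X: RelativeAbundanceTable, y=None) -> "FourthRootTransform":
        return self

    def transform(self, X: RelativeAbundanceTable) -> RelativeAbundanceTable:
        if X.transformed:
            raise ValidationError("table is already fourth-root transformed")
        values = np.power(X.values, 0.25)
        return RelativeAbundanceTable(values, transformed=True)


def remove_singletons(table: OtuTable) -> tuple[OtuTable, list[str]]:
    f = SingletonFilter().fit(table)
    return f.transform(table), f.removed_otu_ids_


def abundance_threshold_filter(
    table: OtuTable, threshold: float = 1e-4, mode: str = "dataset"
) -> tuple[OtuTable, list[str]]:
    f = AbundanceThresholdFilter(threshold=threshold, mode=mode).fit(table)
    return f.transform(table), f.removed_otu_ids_


def contaminant_filter(
    table: OtuTable, controls: OtuTable, cutoff: float = 5e-4, mode: str = "max"
) -> tuple[OtuTable, list[str]]:
    f = ContaminantFilter(controls=controls, cutoff=cutoff, mode=mode).fit(table)
    return f.transform(table), f.removed_otu_ids_


def fourth_root_transform(rel: RelativeAbundanceTable) -> RelativeAbundanceTable:
    return FourthRootTransform().fit(rel).transform(rel)


def apply_filter_chain(
    table: OtuTable,
    controls: OtuTable | None = None,
    *,
    singletons: bool = True,
    threshold: float = 1e-4,
    control_cutoff: float = 5e-4,
) -> tuple[OtuTable, dict[str, list[str]]]:
    """Run the full filter chain, returning the table and a removal ledger.

    Order: singletons → abundance threshold → control-based contaminants.
    """
    ledger: dict[str, list[str]] = {}
    if singletons:
        table, ledger["singletons"] = remove_singletons(table)
    table, ledger["abundance_threshold"] = abundance_threshold_filter(
        table, threshold=threshold
    )
    if controls is not None:
        table, ledger["contaminants"] = contaminant_filter(
            table, controls, cutoff=control_cutoff
        )
    return table, ledger


__all__ = [
    "SingletonFilter",
    "AbundanceThresholdFilter",
    "ContaminantFilter",
    "FourthRootTransform",
    "remove_singletons",
    "abundance_threshold_filter",
    "contaminant_filter",
    "fourth_root_transform",
    "to_relative_abundance",
    "apply_filter_chain",
]
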